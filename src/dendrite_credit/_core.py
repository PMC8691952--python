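"""Numba-compiled integration core.

Implements the semi-implicit (implicit-Euler, staggered-gating) update for the
compartmental cable + Hodgkin-Huxley + synapse system, and the coupled forward
sensitivity system for per-synapse voltage gradients.  The tree-structured
linear system of each step is solved exactly by ordered (Hines) elimination in
O(n_comp); the sensitivity system reuses one factorization for all tracked
synapses.

All quantities are pre-normalized by compartment capacitance, so voltage-like
states are in mV, rates in ms^-1, synaptic weights in uS, currents in nA, and
sensitivities in mV/uS.
"""

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# gating kinetics (threshold-shifted Traub-style Na/K, M-type K, HCN)


@njit(cache=True)
def _f_exprel(x):
    """x / (exp(x) - 1), stable near 0."""
    if abs(x) < 1e-6:
        return 1.0 - x / 2.0 + x * x / 12.0
    return x / np.expm1(x)


@njit(cache=True)
def rates_m(v, vt):
    x = v - vt - 13.0
    y = v - vt - 40.0
    am = 1.28 * _f_exprel(-x / 4.0)
    bm = 1.4 * _f_exprel(y / 5.0)
    return am, bm


@njit(cache=True)
def rates_h(v, vt):
    ah = 0.128 * np.exp(-(v - vt - 17.0) / 18.0)
    bh = 4.0 / (1.0 + np.exp(-(v - vt - 40.0) / 5.0))
    return ah, bh


@njit(cache=True)
def rates_n(v, vt):
    z = v - vt - 15.0
    an = 0.16 * _f_exprel(-z / 5.0)
    bn = 0.5 * np.exp(-(v - vt - 10.0) / 40.0)
    return an, bn


@njit(cache=True)
def rates_p(v, tau_peak):
    """Slow (M-type) K+ gate; tau_peak is the maximum of the time constant."""
    u = v + 35.0
    pinf = 1.0 / (1.0 + np.exp(-u / 10.0))
    # denominator minimum is 2*sqrt(3.3); scale so max(tau) == tau_peak
    inv_tau = (3.3 * np.exp(u / 20.0) + np.exp(-u / 20.0)) \
        / (tau_peak * 2.0 * np.sqrt(3.3))
    ap = pinf * inv_tau
    bp = (1.0 - pinf) * inv_tau
    return ap, bp


@njit(cache=True)
def rates_q(v):
    """HCN gate (hyperpolarization-activated)."""
    w = v + 154.9
    aq = 0.00643 * 11.9 * _f_exprel(w / 11.9)
    bq = 0.193 * np.exp(v / 33.1)
    return aq, bq


@njit(cache=True)
def _all_rates(v, vt, tau_km):
    am, bm = rates_m(v, vt)
    ah, bh = rates_h(v, vt)
    an, bn = rates_n(v, vt)
    ap, bp = rates_p(v, tau_km)
    aq, bq = rates_q(v)
    return am, bm, ah, bh, an, bn, ap, bp, aq, bq


@njit(cache=True)
def _all_rate_derivs(v, vt, tau_km):
    """Voltage derivatives of all rate functions, central differences."""
    h = 1e-3
    up = _all_rates(v + h, vt, tau_km)
    dn = _all_rates(v - h, vt, tau_km)
    out = np.empty(10)
    for k in range(10):
        out[k] = (up[k] - dn[k]) / (2.0 * h)
    return out


@njit(cache=True)
def sigmoid_nmda(v, c, rho):
    return 1.0 / (1.0 + c * np.exp(-rho * v))


@njit(cache=True)
def sigmoid_nmda_deriv(v, c, rho):
    s = sigmoid_nmda(v, c, rho)
    return rho * s * (1.0 - s)


# ---------------------------------------------------------------------------
# Hines tree solver: compartments ordered so parent[i] < i

@njit(cache=True)
def _hines_factor(d, e, f, parent):
    """In-place elimination of the tree system; returns multipliers.

    d: diagonal (modified in place), e[i]: entry (i, parent), f[i]: entry
    (parent, i).  After the call, ``coef[i] = f[i] / d[i]`` with d final.
    """
    n = d.shape[0]
    coef = np.zeros(n)
    for i in range(n - 1, 0, -1):
        p = parent[i]
        coef[i] = f[i] / d[i]
        d[p] -= coef[i] * e[i]
    return coef


@njit(cache=True)
def _hines_solve(d, e, coef, parent, b):
    """Solve with a factored tree system (single RHS, in place)."""
    n = d.shape[0]
    for i in range(n - 1, 0, -1):
        b[parent[i]] -= coef[i] * b[i]
    b[0] /= d[0]
    for i in range(1, n):
        b[i] = (b[i] - e[i] * b[parent[i]]) / d[i]


@njit(cache=True)
def _hines_solve_many(d, e, coef, parent, B):
    """Solve a factored tree system for B of shape (n_rhs, n_comp), in place."""
    n = d.shape[0]
    for i in range(n - 1, 0, -1):
        p = parent[i]
        c = coef[i]
        for r in range(B.shape[0]):
            B[r, p] -= c * B[r, i]
    d0 = d[0]
    for r in range(B.shape[0]):
        B[r, 0] /= d0
    for i in range(1, n):
        p = parent[i]
        ei = e[i]
        di = d[i]
        for r in range(B.shape[0]):
            B[r, i] = (B[r, i] - ei * B[r, p]) / di


# ---------------------------------------------------------------------------
# main integrator

@njit(cache=True)
def run_core(
    # geometry / passive
    parent, gp_over_ci, gp_over_cp, inv_c, gl, el,
    # active conductances (per-ms units: density / c_m_eff)
    gna, gk, gkm, gih, ena, ek, ehcn, vt, tau_km, has_gating,
    # synapses
    e_comp, e_w, i_comp, i_w,
    gamma, c_nmda, rho_nmda, nmda_on, e_e, e_i,
    # double-exponential kinetics: per-step decay factors and peak norms
    dec_ar, dec_ad, dec_nr, dec_nd, dec_gr, dec_gd,
    inv_gmax_a, inv_gmax_n, inv_gmax_g,
    # events (sorted by step); syn id is global: [0, nE) exc, [nE, nE+nI) inh
    ev_step, ev_syn,
    # run control
    n_steps, dt, t0, i_inj, inj_comp,
    record_every, record_all, stop_on_spike, spike_lag_steps,
    chk_every,
    # sensitivity
    sens_on, sens_syn,
    # initial state
    v0, m0, h0, n0, p0, q0,
    s_ar0, s_ad0, s_nr0, s_nd0, s_gr0, s_gd0,
):
    n_comp = v0.shape[0]
    n_e = e_w.shape[0]
    n_i = i_w.shape[0]
    n_trk = sens_syn.shape[0] if sens_on else 0

    v = v0.copy()
    m = m0.copy(); hh = h0.copy(); nn = n0.copy(); pp = p0.copy(); qq = q0.copy()
    s_ar = s_ar0.copy(); s_ad = s_ad0.copy()
    s_nr = s_nr0.copy(); s_nd = s_nd0.copy()
    s_gr = s_gr0.copy(); s_gd = s_gd0.copy()

    # sensitivity state
    dv = np.zeros((n_trk, n_comp))
    dm = np.zeros((n_trk, n_comp)); dh = np.zeros((n_trk, n_comp))
    dn_ = np.zeros((n_trk, n_comp)); dp = np.zeros((n_trk, n_comp))
    dq = np.zeros((n_trk, n_comp))

    # recording buffers
    n_rec = n_steps // record_every + 1
    rec_t = np.empty(n_rec)
    rec_vs = np.empty(n_rec)
    rec_va = np.empty((n_rec if record_all else 0, n_comp))
    rec_dvs = np.empty((n_rec if sens_on else 0, n_trk))
    rec_t[0] = t0
    rec_vs[0] = v[0]
    if record_all:
        rec_va[0] = v
    if sens_on:
        for r in range(n_trk):
            rec_dvs[0, r] = dv[r, 0]
    i_rec = 1

    # checkpoints
    n_chk = (n_steps // chk_every + 1) if chk_every > 0 else 0
    chk_t = np.empty(n_chk)
    chk_v = np.empty((n_chk, n_comp))
    chk_m = np.empty((n_chk, n_comp)); chk_h = np.empty((n_chk, n_comp))
    chk_n = np.empty((n_chk, n_comp)); chk_p = np.empty((n_chk, n_comp))
    chk_q = np.empty((n_chk, n_comp))
    chk_sar = np.empty((n_chk, n_e)); chk_sad = np.empty((n_chk, n_e))
    chk_snr = np.empty((n_chk, n_e)); chk_snd = np.empty((n_chk, n_e))
    chk_sgr = np.empty((n_chk, n_i)); chk_sgd = np.empty((n_chk, n_i))
    i_chk = 0
    if chk_every > 0:
        chk_t[0] = t0
        chk_v[0] = v; chk_m[0] = m; chk_h[0] = hh; chk_n[0] = nn
        chk_p[0] = pp; chk_q[0] = qq
        chk_sar[0] = s_ar; chk_sad[0] = s_ad
        chk_snr[0] = s_nr; chk_snd[0] = s_nd
        chk_sgr[0] = s_gr; chk_sgd[0] = s_gd
        i_chk = 1

    # spike bookkeeping
    max_spk = 4096
    cross_times = np.empty(max_spk)
    n_spk = 0
    lag = spike_lag_steps
    vbuf = np.empty((lag + 1, n_comp))
    vbuf[0] = v
    v_at_lag = np.zeros((max_spk if lag > 0 else 1, n_comp))

    # scratch
    d_diag = np.empty(n_comp)
    e_off = np.empty(n_comp)
    f_off = np.empty(n_comp)
    rhs = np.empty(n_comp)
    wa = np.empty(n_comp)   # AMPA-weighted conductance accumulator (uS)
    wn = np.empty(n_comp)   # NMDA-weighted (pre-sigmoid) accumulator (uS)
    wg = np.empty(n_comp)   # GABA accumulator (uS)

    for i in range(n_comp):
        e_off[i] = -dt * gp_over_ci[i]
        f_off[i] = -dt * gp_over_cp[i]

    ev_ptr = 0
    n_ev = ev_step.shape[0]
    step_stop = n_steps
    unstable_at = -1.0

    for step in range(n_steps):
        t_new = t0 + (step + 1) * dt

        # --- synaptic kinetics: exact decay, then event increments
        for j in range(n_e):
            s_ar[j] *= dec_ar; s_ad[j] *= dec_ad
            s_nr[j] *= dec_nr; s_nd[j] *= dec_nd
        for j in range(n_i):
            s_gr[j] *= dec_gr; s_gd[j] *= dec_gd
        while ev_ptr < n_ev and ev_step[ev_ptr] == step:
            sj = ev_syn[ev_ptr]
            if sj < n_e:
                s_ar[sj] += inv_gmax_a; s_ad[sj] += inv_gmax_a
                s_nr[sj] += inv_gmax_n; s_nd[sj] += inv_gmax_n
            else:
                k = sj - n_e
                s_gr[k] += inv_gmax_g; s_gd[k] += inv_gmax_g
            ev_ptr += 1

        # --- accumulate per-compartment synaptic conductances (uS)
        for i in range(n_comp):
            wa[i] = 0.0; wn[i] = 0.0; wg[i] = 0.0
        inv_g1 = 1.0 / (1.0 + gamma)
        for j in range(n_e):
            c = e_comp[j]
            ga = s_ad[j] - s_ar[j]
            gn = s_nd[j] - s_nr[j]
            wa[c] += e_w[j] * ga * inv_g1
            wn[c] += e_w[j] * gn * gamma * inv_g1
        for j in range(n_i):
            c = i_comp[j]
            wg[c] += i_w[j] * (s_gd[j] - s_gr[j])

        # --- gating update (staggered: voltage-stale, implicit in x)
        for i in range(n_comp):
            if has_gating[i]:
                am, bm, ah, bh, an, bn, ap, bp, aq, bq = _all_rates(v[i], vt, tau_km)
                m[i] = (m[i] + dt * am) / (1.0 + dt * (am + bm))
                hh[i] = (hh[i] + dt * ah) / (1.0 + dt * (ah + bh))
                nn[i] = (nn[i] + dt * an) / (1.0 + dt * (an + bn))
                pp[i] = (pp[i] + dt * ap) / (1.0 + dt * (ap + bp))
                qq[i] = (qq[i] + dt * aq) / (1.0 + dt * (aq + bq))

        # --- voltage system (conductance coefficients frozen at current state)
        for i in range(n_comp):
            sn = sigmoid_nmda(v[i], c_nmda, rho_nmda) if nmda_on else 1.0
            ge = (wa[i] + wn[i] * sn) * inv_c[i]      # ms^-1
            gi_ = wg[i] * inv_c[i]
            gact_na = gna[i] * m[i] ** 3 * hh[i]
            gact_k = gk[i] * nn[i] ** 4
            gact_km = gkm[i] * pp[i]
            gact_ih = gih[i] * qq[i]
            a_i = gl[i] + ge + gi_ + gact_na + gact_k + gact_km + gact_ih
            b_i = (gl[i] * el + ge * e_e + gi_ * e_i + gact_na * ena
                   + gact_k * ek + gact_km * ek + gact_ih * ehcn)
            if i == inj_comp:
                b_i += i_inj[step] * inv_c[i]
            # axial diagonal
            ax = gp_over_ci[i]
            d_diag[i] = 1.0 + dt * (a_i + ax)
            rhs[i] = v[i] + dt * b_i
        # children contribute to parent diagonals
        for i in range(1, n_comp):
            d_diag[parent[i]] += dt * gp_over_cp[i]

        coef = _hines_factor(d_diag, e_off, f_off, parent)
        _hines_solve(d_diag, e_off, coef, parent, rhs)
        v_old_soma = v[0]
        v_new = rhs

        # --- sensitivity update (coefficients at updated forward state)
        if sens_on and n_trk > 0:
            sd = np.empty(n_comp)
            # shared diagonal
            for i in range(n_comp):
                if nmda_on:
                    sn = sigmoid_nmda(v_new[i], c_nmda, rho_nmda)
                    snp = sigmoid_nmda_deriv(v_new[i], c_nmda, rho_nmda)
                else:
                    sn = 1.0; snp = 0.0
                ge_jac = (wa[i] + wn[i] * (sn + snp * (v_new[i] - e_e))) * inv_c[i]
                gi_ = wg[i] * inv_c[i]
                a_i = (gl[i] + ge_jac + gi_
                       + gna[i] * m[i] ** 3 * hh[i] + gk[i] * nn[i] ** 4
                       + gkm[i] * pp[i] + gih[i] * qq[i])
                sd[i] = 1.0 + dt * (a_i + gp_over_ci[i])
            for i in range(1, n_comp):
                sd[parent[i]] += dt * gp_over_cp[i]
            scoef = _hines_factor(sd, e_off, f_off, parent)

            B = np.empty((n_trk, n_comp))
            for r in range(n_trk):
                sj = sens_syn[r]
                for i in range(n_comp):
                    B[r, i] = dv[r, i]
                # gating sensitivities (staggered, stale dv)
                for i in range(n_comp):
                    if has_gating[i]:
                        am, bm, ah, bh, an, bn, ap, bp, aq, bq = _all_rates(
                            v_new[i], vt, tau_km)
                        der = _all_rate_derivs(v_new[i], vt, tau_km)
                        dvi = dv[r, i]
                        dm[r, i] = (dm[r, i] + dt * (der[0] * (1.0 - m[i]) - der[1] * m[i]) * dvi) / (1.0 + dt * (am + bm))
                        dh[r, i] = (dh[r, i] + dt * (der[2] * (1.0 - hh[i]) - der[3] * hh[i]) * dvi) / (1.0 + dt * (ah + bh))
                        dn_[r, i] = (dn_[r, i] + dt * (der[4] * (1.0 - nn[i]) - der[5] * nn[i]) * dvi) / (1.0 + dt * (an + bn))
                        dp[r, i] = (dp[r, i] + dt * (der[6] * (1.0 - pp[i]) - der[7] * pp[i]) * dvi) / (1.0 + dt * (ap + bp))
                        dq[r, i] = (dq[r, i] + dt * (der[8] * (1.0 - qq[i]) - der[9] * qq[i]) * dvi) / (1.0 + dt * (aq + bq))
                        # gating coupling into the voltage equation
                        cpl = (3.0 * gna[i] * m[i] ** 2 * hh[i] * (v_new[i] - ena) * dm[r, i]
                               + gna[i] * m[i] ** 3 * (v_new[i] - ena) * dh[r, i]
                               + 4.0 * gk[i] * nn[i] ** 3 * (v_new[i] - ek) * dn_[r, i]
                               + gkm[i] * (v_new[i] - ek) * dp[r, i]
                               + gih[i] * (v_new[i] - ehcn) * dq[r, i])
                        B[r, i] -= dt * cpl
                # direct synaptic drive
                if sj < n_e:
                    c = e_comp[sj]
                    ga = s_ad[sj] - s_ar[sj]
                    gn = s_nd[sj] - s_nr[sj]
                    sn = sigmoid_nmda(v_new[c], c_nmda, rho_nmda) if nmda_on else 1.0
                    drive = (ga * inv_g1 + gn * gamma * inv_g1 * sn) * (v_new[c] - e_e)
                    B[r, c] -= dt * drive * inv_c[c]
                else:
                    k = sj - n_e
                    c = i_comp[k]
                    gg = s_gd[k] - s_gr[k]
                    B[r, c] -= dt * gg * (v_new[c] - e_i) * inv_c[c]
            _hines_solve_many(sd, e_off, scoef, parent, B)
            for r in range(n_trk):
                for i in range(n_comp):
                    dv[r, i] = B[r, i]

        # --- commit voltage
        for i in range(n_comp):
            v[i] = v_new[i]

        if np.isnan(v[0]) or np.isinf(v[0]):
            unstable_at = t_new
            step_stop = step + 1
            break

        # ring buffer of full voltage (for lagged spike-state readout)
        vbuf[(step + 1) % (lag + 1)] = v

        # --- somatic spike: upward crossing of 0 mV
        spiked = v[0] >= 0.0 and v_old_soma < 0.0
        if spiked and n_spk < max_spk:
            frac = (0.0 - v_old_soma) / (v[0] - v_old_soma)
            cross_times[n_spk] = t0 + (step + frac) * dt
            if lag > 0:
                src = max(step + 1 - lag, 0)
                v_at_lag[n_spk] = vbuf[src % (lag + 1)]
            n_spk += 1

        # --- recording
        if (step + 1) % record_every == 0 and i_rec < n_rec:
            rec_t[i_rec] = t_new
            rec_vs[i_rec] = v[0]
            if record_all:
                rec_va[i_rec] = v
            if sens_on:
                for r in range(n_trk):
                    rec_dvs[i_rec, r] = dv[r, 0]
            i_rec += 1

        # --- checkpoints
        if chk_every > 0 and (step + 1) % chk_every == 0 and i_chk < n_chk:
            chk_t[i_chk] = t_new
            chk_v[i_chk] = v; chk_m[i_chk] = m; chk_h[i_chk] = hh
            chk_n[i_chk] = nn; chk_p[i_chk] = pp; chk_q[i_chk] = qq
            chk_sar[i_chk] = s_ar; chk_sad[i_chk] = s_ad
            chk_snr[i_chk] = s_nr; chk_snd[i_chk] = s_nd
            chk_sgr[i_chk] = s_gr; chk_sgd[i_chk] = s_gd
            i_chk += 1

        if spiked and stop_on_spike:
            step_stop = step + 1
            break

    rec_out = (rec_t[:i_rec], rec_vs[:i_rec],
               rec_va[:i_rec] if record_all else rec_va,
               rec_dvs[:i_rec] if sens_on else rec_dvs)
    spk_out = (cross_times[:n_spk],
               v_at_lag[:n_spk] if lag > 0 else v_at_lag)
    chk_out = (chk_t[:i_chk], chk_v[:i_chk], chk_m[:i_chk], chk_h[:i_chk],
               chk_n[:i_chk], chk_p[:i_chk], chk_q[:i_chk],
               chk_sar[:i_chk], chk_sad[:i_chk], chk_snr[:i_chk],
               chk_snd[:i_chk], chk_sgr[:i_chk], chk_sgd[:i_chk])
    fin_out = (v, m, hh, nn, pp, qq, s_ar, s_ad, s_nr, s_nd, s_gr, s_gd)
    return (rec_out, spk_out, chk_out, fin_out, dv, step_stop, unstable_at)
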