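"""Forward sensitivity analysis: ∂v/∂w integrated alongside the model.

The sensitivity (variational) system is obtained by differentiating the
membrane equations with respect to each synaptic weight.  Its solution
delta_v[j, i] = dv_i/dw_j (mV/uS) is integrated in parallel with the forward
state using the same implicit scheme and shared tree factorization.  The
spike-window protocol re-simulates a 150 ms window before each somatic spike
from a stored checkpoint, with multiply-activated synapses duplicated into
single-spike dummy copies and the somatic action potential blocked, to obtain
a clean gradient and local-voltage record per synaptic activation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import _core
from .biophysics import (BiophysicsSpec, SimState, SpikeTrains, SynapseLayout,
                         TraceRecord, _assemble, double_exp_gmax, nmda_gate,
                         simulate)
from .morphology import Geometry

WINDOW_MS = 150.0
SYNC_WINDOW_MS = 100.0


class CheckpointError(RuntimeError):
    """Raised when a window replay has no usable state checkpoint."""


# ---------------------------------------------------------------------------
# dense reference right-hand side of the variational system

def sensitivity_rhs(state: SimState, sens: dict, layout: SynapseLayout,
                    spec: BiophysicsSpec, geom: Geometry,
                    track: np.ndarray) -> dict:
    """Time derivative of the sensitivity state, dense reference evaluation.

    ``sens`` holds arrays ``dv, dm, dh, dn, dp, dq`` of shape
    (n_tracked, n_comp); ``track`` lists the tracked global synapse ids
    (excitatory first, matching the layout ordering).  Returns the
    derivatives in the same structure.  Each row obeys

        d(dv)/dt = direct drive + J_vv * dv + gating coupling + G @ dv

    where the diagonal Jacobian includes the NMDA voltage-derivative term
    sigma_N'(v) (v - E_E) and the gating rows use the voltage derivatives of
    the opening/closing rates.
    """
    from .biophysics import _axial_operator

    asm = _assemble(geom, spec, layout)
    v = state.v
    n = geom.n_comp
    n_trk = len(track)
    n_e = layout.n_e

    # per-compartment synaptic conductance accumulators (weighted)
    wa = np.zeros(n); wn = np.zeros(n); wg = np.zeros(n)
    inv_g1 = 1.0 / (1.0 + spec.gamma)
    np.add.at(wa, asm["e_comp"], asm["e_w"] * (state.s_ad - state.s_ar) * inv_g1)
    np.add.at(wn, asm["e_comp"],
              asm["e_w"] * (state.s_nd - state.s_nr) * spec.gamma * inv_g1)
    np.add.at(wg, asm["i_comp"], asm["i_w"] * (state.s_gd - state.s_gr))
    if spec.nmda_on:
        sn = 1.0 / (1.0 + spec.c_nmda * np.exp(-spec.rho_nmda * v))
        snp = spec.rho_nmda * sn * (1.0 - sn)
    else:
        sn = np.ones(n); snp = np.zeros(n)
    inv_c = asm["inv_c"]

    rates = np.array([_core._all_rates(float(vi), spec.v_t, spec.tau_km)
                      for vi in v])           # (n, 10)
    drates = np.array([_core._all_rate_derivs(float(vi), spec.v_t, spec.tau_km)
                       for vi in v])          # (n, 10) of d(a)/dv, d(b)/dv
    am, bm, ah, bh, an, bn, ap_, bp, aq, bq = rates.T
    dam, dbm, dah, dbh, dan, dbn, dap, dbp, daq, dbq = drates.T

    gna, gk, gkm, gih = asm["gna"], asm["gk"], asm["gkm"], asm["gih"]
    # diagonal of dF_v/dv (excluding axial part)
    jvv = -(asm["gl"] + (wa + wn * sn) * inv_c + wn * snp * inv_c * (v - spec.e_e)
            + wg * inv_c + gna * state.m ** 3 * state.h + gk * state.n ** 4
            + gkm * state.p + gih * state.q)
    G = _axial_operator(geom, spec)

    dv = sens["dv"]
    out = {k: np.zeros((n_trk, n)) for k in ("dv", "dm", "dh", "dn", "dp", "dq")}
    for r, gid in enumerate(track):
        row = dv[r]
        ddv = jvv * row + G @ row
        # gating coupling
        ddv += (-gna * (v - spec.e_na)
                * (3 * state.m ** 2 * state.h * sens["dm"][r]
                   + state.m ** 3 * sens["dh"][r])
                - gk * (v - spec.e_k) * 4 * state.n ** 3 * sens["dn"][r]
                - gkm * (v - spec.e_k) * sens["dp"][r]
                - gih * (v - spec.e_hcn) * sens["dq"][r])
        # direct synaptic-drive term for the tracked synapse's own compartment
        if gid < n_e:
            c = asm["e_comp"][gid]
            drive = ((state.s_ad[gid] - state.s_ar[gid]) * inv_g1
                     + (state.s_nd[gid] - state.s_nr[gid]) * spec.gamma
                     * inv_g1 * sn[c])
            ddv[c] += -drive * inv_c[c] * (v[c] - spec.e_e)
        else:
            k = gid - n_e
            c = asm["i_comp"][k]
            drive = state.s_gd[k] - state.s_gr[k]
            ddv[c] += -drive * inv_c[c] * (v[c] - spec.e_i)
        out["dv"][r] = ddv
        out["dm"][r] = (dam * (1 - state.m) - dbm * state.m) * row \
            - (am + bm) * sens["dm"][r]
        out["dh"][r] = (dah * (1 - state.h) - dbh * state.h) * row \
            - (ah + bh) * sens["dh"][r]
        out["dn"][r] = (dan * (1 - state.n) - dbn * state.n) * row \
            - (an + bn) * sens["dn"][r]
        out["dp"][r] = (dap * (1 - state.p) - dbp * state.p) * row \
            - (ap_ + bp) * sens["dp"][r]
        out["dq"][r] = (daq * (1 - state.q) - dbq * state.q) * row \
            - (aq + bq) * sens["dq"][r]
    return out


def simulate_with_sensitivities(geom: Geometry, spec: BiophysicsSpec,
                                layout: SynapseLayout,
                                trains: SpikeTrains | None, horizon: float,
                                active_set: np.ndarray, **kwargs) -> TraceRecord:
    """Forward + variational integration; records dv_soma/dw per tracked synapse.

    ``active_set`` holds global synapse ids (excitatory block first).  The
    returned record's ``dv_soma`` has one column per tracked synapse in
    mV/uS, sampled at the recording cadence.
    """
    active_set = np.asarray(active_set, dtype=np.int64)
    if len(active_set) == 0:
        raise ValueError("active_set must be nonempty")
    if np.any(active_set < 0) or np.any(active_set >= layout.n_syn):
        raise ValueError("active_set contains out-of-range synapse ids")
    return simulate(geom, spec, layout, trains, horizon,
                    sens_syn=active_set, **kwargs)


# ---------------------------------------------------------------------------
# spike-window gradient protocol

def _window_layout(layout: SynapseLayout, trains: SpikeTrains,
                   t_lo: float, t_hi: float):
    """Augment the layout with single-spike dummy copies of in-window events.

    Returns (new layout, new trains, dummy global ids in the new layout,
    DataFrame of dummy descriptors, index mapping of original E/I blocks into
    the new E/I blocks).  Original synapses keep their out-of-window spikes;
    every event with spike time in (t_lo, t_hi] moves to a fresh dummy copy
    at the same compartment with the same weight.
    """
    e_orig = np.flatnonzero(layout.is_exc)
    i_orig = np.flatnonzero(~layout.is_exc)
    comp_new, exc_new, w_new, times_new = [], [], [], []
    dummy_desc = []  # (orig synapse id, spike time)

    def add(orig_ids):
        for j in orig_ids:
            t = trains.times[j]
            in_win = (t > t_lo) & (t <= t_hi)
            comp_new.append(layout.comp[j]); exc_new.append(layout.is_exc[j])
            w_new.append(layout.weight[j]); times_new.append(t[~in_win])
            for tk in t[in_win]:
                comp_new.append(layout.comp[j]); exc_new.append(layout.is_exc[j])
                w_new.append(layout.weight[j]); times_new.append(np.array([tk]))
                dummy_desc.append((int(j), float(tk)))

    # E block first, then I block, preserving original order with dummies
    # interleaved right after their parent synapse
    add(e_orig); add(i_orig)
    new_layout = SynapseLayout(np.array(comp_new), np.array(exc_new),
                               np.array(w_new))
    new_trains = SpikeTrains(times_new)
    exc_arr = np.array(exc_new)
    # position of each new synapse within its E/I block
    block_pos = np.where(exc_arr, np.cumsum(exc_arr) - 1,
                         np.cumsum(~exc_arr) - 1)
    n_syn_new = len(comp_new)
    is_dummy = np.zeros(n_syn_new, bool)
    # originals are the first entry of each (original, dummies...) cluster
    k = 0
    orig_block_pos = {}
    for j in list(e_orig) + list(i_orig):
        orig_block_pos[int(j)] = int(block_pos[k])
        n_d = int(((trains.times[j] > t_lo) & (trains.times[j] <= t_hi)).sum())
        is_dummy[k + 1:k + 1 + n_d] = True
        k += 1 + n_d
    dummy_global = np.flatnonzero(is_dummy)
    n_e_new = int(exc_arr.sum())
    dummy_gid = np.where(exc_arr[dummy_global],
                         block_pos[dummy_global],
                         n_e_new + block_pos[dummy_global])
    desc = pd.DataFrame(dummy_desc, columns=["syn", "t_pre"])
    return new_layout, new_trains, dummy_gid.astype(np.int64), desc, \
        orig_block_pos, block_pos, is_dummy


def _map_checkpoint_state(chk: dict, idx: int, layout_old: SynapseLayout,
                          layout_new: SynapseLayout, orig_block_pos: dict,
                          t_c: float) -> SimState:
    """Build an initial state for the augmented layout from a checkpoint."""
    n_e_new, n_i_new = layout_new.n_e, layout_new.n_i
    arrs = {}
    for name in ("s_ar", "s_ad", "s_nr", "s_nd"):
        new = np.zeros(n_e_new)
        old = chk[name][idx]
        for j in np.flatnonzero(layout_old.is_exc):
            # old E-block position
            pos_old = int(layout_old.is_exc[:j].sum())
            new[orig_block_pos[int(j)]] = old[pos_old]
        arrs[name] = new
    for name in ("s_gr", "s_gd"):
        new = np.zeros(n_i_new)
        old = chk[name][idx]
        for j in np.flatnonzero(~layout_old.is_exc):
            pos_old = int((~layout_old.is_exc[:j]).sum())
            new[orig_block_pos[int(j)]] = old[pos_old]
        arrs[name] = new
    return SimState(t_c, chk["v"][idx].copy(), chk["m"][idx].copy(),
                    chk["h"][idx].copy(), chk["n"][idx].copy(),
                    chk["p"][idx].copy(), chk["q"][idx].copy(),
                    arrs["s_ar"], arrs["s_ad"], arrs["s_nr"], arrs["s_nd"],
                    arrs["s_gr"], arrs["s_gd"])


def spike_window_gradient(run: TraceRecord, spike_time: float, geom: Geometry,
                          spec: BiophysicsSpec, layout: SynapseLayout,
                          trains: SpikeTrains, window: float = WINDOW_MS,
                          dt: float = 0.025) -> pd.DataFrame:
    """Gradient and local-voltage record for one isolated somatic spike.

    Re-simulates the ``window`` ms before ``spike_time`` (the reported spike
    time, 2 ms before the 0 mV crossing) from the nearest stored checkpoint,
    with multiply-activated synapses duplicated into dummy single-spike
    copies and the fast axo-somatic Na+/K+ conductances set to zero so the
    terminal action potential is blocked.  Returns one row per in-window
    synaptic activation with columns: syn, comp, branch, domain, is_exc,
    weight, dt (ms before the spike), v_dend (mV at the spike), g
    (dv_soma/dw, mV/uS), kin (own kinetic activation at the spike),
    e_sync/i_sync (summed same-branch synchronous E/I drive within 100 ms).

    Raises :class:`CheckpointError` if no checkpoint at or before the window
    start exists.
    """
    if run.checkpoints is None:
        raise CheckpointError("run has no checkpoints; re-run with checkpoint_dt")
    t_w = spike_time - window
    chk_t = run.checkpoints["t"]
    # initial condition: allow starting from rest at t=0 if the window
    # reaches before the first checkpoint
    use_rest = t_w <= 0
    if not use_rest:
        cand = np.flatnonzero(chk_t <= t_w + 1e-9)
        if len(cand) == 0:
            raise CheckpointError(
                f"no checkpoint at or before window start {t_w:.1f} ms")
        idx = int(cand[-1])
        t_c = float(chk_t[idx])
    else:
        t_c = 0.0
    # reject windows contaminated by an earlier spike
    cross = spike_time + 2.0
    earlier = run.cross_times[(run.cross_times < cross - 1e-9)
                              & (run.cross_times >= cross - window)]
    if len(earlier):
        raise ValueError("another somatic spike inside the window")

    lay_w, trains_w, dummy_gid, desc, orig_pos, _, _ = _window_layout(
        layout, trains, t_w, spike_time)
    if len(dummy_gid) == 0:
        return _empty_window_frame()

    if use_rest:
        from .biophysics import resting_state
        init = resting_state(geom, spec, lay_w)
    else:
        init = _map_checkpoint_state(run.checkpoints, idx, layout, lay_w,
                                     orig_pos, t_c)
    horizon = spike_time - t_c
    n_steps = int(round(horizon / dt))
    horizon = n_steps * dt
    rec = simulate(geom, spec, lay_w, trains_w, horizon, ap_block=True,
                   init_state=init, t0=t_c, dt=dt, record_dt=horizon,
                   sens_syn=dummy_gid)
    g = rec._dv_final[:, geom.soma_index]          # (n_dummy,)
    v_final = rec.final_state.v

    syn = desc["syn"].to_numpy()
    t_pre = desc["t_pre"].to_numpy()
    comp = layout.comp[syn]
    dts = spike_time - t_pre
    # own kinetic activation (slow component) at the spike, from dummy states
    n_e_new = lay_w.n_e
    kin = np.empty(len(syn))
    inv_n = 1.0 / double_exp_gmax(spec.tau_nr, spec.tau_nd)
    inv_g = 1.0 / double_exp_gmax(spec.tau_gr, spec.tau_gd)
    fs = rec.final_state
    for r, gid in enumerate(dummy_gid):
        if gid < n_e_new:
            kin[r] = (fs.s_nd[gid] - fs.s_nr[gid]) * inv_n
        else:
            k = gid - n_e_new
            kin[r] = (fs.s_gd[k] - fs.s_gr[k]) * inv_g

    # same-branch synchronous drive within 100 ms before the spike
    branch = geom.branch_id[comp]
    is_exc = layout.is_exc[syn]
    w = layout.weight[syn]
    sync_mask = dts <= SYNC_WINDOW_MS
    e_sync = np.zeros(len(syn)); i_sync = np.zeros(len(syn))
    for r in range(len(syn)):
        same = (branch == branch[r]) & sync_mask
        same[r] = False
        e_sync[r] = w[same & is_exc].sum()
        i_sync[r] = w[same & ~is_exc].sum()

    return pd.DataFrame({
        "syn": syn, "comp": comp, "branch": branch,
        "domain": geom.domain[comp], "is_exc": is_exc, "weight": w,
        "dt": dts, "v_dend": v_final[comp], "g": g, "kin": kin,
        "e_sync": e_sync, "i_sync": i_sync,
    })


def _empty_window_frame() -> pd.DataFrame:
    return pd.DataFrame({k: pd.Series(dtype=t) for k, t in [
        ("syn", "int64"), ("comp", "int64"), ("branch", "int64"),
        ("domain", "int64"), ("is_exc", "bool"), ("weight", "float64"),
        ("dt", "float64"), ("v_dend", "float64"), ("g", "float64"),
        ("kin", "float64"), ("e_sync", "float64"), ("i_sync", "float64")]})
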