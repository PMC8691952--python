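"""Plasticity-kernel pipeline: campaigns, spike-triggered averages, fits.

The kernel K(dt, v_dend) approximates a synapse's gradient dv_soma/dw at a
somatic spike from two locally available quantities: how long before the
spike the synapse was activated (dt) and the local dendritic voltage at the
spike.  Kernels are fitted per stratum (basal/apical x excitatory/inhibitory)
as polynomial surfaces over binned spike-triggered averages of window
gradients collected under random Poisson input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial import polynomial as npoly

from .biophysics import BiophysicsSpec, SpikeTrains, SynapseLayout, simulate
from .morphology import Geometry, DOMAIN_BASAL, DOMAIN_APICAL, DOMAIN_NAMES
from .variational import WINDOW_MS, spike_window_gradient

DT_MAX = 100.0     # ms; kernel temporal domain (0, 100]
V_MIN, V_MAX = -80.0, 0.0
DT_BIN = 1.0
V_BIN = 1.0
DEGREE_2D = 8
DEGREE_1D = 10

STRATA = [(DOMAIN_BASAL, True), (DOMAIN_BASAL, False),
          (DOMAIN_APICAL, True), (DOMAIN_APICAL, False)]


def stratum_name(domain: int, is_exc: bool) -> str:
    return f"{DOMAIN_NAMES[domain]}_{'E' if is_exc else 'I'}"


class CampaignError(RuntimeError):
    pass


class FitError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# random-input campaign

def perturbed_weights(layout: SynapseLayout, seed: int,
                      passive_e_scale: float = 1.0) -> SynapseLayout:
    """Redraw weights uniformly on [0.4, 1.0] nS (E optionally rescaled)."""
    rng = np.random.default_rng(seed)
    w = rng.uniform(0.4e-3, 1.0e-3, layout.n_syn)
    w[layout.is_exc] *= passive_e_scale
    return SynapseLayout(layout.comp.copy(), layout.is_exc.copy(), w)


def random_input_campaign(geom: Geometry, spec: BiophysicsSpec,
                          layout: SynapseLayout, n_runs: int = 5000,
                          run_length: float = 10_000.0, seed: int = 0,
                          dt: float = 0.025,
                          window: float = WINDOW_MS) -> pd.DataFrame:
    """Collect window gradients from random constant-rate Poisson runs.

    Each run draws per-synapse rates from lognormal(0, 1) Hz and fresh
    weights spanning ~0.4-1 nS (excitatory weights divided by 5 in the
    passive variant).  All isolated somatic spikes (no other spike in the
    preceding ``window`` ms and a full window inside the run) contribute one
    record per in-window synaptic activation.
    """
    rng = np.random.default_rng(seed)
    e_scale = 0.2 if spec.mode == "passive" else 1.0
    frames = []
    n_spikes_total = 0
    for run_i in range(n_runs):
        lay = perturbed_weights(layout, rng.integers(2**31),
                                passive_e_scale=e_scale)
        rates = rng.lognormal(0.0, 1.0, lay.n_syn)   # Hz
        trains = SpikeTrains([
            np.sort(rng.uniform(0.0, run_length,
                                rng.poisson(r * run_length / 1000.0)))
            for r in rates])
        rec = simulate(geom, spec, lay, trains, run_length, dt=dt,
                       record_dt=run_length, checkpoint_dt=10.0)
        n_spikes_total += rec.n_spikes
        for k, t_sp in enumerate(rec.spike_times):
            cross = rec.cross_times[k]
            if cross - window - 2.0 < 0:
                continue
            prev = rec.cross_times[(rec.cross_times < cross - 1e-9)
                                   & (rec.cross_times >= cross - window)]
            if len(prev):
                continue
            df = spike_window_gradient(rec, t_sp, geom, spec, lay, trains,
                                       window=window, dt=dt)
            if len(df):
                df["run"] = run_i
                df["spike"] = k
                frames.append(df)
    if n_spikes_total == 0:
        raise CampaignError(
            "campaign produced no somatic spikes; increase synaptic weights "
            "or input rates")
    if not frames:
        raise CampaignError(
            f"{n_spikes_total} spikes but none isolated with a full window")
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# spike-triggered average grids

@dataclass
class STAGrid:
    """Binned spike-triggered average of window gradients for one stratum.

    Bins: dt in (0, 100] ms at 1 ms, v_dend in [-80, 0] mV at 1 mV.  The
    temporal-only variant collapses the voltage axis.
    """

    domain: int
    is_exc: bool
    mean_g: np.ndarray       # (n_dt, n_v) or (n_dt,) — nan where empty
    count: np.ndarray
    temporal_only: bool = False

    @property
    def dt_centers(self) -> np.ndarray:
        return np.arange(DT_BIN / 2, DT_MAX, DT_BIN)

    @property
    def v_centers(self) -> np.ndarray:
        return np.arange(V_MIN + V_BIN / 2, V_MAX, V_BIN)

    @property
    def occupied(self) -> np.ndarray:
        return self.count > 0


def spike_triggered_average(records: pd.DataFrame, domain: int, is_exc: bool,
                            temporal_only: bool = False) -> STAGrid:
    """Per-bin mean of g over a stratum's records."""
    df = records[(records["domain"] == domain)
                 & (records["is_exc"] == is_exc)
                 & (records["dt"] > 0) & (records["dt"] <= DT_MAX)]
    if not temporal_only:
        df = df[(df["v_dend"] >= V_MIN) & (df["v_dend"] <= V_MAX)]
    if len(df) == 0:
        raise ValueError(f"no records for stratum "
                         f"{stratum_name(domain, is_exc)}")
    n_dt = int(round(DT_MAX / DT_BIN))
    i_dt = np.clip(((df["dt"].to_numpy() - 1e-12) // DT_BIN).astype(int),
                   0, n_dt - 1)
    if temporal_only:
        count = np.bincount(i_dt, minlength=n_dt).astype(float)
        s = np.bincount(i_dt, weights=df["g"].to_numpy(), minlength=n_dt)
        mean = np.divide(s, count, out=np.full(n_dt, np.nan),
                         where=count > 0)
        return STAGrid(domain, is_exc, mean, count, temporal_only=True)
    n_v = int(round((V_MAX - V_MIN) / V_BIN))
    i_v = np.clip(((df["v_dend"].to_numpy() - V_MIN) // V_BIN).astype(int),
                  0, n_v - 1)
    flat = i_dt * n_v + i_v
    count = np.bincount(flat, minlength=n_dt * n_v).astype(float)
    s = np.bincount(flat, weights=df["g"].to_numpy(), minlength=n_dt * n_v)
    mean = np.divide(s, count, out=np.full(n_dt * n_v, np.nan),
                     where=count > 0)
    return STAGrid(domain, is_exc, mean.reshape(n_dt, n_v),
                   count.reshape(n_dt, n_v))


# ---------------------------------------------------------------------------
# polynomial kernels

@dataclass
class PlasticityKernel:
    """Polynomial plasticity kernel for one stratum.

    ``coef[i, j]`` multiplies dt^i * v^j on normalized coordinates; the sign
    clamp (E >= 0, I <= 0) and the domain cutoff (0 outside dt in (0, 100],
    v in [-80, 0]) are applied at evaluation.  Output is mV/uS.
    """

    domain: int
    is_exc: bool
    coef: np.ndarray
    temporal_only: bool = False
    r2_holdout: float | None = None

    def _norm(self, dts, vs):
        # map to [-1, 1] for numerical conditioning
        x = 2.0 * np.asarray(dts, float) / DT_MAX - 1.0
        y = (2.0 * (np.asarray(vs, float) - V_MIN) / (V_MAX - V_MIN) - 1.0)
        return x, y

    def __call__(self, dts, vs=None):
        return evaluate_kernel(self, dts, vs)

    def to_dict(self) -> dict:
        return dict(domain=int(self.domain), is_exc=bool(self.is_exc),
                    coef=self.coef.tolist(),
                    temporal_only=bool(self.temporal_only),
                    r2_holdout=self.r2_holdout)

    @classmethod
    def from_dict(cls, d: dict) -> "PlasticityKernel":
        return cls(domain=d["domain"], is_exc=d["is_exc"],
                   coef=np.array(d["coef"]),
                   temporal_only=d.get("temporal_only", False),
                   r2_holdout=d.get("r2_holdout"))


def evaluate_kernel(kern: PlasticityKernel, dts, vs=None):
    """Kernel value (mV/uS); 0 outside the valid domain; sign-clamped."""
    dts = np.asarray(dts, dtype=float)
    scalar = dts.ndim == 0
    dts = np.atleast_1d(dts)
    inside = (dts > 0) & (dts <= DT_MAX)
    if kern.temporal_only:
        x = 2.0 * dts / DT_MAX - 1.0
        val = npoly.polyval(x, kern.coef)
    else:
        if vs is None:
            raise ValueError("2-D kernel requires v_dend values")
        vs = np.atleast_1d(np.asarray(vs, dtype=float))
        vs_b = np.broadcast_to(vs, dts.shape)
        inside = inside & (vs_b >= V_MIN) & (vs_b <= V_MAX)
        x, y = kern._norm(dts, vs_b)
        val = npoly.polyval2d(x, y, kern.coef)
    val = np.where(inside, val, 0.0)
    val = np.maximum(val, 0.0) if kern.is_exc else np.minimum(val, 0.0)
    return float(val[0]) if scalar else val


def _pad_grid(grid: STAGrid):
    """Occupied bin coordinates/values/weights plus zero padding rows.

    Boundaries at v = 0 mV, v = -80 mV, and t = -1 ms are padded with zeros
    (weight 1) so the polynomial interpolates smoothly to the edges.
    """
    if grid.temporal_only:
        occ = grid.occupied
        dts = grid.dt_centers[occ]
        vals = grid.mean_g[occ]
        wts = grid.count[occ]
        pad_t = np.array([-1.0])
        return (np.concatenate([dts, pad_t]), None,
                np.concatenate([vals, np.zeros(1)]),
                np.concatenate([wts, np.ones(1)]))
    occ = grid.occupied
    ii, jj = np.nonzero(occ)
    dts = grid.dt_centers[ii]
    vs = grid.v_centers[jj]
    vals = grid.mean_g[occ]
    wts = grid.count[occ]
    # padding: full rows at t=-1 over all v; full columns at v=0 and v=-80
    vpad = grid.v_centers
    tpad = grid.dt_centers
    pd_dt = np.concatenate([np.full(len(vpad), -1.0), tpad, tpad])
    pd_v = np.concatenate([vpad, np.full(len(tpad), V_MAX),
                           np.full(len(tpad), V_MIN)])
    dts = np.concatenate([dts, pd_dt])
    vs = np.concatenate([vs, pd_v])
    vals = np.concatenate([vals, np.zeros(len(pd_dt))])
    wts = np.concatenate([wts, np.ones(len(pd_dt))])
    return dts, vs, vals, wts


def fit_kernel(grid: STAGrid, holdout: float = 0.25, seed: int = 0) -> PlasticityKernel:
    """Weighted least-squares polynomial fit of an STA grid.

    Occupied bins are weighted by their counts; stated boundaries are
    zero-padded with weight 1.  A random ``holdout`` fraction of the
    occupied bins is excluded from the fit and used for the reported
    count-weighted R^2.  The sign clamp is applied at evaluation.
    """
    dts, vs, vals, wts = _pad_grid(grid)
    n_occ = int(grid.occupied.sum())
    if n_occ == 0:
        raise FitError("grid has no occupied bins")
    rng = np.random.default_rng(seed)
    # occupied bins come first in the padded arrays
    test = np.zeros(len(vals), bool)
    if holdout > 0 and n_occ >= 8:
        idx = rng.permutation(n_occ)[:max(1, int(round(holdout * n_occ)))]
        test[idx] = True
    train = ~test

    kern = PlasticityKernel(grid.domain, grid.is_exc, np.zeros(1),
                            temporal_only=grid.temporal_only)
    if grid.temporal_only:
        x = 2.0 * dts / DT_MAX - 1.0
        V = npoly.polyvander(x, DEGREE_1D)
        ncoef_shape = (DEGREE_1D + 1,)
    else:
        x, y = kern._norm(dts, vs)
        V = npoly.polyvander2d(x, y, [DEGREE_2D, DEGREE_2D])
        ncoef_shape = (DEGREE_2D + 1, DEGREE_2D + 1)
    if train.sum() < V.shape[1]:
        raise FitError(
            f"rank-deficient fit: {int(train.sum())} bins for "
            f"{V.shape[1]} coefficients")
    sw = np.sqrt(wts[train])
    coef, *_ = np.linalg.lstsq(V[train] * sw[:, None], vals[train] * sw,
                               rcond=None)
    kern.coef = coef.reshape(ncoef_shape)

    if test.any():
        if grid.temporal_only:
            pred = evaluate_kernel(kern, dts[test])
        else:
            pred = evaluate_kernel(kern, dts[test], vs[test])
        w = wts[test]
        mu = np.average(vals[test], weights=w)
        ss_res = np.average((vals[test] - pred) ** 2, weights=w)
        ss_tot = np.average((vals[test] - mu) ** 2, weights=w)
        kern.r2_holdout = float(1.0 - ss_res / ss_tot) if ss_tot > 0 else 1.0
    return kern


def fit_all_kernels(records: pd.DataFrame, temporal_only: bool = False,
                    holdout: float = 0.25, seed: int = 0) -> dict:
    """Kernels for every stratum present in the campaign records."""
    out = {}
    for domain, is_exc in STRATA:
        mask = (records["domain"] == domain) & (records["is_exc"] == is_exc)
        if mask.sum() == 0:
            continue
        grid = spike_triggered_average(records, domain, is_exc,
                                       temporal_only=temporal_only)
        out[(domain, is_exc)] = fit_kernel(grid, holdout=holdout, seed=seed)
    return out


def record_level_r2(records: pd.DataFrame, domain: int, is_exc: bool,
                    holdout: float = 0.25, seed: int = 0,
                    temporal_only: bool = False) -> float:
    """Held-out variance explained at the individual-record level.

    Fits the kernel on an STA grid built from 75% of the stratum's records
    and scores R^2 of the kernel's prediction of the raw held-out gradients.
    """
    df = records[(records["domain"] == domain)
                 & (records["is_exc"] == is_exc)
                 & (records["dt"] > 0) & (records["dt"] <= DT_MAX)]
    if len(df) < 20:
        raise FitError("too few records for record-level validation")
    rng = np.random.default_rng(seed)
    test = rng.random(len(df)) < holdout
    grid = spike_triggered_average(df[~test], domain, is_exc,
                                   temporal_only=temporal_only)
    kern = fit_kernel(grid, holdout=0.0, seed=seed)
    te = df[test]
    pred = evaluate_kernel(kern, te["dt"].to_numpy(),
                           None if temporal_only else te["v_dend"].to_numpy())
    g = te["g"].to_numpy()
    ss_res = np.mean((g - pred) ** 2)
    ss_tot = np.mean((g - g.mean()) ** 2)
    return float(1.0 - ss_res / ss_tot) if ss_tot > 0 else 1.0


def save_kernels(kernels: dict, path) -> None:
    payload = {stratum_name(d, e): k.to_dict() for (d, e), k in kernels.items()}
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_kernels(path) -> dict:
    with open(path) as fh:
        payload = json.load(fh)
    out = {}
    for k in payload.values():
        kern = PlasticityKernel.from_dict(k)
        out[(kern.domain, kern.is_exc)] = kern
    return out


# ---------------------------------------------------------------------------
# what does the local voltage encode?

def input_resistance(geom: Geometry, spec: BiophysicsSpec) -> np.ndarray:
    """Steady-state passive input resistance per compartment (MOhm)."""
    n = geom.n_comp
    gl_uS = spec.g_l * geom.area * 1e3          # mS/cm^2 * cm^2 -> uS
    if spec.spine_scaling:
        gl_uS = np.where(geom.dendritic_mask(), 2 * gl_uS, gl_uS)
    A = np.diag(gl_uS)
    for i in range(1, n):
        p = int(geom.parent[i])
        g = geom.g_pair[i]
        A[i, i] += g; A[p, p] += g
        A[i, p] -= g; A[p, i] -= g
    return np.diag(np.linalg.inv(A)).copy()     # mV/nA = MOhm


COVARIATES = ("r_in", "e_sync", "i_sync", "weight", "kin")


def local_voltage_regression(records: pd.DataFrame, geom: Geometry,
                             spec: BiophysicsSpec, holdout: float = 0.25,
                             seed: int = 0) -> pd.DataFrame:
    """Semipartial correlations of local covariates with v_dend at the spike.

    For each covariate, a linear model of v_dend on the remaining covariates
    is fitted on a 75% split; the semipartial correlation is the Pearson
    correlation between the covariate and the held-out residual of that
    reduced model.  Returns a tidy frame (covariate, semipartial, r2_full,
    cond_number).
    """
    from sklearn.linear_model import LinearRegression

    r_in = input_resistance(geom, spec)
    df = records.copy()
    df["r_in"] = r_in[df["comp"].to_numpy()]
    X = df[list(COVARIATES)].to_numpy()
    yv = df["v_dend"].to_numpy()
    rng = np.random.default_rng(seed)
    test = rng.random(len(df)) < holdout
    cond = float(np.linalg.cond(X[~test] - X[~test].mean(0)))

    full = LinearRegression().fit(X[~test], yv[~test])
    r2_full = float(full.score(X[test], yv[test]))
    rows = []
    for k, name in enumerate(COVARIATES):
        keep = [j for j in range(len(COVARIATES)) if j != k]
        red = LinearRegression().fit(X[~test][:, keep], yv[~test])
        resid = yv[test] - red.predict(X[test][:, keep])
        x = X[test][:, k]
        if np.std(x) == 0 or np.std(resid) == 0:
            r = 0.0
        else:
            r = float(np.corrcoef(x, resid)[0, 1])
        rows.append(dict(covariate=name, semipartial=r, r2_full=r2_full,
                         cond_number=cond))
    return pd.DataFrame(rows)
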