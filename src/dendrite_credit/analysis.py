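"""Analyses of the learned computation.

Quantifies how trained weights shape dendritic integration: supra/sublinear
summation of feature pairs, spatial/temporal/spatiotemporal weighted input
profiles and their correlations, somatic-trace correlations, and prediction
of association labels from profile-correlation features.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .biophysics import BiophysicsSpec, SynapseLayout, simulate
from .inputs import AssociationTask, FeaturePattern, realize_poisson
from .morphology import Geometry, DOMAIN_BASAL, DOMAIN_APICAL


class DegenerateResponseError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# subthreshold summation nonlinearity

@dataclass
class NonlinearityIndex:
    """Peak of the joint response over the peak of the summed responses.

    Ratio 1 marks linear summation; computed from rep-averaged somatic
    depolarization in the second half of the stimulus window, with somatic
    spiking blocked.
    """

    ratio: float
    peak_joint: float
    peak_sum: float
    domain: int
    pair: tuple


def _domain_restricted(layout: SynapseLayout, geom: Geometry,
                       domain: int) -> SynapseLayout:
    """Zero the weights of synapses outside the given dendritic domain."""
    w = layout.weight.copy()
    w[geom.domain[layout.comp] != domain] = 0.0
    return SynapseLayout(layout.comp.copy(), layout.is_exc.copy(), w)


def _mean_trace(geom, spec, layout, patterns, task_spec, n_reps, rng,
                dt=0.025, record_dt=1.0):
    acc = None
    for _ in range(n_reps):
        trains = realize_poisson(patterns, task_spec,
                                 int(rng.integers(2**31)))
        rec = simulate(geom, spec, layout, trains, task_spec.t_off,
                       dt=dt, record_dt=record_dt, ap_block=True)
        acc = rec.v_soma if acc is None else acc + rec.v_soma
    return acc / n_reps, rec.t


def summation_nonlinearity(geom: Geometry, spec: BiophysicsSpec,
                           layout: SynapseLayout, task: AssociationTask,
                           pair: tuple, domain: int, n_reps: int = 20,
                           seed: int = 0) -> NonlinearityIndex:
    """Supra/sublinearity of feature-pair summation in one dendritic domain.

    Simulates the X and Y features separately and jointly (spiking blocked,
    other-domain weights zeroed), averages the somatic traces over
    ``n_reps`` realizations, and compares peak depolarization above rest in
    the second half of the stimulus window.
    """
    i, j = pair
    rng = np.random.default_rng(seed)
    lay = _domain_restricted(layout, geom, domain)
    fx, fy = task.x_features[i], task.y_features[j]
    v_joint, t = _mean_trace(geom, spec, lay, [fx, fy], task.spec, n_reps, rng)
    v_x, _ = _mean_trace(geom, spec, lay, [fx], task.spec, n_reps, rng)
    v_y, _ = _mean_trace(geom, spec, lay, [fy], task.spec, n_reps, rng)
    v0, _ = _mean_trace(geom, spec, lay, [], task.spec, 1, rng)
    half = t >= task.spec.t_on + task.spec.t_stim / 2.0
    peak_joint = float((v_joint - v0)[half].max())
    peak_sum = float(((v_x - v0) + (v_y - v0))[half].max())
    if abs(peak_sum) < 1e-9:
        raise DegenerateResponseError("summed response is zero")
    return NonlinearityIndex(ratio=peak_joint / peak_sum,
                             peak_joint=peak_joint, peak_sum=peak_sum,
                             domain=domain, pair=pair)


# ---------------------------------------------------------------------------
# weighted input profiles

@dataclass
class InputProfile:
    kind: str                # "spatial", "temporal", "spatiotemporal"
    values: np.ndarray
    is_exc: bool
    domain: int | None


def _syn_of(layout, geom, feature, domain, is_exc):
    """Global synapse ids of a feature's population in a stratum."""
    sel = np.zeros(layout.n_syn, bool)
    sel[feature.indices] = True
    sel &= layout.is_exc == is_exc
    if domain is not None:
        sel &= geom.domain[layout.comp] == domain
    return np.flatnonzero(sel)


def profiles(task: AssociationTask, layout: SynapseLayout, geom: Geometry,
             feature: FeaturePattern, kind: str, domain: int | None,
             is_exc: bool = True, dt_ms: float = 1.0) -> InputProfile:
    """Weighted input profile of one feature.

    spatial: S_b = sum_i w_ib lam_bar_ib per branch b of the domain;
    temporal: T(t) = sum_i w_i lam_i(t) at 1 ms resolution over the
    presentation; spatiotemporal: per-branch temporal profiles concatenated
    in branch order.
    """
    syn = _syn_of(layout, geom, feature, domain, is_exc)
    pos = {int(g): k for k, g in enumerate(feature.indices)}
    w = layout.weight[syn]
    if kind == "spatial":
        branches = sorted(b for b, comps in geom.branch_compartments().items()
                          if domain is None
                          or geom.domain[comps[0]] == domain)
        lam = np.array([feature.lam_bar()[pos[int(g)]] for g in syn]) \
            if len(syn) else np.empty(0)
        vals = np.zeros(len(branches))
        bidx = {b: k for k, b in enumerate(branches)}
        for s, ww, ll in zip(syn, w, lam):
            vals[bidx[int(geom.branch_id[layout.comp[s]])]] += ww * ll
        return InputProfile("spatial", vals, is_exc, domain)
    t = np.arange(0.0, task.spec.t_off, dt_ms)
    if kind == "temporal":
        vals = np.zeros_like(t)
        for s, ww in zip(syn, w):
            vals += ww * feature.rate(pos[int(s)], t)
        return InputProfile("temporal", vals, is_exc, domain)
    if kind == "spatiotemporal":
        branches = sorted(b for b, comps in geom.branch_compartments().items()
                          if domain is None
                          or geom.domain[comps[0]] == domain)
        chunks = []
        for b in branches:
            vals = np.zeros_like(t)
            for s, ww in zip(syn, w):
                if int(geom.branch_id[layout.comp[s]]) == b:
                    vals += ww * feature.rate(pos[int(s)], t)
            chunks.append(vals)
        return InputProfile("spatiotemporal", np.concatenate(chunks),
                            is_exc, domain)
    raise ValueError(f"unknown profile kind {kind!r}")


def profile_correlation(p: InputProfile, q: InputProfile) -> float | None:
    """Pearson correlation of two profiles; None if either is constant."""
    a, b = np.asarray(p.values, float), np.asarray(q.values, float)
    if len(a) != len(b):
        raise ValueError("profiles have different lengths")
    if np.std(a) == 0 or np.std(b) == 0:
        return None
    return float(stats.pearsonr(a, b)[0])


def pair_profile_correlation(task, layout, geom, pair, kind, domain,
                             mode: str = "EE") -> float | None:
    """Profile correlation for an association pair.

    ``EE``: the X feature's excitatory profile vs the Y feature's; ``EI``:
    summed excitation of both features vs their summed inhibition.
    """
    i, j = pair
    fx, fy = task.x_features[i], task.y_features[j]
    if mode == "EE":
        px = profiles(task, layout, geom, fx, kind, domain, True)
        py = profiles(task, layout, geom, fy, kind, domain, True)
        return profile_correlation(px, py)
    if mode == "EI":
        ex = profiles(task, layout, geom, fx, kind, domain, True)
        ey = profiles(task, layout, geom, fy, kind, domain, True)
        ix = profiles(task, layout, geom, fx, kind, domain, False)
        iy = profiles(task, layout, geom, fy, kind, domain, False)
        pe = InputProfile(kind, ex.values + ey.values, True, domain)
        pi = InputProfile(kind, ix.values + iy.values, False, domain)
        return profile_correlation(pe, pi)
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# voltage-trace correlations

def trace_correlation(geom: Geometry, spec: BiophysicsSpec,
                      layout: SynapseLayout, task: AssociationTask,
                      pair: tuple, n_reps: int = 20, seed: int = 0,
                      by_domain: bool = False) -> float | None:
    """Pearson correlation of rep-averaged somatic traces (spiking blocked).

    Default: the two features of the pair presented separately.  With
    ``by_domain``, correlates the response to basal-restricted versus
    apical-restricted weights for the same joint pair (basal/apical
    alignment).
    """
    i, j = pair
    rng = np.random.default_rng(seed)
    fx, fy = task.x_features[i], task.y_features[j]
    if by_domain:
        lb = _domain_restricted(layout, geom, DOMAIN_BASAL)
        la = _domain_restricted(layout, geom, DOMAIN_APICAL)
        va, _ = _mean_trace(geom, spec, lb, [fx, fy], task.spec, n_reps, rng)
        vb, _ = _mean_trace(geom, spec, la, [fx, fy], task.spec, n_reps, rng)
    else:
        va, _ = _mean_trace(geom, spec, layout, [fx], task.spec, n_reps, rng)
        vb, _ = _mean_trace(geom, spec, layout, [fy], task.spec, n_reps, rng)
    if np.std(va) == 0 or np.std(vb) == 0:
        return None
    return float(stats.pearsonr(va, vb)[0])


# ---------------------------------------------------------------------------
# label prediction from correlation features

def predict_labels(features: pd.DataFrame, labels: np.ndarray) -> float:
    """Leave-one-out logistic-regression accuracy of label prediction.

    ``features`` holds one row per association (any numeric columns);
    ``labels`` the corresponding binary classes.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import LeaveOneOut

    X = features.to_numpy(dtype=float)
    y = np.asarray(labels).ravel().astype(int)
    if len(X) < 10:
        raise ValueError("need at least 10 associations")
    if len(np.unique(y)) < 2:
        raise ValueError("labels are single-class")
    hits = 0
    for tr, te in LeaveOneOut().split(X):
        clf = LogisticRegression(max_iter=1000).fit(X[tr], y[tr])
        hits += int(clf.predict(X[te])[0] == y[te][0])
    return hits / len(X)


def wilcoxon_summary(a, b) -> dict:
    """Two-tailed Wilcoxon signed-rank summary for paired replications."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    res = stats.wilcoxon(a, b, alternative="two-sided")
    return dict(statistic=float(res.statistic), p_value=float(res.pvalue),
                mean_a=float(a.mean()), mean_b=float(b.mean()))
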