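"""Parameterized stimulus ensembles, association tasks, and noise models.

A stimulus presentation consists of 100 ms of background activity followed
by a T = 400 ms stimulus window.  Each feature activates a random subset of
its synapse population (Bernoulli with probability lambda_pop/lambda_syn, so
the population-averaged rate is fixed at lambda_pop regardless of
sparseness).  Active synapses fire either at a constant rate (K = 0, rate
code) or in K precisely timed Gaussian bursts whose widths scale with the
expected number of spikes per burst.  Spike trains are inhomogeneous Poisson
realizations generated by thinning.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from .biophysics import SpikeTrains, SynapseLayout
from .morphology import Geometry, DOMAIN_BASAL, DOMAIN_APICAL, StructureError


@dataclass
class InputEnsembleSpec:
    """Stimulus-ensemble parameters (rates in Hz, times in ms)."""

    n_syn: int = 1000
    lam_pop: float = 2.5     # population-average stimulus rate, Hz
    lam_syn: float = 40.0    # rate of active synapses, Hz
    k_events: int = 0        # precisely timed events per active synapse
    lam_bg: float = 1.25     # background rate, Hz
    sigma0: float = 2.5      # base bump width, ms (per expected spike)
    t_stim: float = 400.0    # stimulus window length, ms
    t_pre: float = 100.0     # pre-stimulus background, ms

    def __post_init__(self) -> None:
        if self.lam_syn < self.lam_pop:
            raise ValueError("lam_syn must be >= lam_pop")
        if not (0 < self.lam_pop):
            raise ValueError("lam_pop must be > 0")
        if self.k_events < 0:
            raise ValueError("k_events must be >= 0")

    @property
    def p_active(self) -> float:
        return self.lam_pop / self.lam_syn

    @property
    def t_on(self) -> float:
        return self.t_pre

    @property
    def t_off(self) -> float:
        return self.t_pre + self.t_stim

    @property
    def expected_spikes_per_burst(self) -> float:
        """lambda_bar * T / K with lambda in Hz and T in seconds."""
        if self.k_events == 0:
            return 0.0
        return self.lam_syn * self.t_stim / 1000.0 / self.k_events


def optimal_burst_spec(n_syn: int = 1000, **kw) -> InputEnsembleSpec:
    """Single-burst preset: K = 1 with an expected 8 spikes per burst."""
    return InputEnsembleSpec(n_syn=n_syn, lam_syn=20.0, k_events=1, **kw)


@dataclass
class FeaturePattern:
    """Time-dependent rate pattern for one feature over its synapse subset."""

    spec: InputEnsembleSpec
    indices: np.ndarray        # global synapse ids of this population
    active: np.ndarray         # bool per population synapse
    centers: list              # per population synapse: array of K burst times

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.active = np.asarray(self.active, dtype=bool)

    @property
    def n_pop(self) -> int:
        return len(self.indices)

    def lam_bar(self) -> np.ndarray:
        """Time-averaged stimulus rate per population synapse (Hz)."""
        return np.where(self.active, self.spec.lam_syn, 0.0)

    def rate(self, j: int, t: np.ndarray) -> np.ndarray:
        """Stimulus rate lambda_j(t) in Hz for population synapse j."""
        s = self.spec
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        if not self.active[j]:
            return out
        in_win = (t >= s.t_on) & (t < s.t_off)
        if s.k_events == 0:
            out[in_win] = s.lam_syn
            return out
        n_per = s.expected_spikes_per_burst       # expected spikes per burst
        sigma = s.sigma0 * n_per                   # ms
        for c in self.centers[j]:
            # unit-area Gaussian carrying n_per expected spikes (1000x for
            # Hz), renormalized so the mass inside the stimulus window is
            # exactly n_per even for bumps near the window edges
            frac = 0.5 * (math.erf((s.t_off - c) / (sigma * math.sqrt(2)))
                          - math.erf((s.t_on - c) / (sigma * math.sqrt(2))))
            out += 1000.0 * (n_per / frac) * _gauss(t - c, sigma)
        return out

    def rate_matrix(self, t: np.ndarray) -> np.ndarray:
        """(n_pop, len(t)) stimulus rates in Hz."""
        return np.stack([self.rate(j, t) for j in range(self.n_pop)])


def _gauss(x, sigma):
    return np.exp(-0.5 * (x / sigma) ** 2) / (sigma * math.sqrt(2 * math.pi))


def make_feature(spec: InputEnsembleSpec, seed: int,
                 indices: np.ndarray | None = None) -> FeaturePattern:
    """Draw a feature: Bernoulli activation plus uniform burst centers."""
    rng = np.random.default_rng(seed)
    if indices is None:
        indices = np.arange(spec.n_syn)
    indices = np.asarray(indices, dtype=np.int64)
    n = len(indices)
    active = rng.random(n) < spec.p_active
    centers = []
    for j in range(n):
        if active[j] and spec.k_events > 0:
            centers.append(np.sort(rng.uniform(spec.t_on, spec.t_off,
                                               spec.k_events)))
        else:
            centers.append(np.empty(0))
    return FeaturePattern(spec=spec, indices=indices, active=active,
                          centers=centers)


# ---------------------------------------------------------------------------
# Poisson realization by thinning

def _envelope(pattern: FeaturePattern, j: int) -> float:
    """Tight upper bound on the stimulus rate of population synapse j (Hz)."""
    s = pattern.spec
    if not pattern.active[j]:
        return 0.0
    if s.k_events == 0:
        return s.lam_syn
    sigma = s.sigma0 * s.expected_spikes_per_burst
    cs = pattern.centers[j]
    lo = max(s.t_on, cs.min() - 4 * sigma)
    hi = min(s.t_off, cs.max() + 4 * sigma)
    grid = np.arange(lo, hi + sigma / 10.0, sigma / 10.0)
    grid = np.concatenate([grid, cs])
    return float(pattern.rate(j, grid).max()) * 1.01


def _poisson_times(rng, rate_hz: float, t0: float, t1: float) -> np.ndarray:
    n = rng.poisson(rate_hz * (t1 - t0) / 1000.0)
    return np.sort(rng.uniform(t0, t1, n))


def realize_poisson(patterns: list, spec: InputEnsembleSpec, seed: int,
                    horizon: float | None = None,
                    background: str = "prestim") -> SpikeTrains:
    """Inhomogeneous Poisson spike trains for a set of feature patterns.

    ``patterns`` is a list of FeaturePattern objects over disjoint synapse
    subsets; synapses not covered receive background only.  ``background``:
    ``prestim`` (lambda_bg active during the first ``t_pre`` ms only),
    ``throughout`` (whole presentation), or ``none``.  Thinning against a
    per-synapse tight rate envelope realizes the stimulus component.
    """
    rng = np.random.default_rng(seed)
    horizon = horizon if horizon is not None else spec.t_off
    times = [np.empty(0) for _ in range(spec.n_syn)]
    # background
    if background == "prestim":
        bg_end = min(spec.t_pre, horizon)
    elif background == "throughout":
        bg_end = horizon
    elif background == "none":
        bg_end = 0.0
    else:
        raise ValueError(f"unknown background mode {background!r}")
    for i in range(spec.n_syn):
        if bg_end > 0 and spec.lam_bg > 0:
            times[i] = _poisson_times(rng, spec.lam_bg, 0.0, bg_end)
    # stimulus component by thinning
    for pat in patterns:
        for j in range(pat.n_pop):
            if not pat.active[j]:
                continue
            gid = int(pat.indices[j])
            env = _envelope(pat, j)
            if env <= 0:
                continue
            t0, t1 = pat.spec.t_on, min(pat.spec.t_off, horizon)
            cand = _poisson_times(rng, env, t0, t1)
            if len(cand):
                keep = rng.random(len(cand)) < pat.rate(j, cand) / env
                cand = cand[keep]
            times[gid] = np.sort(np.concatenate([times[gid], cand]))
    return SpikeTrains(times)


# ---------------------------------------------------------------------------
# association tasks

@dataclass
class AssociationTask:
    """n x n association task: features X_i and Y_j over synapse halves.

    ``labels[i, j]`` in {0, 1} is the class of pairing (X_i, Y_j); 1 marks
    the preferred (+) class that should elicit a somatic spike.
    """

    spec: InputEnsembleSpec
    x_features: list
    y_features: list
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)

    @property
    def n(self) -> int:
        return len(self.x_features)

    def pairs(self):
        return [(i, j) for i in range(self.n) for j in range(self.n)]

    def realize(self, i: int, j: int, seed: int,
                background: str = "prestim",
                horizon: float | None = None) -> SpikeTrains:
        return realize_poisson([self.x_features[i], self.y_features[j]],
                               self.spec, seed, horizon=horizon,
                               background=background)


def make_task(spec: InputEnsembleSpec, n: int = 2, nonlinear_2x2: bool = True,
              seed: int = 0) -> AssociationTask:
    """Build an association task; features split the population into halves.

    For n = 2 with ``nonlinear_2x2``, labels are the XOR-like identity
    assignment (diagonal pairs preferred), which no linear weighting of the
    two halves can separate.  For larger n, labels are random i.i.d.
    Bernoulli(1/2) (redrawn to avoid a single-class degenerate matrix).
    """
    if not (1 <= n <= 10):
        raise ValueError("task side n must be in 1..10")
    rng = np.random.default_rng(seed)
    half = spec.n_syn // 2
    x_idx = np.arange(half)
    y_idx = np.arange(half, spec.n_syn)
    xs = [make_feature(spec, rng.integers(2**31), indices=x_idx)
          for _ in range(n)]
    ys = [make_feature(spec, rng.integers(2**31), indices=y_idx)
          for _ in range(n)]
    if n == 2 and nonlinear_2x2:
        labels = np.eye(2, dtype=int)
    else:
        labels = rng.integers(0, 2, size=(n, n))
        while labels.min() == labels.max():
            labels = rng.integers(0, 2, size=(n, n))
    return AssociationTask(spec=spec, x_features=xs, y_features=ys,
                           labels=labels)


def compress_duration(task: AssociationTask, t_new: float) -> AssociationTask:
    """Rescale the stimulus window to ``t_new`` ms, conserving spike counts.

    Burst centers move affinely into the new window (widths unchanged); the
    rate-code rate scales by T/T_new so each synapse's expected spike count
    is preserved.
    """
    if not (25.0 <= t_new <= 400.0):
        raise ValueError("t_new must be in [25, 400] ms")
    old = task.spec
    if t_new == old.t_stim:
        return task
    scale = t_new / old.t_stim
    new_spec = replace(old, t_stim=t_new,
                       lam_syn=old.lam_syn / scale,
                       lam_pop=old.lam_pop / scale)

    def remap(feat: FeaturePattern) -> FeaturePattern:
        centers = [old_c * 0 + new_spec.t_on + (old_c - old.t_on) * scale
                   for old_c in feat.centers]
        return FeaturePattern(spec=new_spec, indices=feat.indices,
                              active=feat.active, centers=centers)

    return AssociationTask(spec=new_spec,
                           x_features=[remap(f) for f in task.x_features],
                           y_features=[remap(f) for f in task.y_features],
                           labels=task.labels.copy())


# ---------------------------------------------------------------------------
# noise manipulations

@dataclass
class NoiseSpec:
    """Noise condition parameters (all optional; zero/off by default)."""

    bg_ratio: float = 0.5        # lambda_bg / lambda_pop in [0.25, 2]
    p_mislabel: float = 0.0      # in [0, 0.2]
    s_jitter: float = 0.0        # weight jitter scale, in [0, 2]
    t_shift: float = 0.0         # burst shift magnitude, ms, in [0, 400]
    shift_mode: str = "shared"   # "shared" or "independent"

    def __post_init__(self) -> None:
        if not (0 <= self.p_mislabel <= 0.2):
            raise ValueError("p_mislabel must be in [0, 0.2]")
        if self.shift_mode not in ("shared", "independent"):
            raise ValueError("shift_mode must be 'shared' or 'independent'")


def jitter_weights(layout: SynapseLayout, s_jitter: float,
                   seed: int) -> SynapseLayout:
    """Multiply weights by (1 + u), u ~ Uniform[-s, s], floored at 0."""
    rng = np.random.default_rng(seed)
    draw = rng.uniform(-s_jitter, s_jitter, layout.n_syn)
    w = np.maximum(layout.weight * (1.0 + draw), 0.0)
    return SynapseLayout(layout.comp.copy(), layout.is_exc.copy(), w)


def mislabel(labels: np.ndarray, p: float, seed: int) -> np.ndarray:
    """Flip each label independently with probability p (per presentation)."""
    rng = np.random.default_rng(seed)
    flips = rng.random(labels.shape) < p
    return np.where(flips, 1 - labels, labels)


def shift_bursts(task: AssociationTask, t_shift: float, mode: str,
                 seed: int) -> AssociationTask:
    """Cyclically shift burst centers within the stimulus window."""
    rng = np.random.default_rng(seed)
    s = task.spec

    def remap(feat: FeaturePattern) -> FeaturePattern:
        shared = rng.uniform(-t_shift, t_shift)
        centers = []
        for c in feat.centers:
            d = shared if mode == "shared" else rng.uniform(-t_shift, t_shift)
            centers.append(s.t_on + np.mod(c - s.t_on + d, s.t_stim))
        return FeaturePattern(spec=s, indices=feat.indices,
                              active=feat.active, centers=centers)

    return AssociationTask(spec=s, x_features=[remap(f) for f in task.x_features],
                           y_features=[remap(f) for f in task.y_features],
                           labels=task.labels.copy())


def apply_noise(obj, noise: NoiseSpec, seed: int):
    """Apply the applicable noise components to a task or a synapse layout."""
    if isinstance(obj, SynapseLayout):
        return jitter_weights(obj, noise.s_jitter, seed) \
            if noise.s_jitter > 0 else obj
    if isinstance(obj, AssociationTask):
        task = obj
        if noise.t_shift > 0:
            task = shift_bursts(task, noise.t_shift, noise.shift_mode, seed)
        if noise.p_mislabel > 0:
            task = AssociationTask(spec=task.spec, x_features=task.x_features,
                                   y_features=task.y_features,
                                   labels=mislabel(task.labels,
                                                   noise.p_mislabel, seed + 1))
        if noise.bg_ratio is not None:
            task = AssociationTask(
                spec=replace(task.spec,
                             lam_bg=noise.bg_ratio * task.spec.lam_pop),
                x_features=task.x_features, y_features=task.y_features,
                labels=task.labels)
        return task
    raise TypeError("apply_noise expects a SynapseLayout or AssociationTask")


# ---------------------------------------------------------------------------
# structured connectivity

def _branch_sets(n_avail: int, overlap: float, rng) -> tuple:
    """Two possibly-overlapping branch sets per the overlap parameterization.

    Set size s = n*(2-overlap)/2 with the shared part 2s - n (the smallest
    overlap two size-s subsets of n branches can have), so the union always
    covers all n branches.  overlap 0 gives two identical full sets;
    overlap 1 gives two disjoint half-sets.
    """
    if not (0.0 <= overlap <= 1.0):
        raise StructureError(f"overlap {overlap} outside [0, 1]")
    s = int(round(n_avail * (2.0 - overlap) / 2.0))
    n_shared = 2 * s - n_avail
    n_unique = s - n_shared
    if n_shared < 0 or n_unique < 0:
        raise StructureError(
            f"overlap {overlap} infeasible with {n_avail} branches")
    perm = rng.permutation(n_avail)
    shared = perm[:n_shared]
    a = np.concatenate([shared, perm[n_shared:n_shared + n_unique]])
    b = np.concatenate([shared,
                        perm[n_shared + n_unique:n_shared + 2 * n_unique]])
    return np.sort(a), np.sort(b)


def structured_placement(geom: Geometry, task: AssociationTask,
                         layout: SynapseLayout, overlap: float,
                         model: str = "active", seed: int = 0) -> SynapseLayout:
    """Re-place synapses onto structured branch sets.

    Two branch sets are drawn per domain (basal, apical) among first-order
    branches.  In the ``active`` model, features forming preferred pairs are
    routed to shared basal sets and split apical sets; in the ``passive``
    model, synapses of preferred features are dispersed over all branches
    while nonpreferred ones are clustered.  Synapses are assigned by which
    feature of their class activates them; synapses active in both or
    neither feature keep an unbiased random branch.
    """
    if model not in ("active", "passive"):
        raise ValueError("model must be 'active' or 'passive'")
    rng = np.random.default_rng(seed)
    basal = geom.root_branches(DOMAIN_BASAL)
    apical = geom.root_branches(DOMAIN_APICAL)
    if len(basal) < 2 or len(apical) < 2:
        raise StructureError("need at least 2 basal and 2 apical root branches")
    b_a, b_b = _branch_sets(len(basal), overlap, rng)
    a_a, a_b = _branch_sets(len(apical), overlap, rng)
    basal_sets = (np.array(basal)[b_a], np.array(basal)[b_b])
    apical_sets = (np.array(apical)[a_a], np.array(apical)[a_b])
    root_of = geom.root_branch_of()

    # subtree compartments (area-weighted) per root-branch set
    def comps_of(branch_ids):
        mask = np.isin(root_of, np.asarray(branch_ids)) & geom.dendritic_mask()
        return np.flatnonzero(mask)

    def draw_from(branch_ids, n):
        comps = comps_of(branch_ids)
        p = geom.area[comps] / geom.area[comps].sum()
        return rng.choice(comps, size=n, p=p)

    dend = np.flatnonzero(geom.dendritic_mask())
    p_all = geom.area[dend] / geom.area[dend].sum()

    if task.n != 2:
        raise ValueError("structured placement is defined for 2x2 tasks")
    new_comp = layout.comp.copy()
    feats = {0: task.x_features, 1: task.y_features}
    # which half each synapse belongs to, and which feature activates it
    for cls in (0, 1):
        f0, f1 = feats[cls]
        for pos, gid in enumerate(f0.indices):
            a0 = bool(f0.active[pos]); a1 = bool(f1.active[pos])
            if a0 == a1:
                new_comp[gid] = rng.choice(dend, p=p_all)
                continue
            feat_id = 0 if a0 else 1
            # preferred pairing of feature: for the identity label matrix,
            # X_i pairs with Y_i -> basal set i shared, apical split by class
            if model == "active":
                bset = basal_sets[feat_id]
                aset = apical_sets[feat_id if cls == 0 else 1 - feat_id]
                target = np.concatenate([comps_of(bset), comps_of(aset)])
                p = geom.area[target] / geom.area[target].sum()
                new_comp[gid] = rng.choice(target, p=p)
            else:
                preferred = (task.labels[feat_id, feat_id] == 1)
                if preferred:
                    new_comp[gid] = rng.choice(dend, p=p_all)
                else:
                    bset = basal_sets[feat_id]
                    aset = apical_sets[feat_id]
                    target = np.concatenate([comps_of(bset), comps_of(aset)])
                    p = geom.area[target] / geom.area[target].sum()
                    new_comp[gid] = rng.choice(target, p=p)
    return SynapseLayout(new_comp, layout.is_exc.copy(), layout.weight.copy())


# ---------------------------------------------------------------------------
# serialization

def task_to_json(task: AssociationTask, path) -> None:
    def feat(f):
        return dict(indices=f.indices.tolist(), active=f.active.tolist(),
                    centers=[c.tolist() for c in f.centers])
    payload = dict(spec=asdict(task.spec), labels=task.labels.tolist(),
                   x_features=[feat(f) for f in task.x_features],
                   y_features=[feat(f) for f in task.y_features])
    with open(path, "w") as fh:
        json.dump(payload, fh)


def task_from_json(path) -> AssociationTask:
    with open(path) as fh:
        payload = json.load(fh)
    spec = InputEnsembleSpec(**payload["spec"])

    def feat(d):
        return FeaturePattern(spec=spec, indices=np.array(d["indices"]),
                              active=np.array(d["active"]),
                              centers=[np.array(c) for c in d["centers"]])
    return AssociationTask(spec=spec,
                           x_features=[feat(d) for d in payload["x_features"]],
                           y_features=[feat(d) for d in payload["y_features"]],
                           labels=np.array(payload["labels"]))
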