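"""Supervised plasticity rule, offline training/testing, and online variant.

Training presents labeled association patterns; on preferred (+) patterns a
small somatic teaching current proportional to the running error is
injected, converting near-threshold depolarizations into spikes.  At each
somatic spike every synapse is updated in proportion to its estimated
influence on the somatic voltage — either a fitted plasticity kernel
K(dt, v_dend) evaluated from locally available quantities, or the directly
integrated gradient dv_soma/dw — scaled by the negative running error.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .biophysics import BiophysicsSpec, SpikeTrains, SynapseLayout, simulate
from .inputs import AssociationTask
from .kernels import DT_MAX, PlasticityKernel, evaluate_kernel
from .morphology import Geometry
from .variational import WINDOW_MS, spike_window_gradient


# ---------------------------------------------------------------------------
# supervisor

def signed_error(z: int, z_star: int) -> int:
    """Per-trial signed error: 0 correct, -1 missed (+), +1 false alarm."""
    if z not in (0, 1) or z_star not in (0, 1):
        raise ValueError("z and z_star must be binary")
    return z - z_star


def running_error(history, z_star: int) -> float:
    """Mean of the last outputs minus the label (in [-1, 1])."""
    if len(history) == 0:
        raise ValueError("empty output history")
    return float(np.mean(list(history)) - z_star)


@dataclass
class SupervisorState:
    """Per-pattern output histories and running errors."""

    n_avg: int = 10
    histories: dict = field(default_factory=dict)

    def init_pattern(self, key, z_star: int) -> None:
        # initialized as all-incorrect so early updates are full-magnitude
        wrong = 1 - z_star
        self.histories[key] = deque([wrong] * self.n_avg, maxlen=self.n_avg)

    def record(self, key, z: int) -> None:
        self.histories[key].append(z)

    def error(self, key, z_star: int) -> float:
        return running_error(self.histories[key], z_star)

    def total_error(self, labels: dict) -> float:
        """Mean absolute running error over patterns (in [0, 1])."""
        return float(np.mean([abs(self.error(k, z)) for k, z in
                              labels.items()]))


def teaching_current(e_bar: float, is_plus: bool, beta: float = 0.1) -> float:
    """Somatic teaching current (nA): beta * |Ebar_p| on (+) patterns."""
    return beta * abs(e_bar) if is_plus else 0.0


# ---------------------------------------------------------------------------
# configuration

@dataclass
class TrainConfig:
    """Training protocol parameters."""

    alpha0: float | None = None   # uS; default 2e-6 / lam_syn
    lr_decay: str = "per-epoch"   # "per-epoch": a0/(1+epoch/1125); "literal": a0/(1+1125*epoch); "none"
    beta: float = 0.1             # nA teaching gain
    w_max: float = 0.01           # uS clip
    epochs: int = 1000
    stop_after: int = 10          # consecutive error-free epochs
    n_avg_train: int = 10
    n_avg_test: int = 20
    early_stop: bool = True       # interrupt presentation at first spike
    mode: str = "kernel"          # "kernel" or "direct"
    dt: float = 0.025
    update_i: bool = True         # plasticity on inhibitory synapses

    def alpha_for(self, task_lam_syn: float) -> float:
        return self.alpha0 if self.alpha0 is not None \
            else 2e-6 / task_lam_syn

    def lr(self, alpha: float, epoch: int) -> float:
        if self.lr_decay == "per-epoch":
            return alpha / (1.0 + epoch / 1125.0)
        if self.lr_decay == "literal":
            return alpha / (1.0 + 1125.0 * epoch)
        if self.lr_decay == "none":
            return alpha
        raise ValueError(f"unknown lr_decay {self.lr_decay!r}")


class KernelConfigError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# the weight update

def weight_update(events: pd.DataFrame, kernels: dict | None, e_bar: float,
                  alpha: float, layout: SynapseLayout,
                  direct: bool = False) -> np.ndarray:
    """Per-synapse weight change for one somatic spike.

    ``events`` has one row per in-window synaptic activation with columns
    syn, domain, is_exc, dt, v_dend (and g for direct mode).  The update is
    dw_i = -alpha * Ebar_p * sum_k K_i(dt_ik, v_dend_i), with events beyond
    the kernel's temporal domain contributing zero.  Direct mode substitutes
    the integrated gradient g for the kernel value.  The caller clips to
    [0, w_max] after applying.
    """
    dw = np.zeros(layout.n_syn)
    if e_bar == 0.0 or len(events) == 0:
        return dw
    if direct:
        vals = events["g"].to_numpy()
    else:
        vals = np.zeros(len(events))
        for (domain, is_exc), sub in events.groupby(["domain", "is_exc"]):
            kern = kernels.get((int(domain), bool(is_exc))) \
                if kernels else None
            if kern is None:
                raise KernelConfigError(
                    f"no kernel for stratum (domain={domain}, "
                    f"is_exc={is_exc})")
            vals[sub.index.to_numpy()] = evaluate_kernel(
                kern, sub["dt"].to_numpy(),
                None if kern.temporal_only else sub["v_dend"].to_numpy())
    np.add.at(dw, events["syn"].to_numpy(), vals)
    return -alpha * e_bar * dw


def _spike_events(layout: SynapseLayout, trains: SpikeTrains, geom: Geometry,
                  t_spike: float, v_at_spike: np.ndarray,
                  window: float = DT_MAX) -> pd.DataFrame:
    """Locally available event records (dt, v_dend) for a kernel update.

    Uses the lagged voltage snapshot from the ongoing run itself — no
    re-simulation is needed because the kernel replaces the gradient.
    """
    syns, dts = [], []
    for j, t in enumerate(trains.times):
        sel = t[(t < t_spike) & (t >= t_spike - window)]
        syns.extend([j] * len(sel))
        dts.extend((t_spike - sel).tolist())
    syns = np.array(syns, dtype=int)
    dts = np.array(dts, dtype=float)
    comp = layout.comp[syns] if len(syns) else np.empty(0, dtype=int)
    return pd.DataFrame({
        "syn": syns, "dt": dts,
        "domain": geom.domain[comp] if len(syns) else np.empty(0, dtype=int),
        "is_exc": layout.is_exc[syns] if len(syns) else np.empty(0, bool),
        "v_dend": v_at_spike[comp] if len(syns) else np.empty(0),
    })


# ---------------------------------------------------------------------------
# offline protocol

def _present(geom, spec, layout, trains, horizon, i_teach, cfg,
             full_duration=False):
    return simulate(geom, spec, layout, trains, horizon, i_soma=i_teach,
                    dt=cfg.dt, record_dt=horizon,
                    stop_on_spike=cfg.early_stop and not full_duration,
                    checkpoint_dt=10.0 if cfg.mode == "direct" else 0.0)


def train_offline(geom: Geometry, spec: BiophysicsSpec,
                  layout: SynapseLayout, task: AssociationTask,
                  cfg: TrainConfig, seed: int = 0,
                  kernels: dict | None = None):
    """Train the weights on an association task; returns (layout, curve).

    Each epoch presents every pattern once in random order; presentations
    stop at the first somatic spike, whose kernel-estimated (or directly
    integrated) per-synapse gradients drive the weight update scaled by the
    negative running error.  Weights are clipped to [0, w_max].  Training
    halts after ``stop_after`` consecutive error-free epochs.  The returned
    curve has one row per epoch (epoch, total_error, lr, n_spikes).
    """
    if cfg.mode == "kernel" and kernels is None:
        raise KernelConfigError("kernel-mode training requires kernels")
    rng = np.random.default_rng(seed)
    lay = layout.copy()
    sup = SupervisorState(n_avg=cfg.n_avg_train)
    labels = {(i, j): int(task.labels[i, j]) for i, j in task.pairs()}
    for key, z_star in labels.items():
        sup.init_pattern(key, z_star)
    alpha = cfg.alpha_for(task.spec.lam_syn)
    horizon = task.spec.t_off
    rows = []
    clean = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(labels))
        keys = list(labels.keys())
        lr = cfg.lr(alpha, epoch)
        n_spk = 0
        any_error = False
        for idx in order:
            key = keys[idx]
            z_star = labels[key]
            e_bar = sup.error(key, z_star)
            trains = task.realize(*key, seed=int(rng.integers(2**31)))
            i_teach = teaching_current(e_bar, z_star == 1, cfg.beta)
            rec = _present(geom, spec, lay, trains, horizon, i_teach, cfg)
            z = int(rec.n_spikes > 0)
            if z != z_star:
                any_error = True
            if rec.n_spikes > 0 and e_bar != 0.0 and lr > 0:
                n_spk += 1
                t_sp = float(rec.spike_times[0])
                if cfg.mode == "direct":
                    ev = spike_window_gradient(
                        rec, t_sp, geom, spec, lay, trains,
                        window=min(WINDOW_MS, max(t_sp, cfg.dt)), dt=cfg.dt)
                    ev = ev[ev["dt"] <= DT_MAX].reset_index(drop=True)
                else:
                    ev = _spike_events(lay, trains, geom, t_sp,
                                       rec.v_at_spike[0])
                dw = weight_update(ev, kernels, e_bar, lr, lay,
                                   direct=cfg.mode == "direct")
                if not cfg.update_i:
                    dw[~lay.is_exc] = 0.0
                lay.weight = np.clip(lay.weight + dw, 0.0, cfg.w_max)
            sup.record(key, z)
        total = sup.total_error(labels)
        rows.append(dict(epoch=epoch, total_error=total, lr=lr,
                         n_updates=n_spk, epoch_error=int(any_error)))
        clean = 0 if any_error else clean + 1
        if clean >= cfg.stop_after:
            break
    return lay, pd.DataFrame(rows)


def evaluate(geom: Geometry, spec: BiophysicsSpec, layout: SynapseLayout,
             task: AssociationTask, n_reps: int = 20, seed: int = 0,
             cfg: TrainConfig | None = None) -> float:
    """Test performance P_test = 1 - mean |running error|, N_avg = n_reps.

    Full-duration presentations with no teaching current and no plasticity;
    the output is 1 if at least one somatic spike occurs.
    """
    cfg = cfg or TrainConfig()
    rng = np.random.default_rng(seed)
    sup = SupervisorState(n_avg=n_reps)
    labels = {(i, j): int(task.labels[i, j]) for i, j in task.pairs()}
    horizon = task.spec.t_off
    for key, z_star in labels.items():
        sup.histories[key] = deque(maxlen=n_reps)
        for _ in range(n_reps):
            trains = task.realize(*key, seed=int(rng.integers(2**31)))
            rec = _present(geom, spec, layout, trains, horizon, 0.0, cfg,
                           full_duration=True)
            sup.record(key, int(rec.n_spikes > 0))
    return 1.0 - sup.total_error(labels)


# ---------------------------------------------------------------------------
# online implementation

@dataclass
class OnlineState:
    """Running rate and error estimators of the online supervisor."""

    r: float = 0.0          # exponentially averaged spike rate, ms^-1
    e_p: float = 0.0        # time-averaged signed error
    tau_r: float = 1000.0   # ms
    tau_e: float = 500.0    # ms
    r_lo: float = 0.1e-3    # ms^-1 (0.1 Hz)
    r_hi: float = 5.0e-3    # ms^-1 (5 Hz)

    def copy(self) -> "OnlineState":
        return OnlineState(self.r, self.e_p, self.tau_r, self.tau_e,
                           self.r_lo, self.r_hi)


def online_step(state: OnlineState, spiked: bool, z_star: int,
                dt: float) -> OnlineState:
    """One Euler update of the running rate/error estimators.

    tau_r dr/dt = -r with an instantaneous increment 1/tau_r per spike;
    tau_e dE/dt = Theta[r - r_lo (1 - z*) - r_hi z*] - z* - E.
    """
    s = state.copy()
    s.r *= (1.0 - dt / s.tau_r)
    if spiked:
        s.r += 1.0 / s.tau_r
    thresh = s.r_lo * (1 - z_star) + s.r_hi * z_star
    theta = 1.0 if s.r > thresh else 0.0
    s.e_p += dt / s.tau_e * (theta - z_star - s.e_p)
    return s


def train_online(geom: Geometry, spec: BiophysicsSpec,
                 layout: SynapseLayout, task: AssociationTask,
                 cfg: TrainConfig, kernels: dict | None = None,
                 t_train: float = 2000.0, n_presentations: int = 50,
                 seed: int = 0):
    """Online training: continuous-time supervisor, no pattern-history table.

    Each presentation periodically extends one (i, j) pattern over
    ``t_train`` ms with background input throughout.  The running estimators
    r and E_p are integrated continuously; the teaching current is
    beta * |E_p| on (+) patterns; plasticity turns on at t_train / 2 and
    every somatic spike triggers a kernel update with Ebar_p <- E_p.
    Between somatic spikes the estimators depend only on elapsed time, so
    each inter-spike segment is simulated in one call with the teaching
    current precomputed on the step grid.
    """
    if cfg.mode == "kernel" and kernels is None:
        raise KernelConfigError("kernel-mode training requires kernels")
    rng = np.random.default_rng(seed)
    lay = layout.copy()
    spec_in = task.spec
    t_cycle = spec_in.t_off      # background + stimulus, tiled periodically
    alpha = cfg.alpha_for(spec_in.lam_syn)
    rows = []
    for pres in range(n_presentations):
        i, j = rng.integers(task.n), rng.integers(task.n)
        z_star = int(task.labels[i, j])
        # periodic extension of the pattern over t_train with background on
        n_cycles = int(np.ceil(t_train / t_cycle))
        all_times = [[] for _ in range(spec_in.n_syn)]
        for c in range(n_cycles):
            tr = task.realize(i, j, seed=int(rng.integers(2**31)),
                              background="throughout")
            for sidx, t in enumerate(tr.times):
                all_times[sidx].extend((t + c * t_cycle).tolist())
        trains = SpikeTrains([np.sort(np.array(t)) for t in all_times])
        st = OnlineState()
        sim_state = None
        t_now = 0.0
        n_spk = 0
        while t_now < t_train - 1e-9:
            horizon = t_train - t_now
            n_steps = int(round(horizon / cfg.dt))
            if n_steps == 0:
                break
            # precompute estimator trajectories assuming no spikes
            tgrid_r = st.r * np.exp(-np.arange(n_steps) * cfg.dt / st.tau_r)
            thresh = st.r_lo * (1 - z_star) + st.r_hi * z_star
            theta = (tgrid_r > thresh).astype(float)
            e_traj = np.empty(n_steps)
            e = st.e_p
            for k in range(n_steps):
                e += cfg.dt / st.tau_e * (theta[k] - z_star - e)
                e_traj[k] = e
            i_teach = cfg.beta * np.abs(e_traj) if z_star == 1 \
                else np.zeros(n_steps)
            rec = simulate(geom, spec, lay, trains, n_steps * cfg.dt,
                           i_soma=i_teach, dt=cfg.dt,
                           record_dt=n_steps * cfg.dt, stop_on_spike=True,
                           init_state=sim_state, t0=t_now)
            sim_state = rec.final_state
            if rec.n_spikes == 0:
                st.r = float(tgrid_r[-1] * np.exp(-cfg.dt / st.tau_r))
                st.e_p = float(e_traj[-1])
                break
            t_sp = float(rec.spike_times[0])
            t_cross = float(rec.cross_times[0])
            k_sp = max(int(round((t_cross - t_now) / cfg.dt)) - 1, 0)
            k_sp = min(k_sp, n_steps - 1)
            st.r = float(tgrid_r[k_sp] * np.exp(-cfg.dt / st.tau_r)
                         + 1.0 / st.tau_r)
            st.e_p = float(e_traj[k_sp])
            n_spk += 1
            if t_cross >= t_train / 2.0 and st.e_p != 0.0:
                ev = _spike_events(lay, trains, geom, t_sp,
                                   rec.v_at_spike[0])
                dw = weight_update(ev, kernels, st.e_p, alpha, lay)
                if not cfg.update_i:
                    dw[~lay.is_exc] = 0.0
                lay.weight = np.clip(lay.weight + dw, 0.0, cfg.w_max)
            t_prev = t_now
            t_now = rec.final_state.t
            if t_now <= t_prev + 1e-9:
                break
        rows.append(dict(presentation=pres, i=int(i), j=int(j),
                         z_star=z_star, n_spikes=n_spk,
                         r_final=st.r * 1000.0, e_final=st.e_p))
    return lay, pd.DataFrame(rows)
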