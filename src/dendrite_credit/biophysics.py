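"""Biophysical model specification and simulation.

The membrane dynamics couple a passive cable (leak + axial currents) with
AMPA/NMDA/GABA synaptic conductances and Hodgkin-Huxley-style somatic spike
currents (fast Na+, delayed-rectifier K+, slow adaptation K+; optionally
dendritic Na+/K+ and HCN channels in the ``extended`` variant).  Four model
variants are supported:

- ``active``: voltage-dependent NMDA conductance (magnesium-block sigmoid),
  dendritic synapses, active soma;
- ``passive``: identical but with the NMDA voltage dependence removed
  (sigmoid clamped to 1), so dendrites integrate sublinearly;
- ``point``: identical biophysics to ``active`` but all synapses relocated to
  the somatic compartment;
- ``extended``: ``active`` plus low-density dendritic Na+/K+/Km and uniform
  HCN conductances.

Units: mV, ms, uS (weights; 1 nS = 1e-3 uS), nA, mS/cm^2 (channel densities),
uF/cm^2 (specific capacitance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import scipy.sparse as sp

from . import _core
from .morphology import Geometry, DOMAIN_SOMA

MODES = ("active", "passive", "point", "extended")


@dataclass
class BiophysicsSpec:
    """Full parameter set of the membrane model (defaults: study values)."""

    mode: str = "active"
    # passive
    c_m: float = 1.0          # uF/cm^2
    r_m: float = 1.0e4        # Ohm*cm^2
    r_a: float = 150.0        # Ohm*cm
    e_l: float = -75.0        # mV
    # somatic active conductances (mS/cm^2)
    g_na_soma: float = 80.0
    g_k_soma: float = 40.0
    g_km_soma: float = 3.0
    tau_km: float = 200.0     # ms, peak adaptation time constant
    e_na: float = 50.0
    e_k: float = -80.0
    v_t: float = -55.0        # mV, spike-threshold shift of the rate functions
    # dendritic densities (extended mode only)
    g_na_dend: float = 2.0
    g_k_dend: float = 1.0
    g_km_dend: float = 0.15
    g_ih: float = 0.1         # HCN, uniform (soma + dendrites) in extended mode
    e_hcn: float = -45.0
    # synaptic kinetics (ms)
    tau_ar: float = 0.1
    tau_ad: float = 2.0
    tau_nr: float = 2.0
    tau_nd: float = 75.0
    tau_gr: float = 1.0
    tau_gd: float = 5.0
    gamma: float = 2.0        # NMDA/AMPA ratio
    e_e: float = 0.0
    e_i: float = -75.0
    c_nmda: float = 1.0 / 3.75
    rho_nmda: float = 0.062
    spine_scaling: bool = False  # x2 on c_m and g_L in dendrites

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        for name in ("g_na_soma", "g_k_soma", "g_km_soma", "g_na_dend",
                     "g_k_dend", "g_km_dend", "g_ih"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def g_l(self) -> float:
        """Leak conductance density, mS/cm^2."""
        return 1.0e3 / self.r_m

    @property
    def nmda_on(self) -> bool:
        return self.mode != "passive"

    def with_mode(self, mode: str) -> "BiophysicsSpec":
        return replace(self, mode=mode)

    def to_yaml(self, path) -> None:
        import yaml
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "BiophysicsSpec":
        import yaml
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# synaptic kinetics

def peak_time(tau_r: float, tau_d: float) -> float:
    """Time to peak of the double exponential (ms after the spike)."""
    return tau_r * tau_d * math.log(tau_d / tau_r) / (tau_d - tau_r)


def double_exp_gmax(tau_r: float, tau_d: float) -> float:
    """Peak of ``exp(-t/tau_d) - exp(-t/tau_r)``, used as normalizer."""
    tp = peak_time(tau_r, tau_d)
    return math.exp(-tp / tau_d) - math.exp(-tp / tau_r)


def syn_activation(t, spikes, tau_r: float, tau_d: float):
    """Normalized double-exponential activation summed over past spikes.

    Each spike contributes ``(exp(-(t-t0)/tau_d) - exp(-(t-t0)/tau_r))/gmax``
    for ``t >= t0`` with the peak of a single contribution normalized to 1.
    """
    if not (tau_d > tau_r > 0):
        raise ValueError("require tau_d > tau_r > 0")
    spikes = np.asarray(spikes, dtype=float)
    if spikes.ndim != 1 or np.any(np.diff(spikes) < 0):
        raise ValueError("spikes must be a sorted 1-D array")
    t = np.asarray(t, dtype=float)
    gmax = double_exp_gmax(tau_r, tau_d)
    dtm = t[..., None] - spikes
    mask = dtm >= 0
    out = np.where(mask, np.exp(-np.clip(dtm, 0, None) / tau_d)
                   - np.exp(-np.clip(dtm, 0, None) / tau_r), 0.0)
    return out.sum(axis=-1) / gmax


def nmda_gate(v, spec: BiophysicsSpec | str = "active"):
    """Voltage-dependent NMDA factor sigma_N(v); identically 1 in passive mode."""
    if isinstance(spec, str):
        spec = BiophysicsSpec(mode=spec)
    v = np.asarray(v, dtype=float)
    if not spec.nmda_on:
        return np.ones_like(v)
    return 1.0 / (1.0 + spec.c_nmda * np.exp(-spec.rho_nmda * v))


def gating_rates(v, channel: str, spec: BiophysicsSpec | None = None):
    """Voltage-dependent opening/closing rates (alpha, beta) in ms^-1.

    ``channel`` is one of m, h, n (threshold-shifted Traub-style), p (slow
    M-type K+, peak time constant ``tau_km``) or q (HCN).
    """
    spec = spec or BiophysicsSpec()
    v = np.atleast_1d(np.asarray(v, dtype=float))
    fns = {
        "m": lambda x: _core.rates_m(x, spec.v_t),
        "h": lambda x: _core.rates_h(x, spec.v_t),
        "n": lambda x: _core.rates_n(x, spec.v_t),
        "p": lambda x: _core.rates_p(x, spec.tau_km),
        "q": lambda x: _core.rates_q(x),
    }
    if channel not in fns:
        raise ValueError(f"unknown channel {channel!r}")
    ab = np.array([fns[channel](float(x)) for x in v])
    a, b = ab[:, 0], ab[:, 1]
    if a.size == 1:
        return float(a[0]), float(b[0])
    return a, b


# ---------------------------------------------------------------------------
# synapse layout

@dataclass
class SynapseLayout:
    """Synapse placement and weights on a geometry.

    ``comp`` maps each synapse to its compartment; excitatory synapses come
    first (``is_exc``), weights are in uS (1 nS = 1e-3 uS).
    """

    comp: np.ndarray      # (n_syn,) int
    is_exc: np.ndarray    # (n_syn,) bool
    weight: np.ndarray    # (n_syn,) float, uS

    def __post_init__(self) -> None:
        self.comp = np.asarray(self.comp, dtype=np.int64)
        self.is_exc = np.asarray(self.is_exc, dtype=bool)
        self.weight = np.asarray(self.weight, dtype=np.float64)
        if np.any(self.weight < 0):
            raise ValueError("weights must be >= 0")

    @property
    def n_syn(self) -> int:
        return len(self.comp)

    @property
    def n_e(self) -> int:
        return int(self.is_exc.sum())

    @property
    def n_i(self) -> int:
        return int((~self.is_exc).sum())

    def domains(self, geom: Geometry) -> np.ndarray:
        return geom.domain[self.comp]

    def branches(self, geom: Geometry) -> np.ndarray:
        return geom.branch_id[self.comp]

    def projection_matrices(self, geom: Geometry, spec: BiophysicsSpec):
        """H^E, H^I incidence matrices scaled by 1/(c_m * area) per nF."""
        inv_c = 1.0 / _effective_capacitance(geom, spec)
        e_idx = np.flatnonzero(self.is_exc)
        i_idx = np.flatnonzero(~self.is_exc)
        n = geom.n_comp

        def build(idx):
            rows = self.comp[idx]
            cols = np.arange(len(idx))
            vals = inv_c[rows]
            return sp.csr_matrix((vals, (rows, cols)), shape=(n, len(idx)))

        return build(e_idx), build(i_idx)

    def copy(self) -> "SynapseLayout":
        return SynapseLayout(self.comp.copy(), self.is_exc.copy(),
                             self.weight.copy())


def place_synapses(geom: Geometry, n_e: int = 800, n_i: int = 200,
                   mode: str = "uniform", seed: int = 0,
                   w_e: float = 0.6e-3, w_i: float = 0.8e-3) -> SynapseLayout:
    """Randomly place synapses on the dendritic tree.

    Placement is uniform by membrane area over basal+apical compartments.
    Modes: ``uniform``; ``point`` (all at the soma); ``somatic_inhibition``
    (inhibitory synapses at the soma, excitatory dendritic).  Default weights
    are 0.6 nS (E) and 0.8 nS (I).
    """
    if n_e < 0 or n_i < 0:
        raise ValueError("synapse counts must be >= 0")
    rng = np.random.default_rng(seed)
    dend = np.flatnonzero(geom.dendritic_mask())
    if len(dend) == 0 and mode != "point":
        raise ValueError("geometry has no dendritic compartments")
    if len(dend):
        p = geom.area[dend] / geom.area[dend].sum()

    def draw(n):
        return rng.choice(dend, size=n, p=p)

    if mode == "uniform":
        comp = np.concatenate([draw(n_e), draw(n_i)])
    elif mode == "point":
        comp = np.zeros(n_e + n_i, dtype=np.int64)
    elif mode == "somatic_inhibition":
        comp = np.concatenate([draw(n_e), np.zeros(n_i, dtype=np.int64)])
    else:
        raise ValueError(f"unknown placement mode {mode!r}")
    is_exc = np.concatenate([np.ones(n_e, bool), np.zeros(n_i, bool)])
    weight = np.concatenate([np.full(n_e, w_e), np.full(n_i, w_i)])
    return SynapseLayout(comp=comp, is_exc=is_exc, weight=weight)


# ---------------------------------------------------------------------------
# spike trains

@dataclass
class SpikeTrains:
    """Per-synapse sorted presynaptic spike times (ms)."""

    times: list  # list of 1-D float arrays, one per synapse

    def __post_init__(self) -> None:
        self.times = [np.asarray(t, dtype=float) for t in self.times]
        for j, t in enumerate(self.times):
            if np.any(np.diff(t) < 0):
                raise ValueError(f"synapse {j}: spike times must be sorted")
            if len(t) and t[0] < 0:
                raise ValueError(f"synapse {j}: negative spike time")

    @property
    def n_syn(self) -> int:
        return len(self.times)

    def n_spikes(self) -> int:
        return int(sum(len(t) for t in self.times))

    def events(self):
        """Flattened (time, synapse) event arrays sorted by time."""
        if self.n_syn == 0:
            return np.empty(0), np.empty(0, dtype=np.int64)
        t = np.concatenate(self.times) if self.n_spikes() else np.empty(0)
        s = np.concatenate([np.full(len(x), j, dtype=np.int64)
                            for j, x in enumerate(self.times)]) \
            if self.n_spikes() else np.empty(0, dtype=np.int64)
        order = np.argsort(t, kind="stable")
        return t[order], s[order]

    @classmethod
    def empty(cls, n_syn: int) -> "SpikeTrains":
        return cls(times=[np.empty(0) for _ in range(n_syn)])

    def save_text(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# synapse_id\tt_ms\n")
            t, s = self.events()
            for ti, si in zip(t, s):
                fh.write(f"{si}\t{ti:.6f}\n")

    @classmethod
    def load_text(cls, path, n_syn: int) -> "SpikeTrains":
        times = [[] for _ in range(n_syn)]
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                s, t = line.split()
                times[int(s)].append(float(t))
        return cls(times=[np.sort(np.array(t)) for t in times])


# ---------------------------------------------------------------------------
# assembled model and simulation

class InstabilityError(RuntimeError):
    pass


@dataclass
class SimState:
    """Full dynamical state at one instant (used for stepping/replay)."""

    t: float
    v: np.ndarray
    m: np.ndarray
    h: np.ndarray
    n: np.ndarray
    p: np.ndarray
    q: np.ndarray
    s_ar: np.ndarray
    s_ad: np.ndarray
    s_nr: np.ndarray
    s_nd: np.ndarray
    s_gr: np.ndarray
    s_gd: np.ndarray

    def copy(self) -> "SimState":
        return SimState(self.t, *(getattr(self, f).copy() for f in
                                  ("v", "m", "h", "n", "p", "q", "s_ar", "s_ad",
                                   "s_nr", "s_nd", "s_gr", "s_gd")))


@dataclass
class TraceRecord:
    """Sampled simulation output."""

    t: np.ndarray
    v_soma: np.ndarray
    v_all: np.ndarray | None
    cross_times: np.ndarray        # upward 0 mV crossings (ms)
    spike_times: np.ndarray        # cross - 2 ms ("upswing" definition)
    v_at_spike: np.ndarray         # full voltage 2 ms before each crossing
    final_state: SimState
    stopped_early: bool
    checkpoints: dict | None = None
    dv_soma: np.ndarray | None = None   # (n_rec, n_tracked) sensitivities

    @property
    def n_spikes(self) -> int:
        return len(self.cross_times)


SPIKE_LAG_MS = 2.0


def _effective_capacitance(geom: Geometry, spec: BiophysicsSpec) -> np.ndarray:
    """Per-compartment capacitance in nF, with optional dendritic spine scaling."""
    cap = 1e3 * spec.c_m * geom.area
    if spec.spine_scaling:
        cap = np.where(geom.dendritic_mask(), 2.0 * cap, cap)
    return cap


def membrane_arrays(geom: Geometry, spec: BiophysicsSpec, ap_block: bool = False):
    """Per-compartment channel densities normalized by c_m (ms^-1 units)."""
    n = geom.n_comp
    dend = geom.dendritic_mask()
    cm_eff = np.where(dend & np.array([spec.spine_scaling] * n), 2 * spec.c_m,
                      spec.c_m)
    gl_density = np.where(dend, spec.g_l * (2.0 if spec.spine_scaling else 1.0),
                          spec.g_l)
    gl = gl_density / (1e3 * cm_eff) * 1e3  # (mS/cm^2)/(uF/cm^2) -> ms^-1
    gna = np.zeros(n); gk = np.zeros(n); gkm = np.zeros(n); gih = np.zeros(n)
    soma = geom.soma_index
    if not ap_block:
        gna[soma] = spec.g_na_soma / spec.c_m
        gk[soma] = spec.g_k_soma / spec.c_m
    gkm[soma] = spec.g_km_soma / spec.c_m
    if spec.mode == "extended":
        cm_d = cm_eff[dend]
        gna[dend] = spec.g_na_dend / cm_d
        gk[dend] = spec.g_k_dend / cm_d
        gkm[dend] = spec.g_km_dend / cm_d
        gih[:] = spec.g_ih / cm_eff
    return gl, gna, gk, gkm, gih


def resting_state(geom: Geometry, spec: BiophysicsSpec,
                  layout: SynapseLayout | None = None) -> SimState:
    """State with v = E_L everywhere and gating at its E_L steady state."""
    n = geom.n_comp
    v = np.full(n, spec.e_l)

    def inf(fn, *args):
        a, b = fn(spec.e_l, *args)
        return np.full(n, a / (a + b))

    m = inf(_core.rates_m, spec.v_t)
    h = inf(_core.rates_h, spec.v_t)
    nn = inf(_core.rates_n, spec.v_t)
    p = inf(_core.rates_p, spec.tau_km)
    q = inf(_core.rates_q)
    n_e = layout.n_e if layout is not None else 0
    n_i = layout.n_i if layout is not None else 0
    z = np.zeros
    return SimState(0.0, v, m, h, nn, p, q, z(n_e), z(n_e), z(n_e), z(n_e),
                    z(n_i), z(n_i))


def _assemble(geom: Geometry, spec: BiophysicsSpec, layout: SynapseLayout,
              ap_block: bool = False):
    cap = _effective_capacitance(geom, spec)
    inv_c = 1.0 / cap
    gp_over_ci = np.zeros(geom.n_comp)
    gp_over_cp = np.zeros(geom.n_comp)
    for i in range(1, geom.n_comp):
        p = geom.parent[i]
        gp_over_ci[i] = geom.g_pair[i] / cap[i]
        gp_over_cp[i] = geom.g_pair[i] / cap[p]
    gl, gna, gk, gkm, gih = membrane_arrays(geom, spec, ap_block=ap_block)
    has_gating = (gna + gk + gkm + gih) > 0

    comp = layout.comp.copy()
    if spec.mode == "point":
        comp[:] = geom.soma_index
    e_mask = layout.is_exc
    e_comp = comp[e_mask].astype(np.int64)
    i_comp = comp[~e_mask].astype(np.int64)
    e_w = layout.weight[e_mask].astype(np.float64)
    i_w = layout.weight[~e_mask].astype(np.float64)
    return dict(
        parent=geom.parent.astype(np.int64), gp_over_ci=gp_over_ci,
        gp_over_cp=gp_over_cp, inv_c=inv_c, gl=gl, el=spec.e_l,
        gna=gna, gk=gk, gkm=gkm, gih=gih, ena=spec.e_na, ek=spec.e_k,
        ehcn=spec.e_hcn, vt=spec.v_t, tau_km=spec.tau_km,
        has_gating=has_gating,
        e_comp=e_comp, e_w=e_w, i_comp=i_comp, i_w=i_w,
        gamma=spec.gamma, c_nmda=spec.c_nmda, rho_nmda=spec.rho_nmda,
        nmda_on=spec.nmda_on, e_e=spec.e_e, e_i=spec.e_i,
        inv_gmax_a=1.0 / double_exp_gmax(spec.tau_ar, spec.tau_ad),
        inv_gmax_n=1.0 / double_exp_gmax(spec.tau_nr, spec.tau_nd),
        inv_gmax_g=1.0 / double_exp_gmax(spec.tau_gr, spec.tau_gd),
    )


def _synapse_event_arrays(layout: SynapseLayout, trains: SpikeTrains | None,
                          t0: float, dt: float, n_steps: int):
    """Map spike times to (step, global synapse id), E synapses first."""
    n_e = layout.n_e
    e_pos = np.cumsum(layout.is_exc) - 1      # global E index per synapse
    i_pos = np.cumsum(~layout.is_exc) - 1
    if trains is None or trains.n_spikes() == 0:
        return (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
    t, s = trains.events()
    step = np.floor((t - t0) / dt).astype(np.int64)
    keep = (step >= 0) & (step < n_steps)
    step, s = step[keep], s[keep]
    gid = np.where(layout.is_exc[s], e_pos[s], n_e + i_pos[s])
    order = np.argsort(step, kind="stable")
    return step[order], gid[order].astype(np.int64)


def simulate(geom: Geometry, spec: BiophysicsSpec, layout: SynapseLayout,
             trains: SpikeTrains | None, horizon: float,
             i_soma: float | np.ndarray = 0.0, *,
             dt: float = 0.025, record: str = "soma", record_dt: float | None = None,
             stop_on_spike: bool = False, checkpoint_dt: float = 0.0,
             init_state: SimState | None = None, t0: float = 0.0,
             ap_block: bool = False, inj_comp: int | None = None,
             sens_syn: np.ndarray | None = None) -> TraceRecord:
    """Integrate the model from ``t0`` over ``horizon`` ms.

    ``i_soma`` is a constant or per-step injected current (nA) at the soma
    (or ``inj_comp``).  Somatic spikes are detected as upward 0 mV crossings;
    each reported spike time is 2 ms before its crossing, and the full
    voltage vector at that moment is recorded.  ``stop_on_spike`` interrupts
    the run at the first crossing.  ``sens_syn`` (global synapse ids,
    excitatory first) switches on the coupled sensitivity system and records
    the somatic voltage gradient of each tracked synapse.

    Raises :class:`InstabilityError` if the state becomes non-finite.
    """
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    n_steps = int(round(horizon / dt))
    asm = _assemble(geom, spec, layout, ap_block=ap_block)
    if init_state is None:
        init_state = resting_state(geom, spec, layout)
    st = init_state

    i_arr = np.broadcast_to(np.asarray(i_soma, dtype=float), (n_steps,)) \
        if np.ndim(i_soma) == 0 else np.asarray(i_soma, dtype=float)
    if len(i_arr) != n_steps:
        raise ValueError("i_soma waveform length must equal step count")

    rec_every = max(1, int(round((record_dt or dt) / dt)))
    chk_every = int(round(checkpoint_dt / dt)) if checkpoint_dt > 0 else 0
    lag_steps = int(round(SPIKE_LAG_MS / dt))
    ev_step, ev_syn = _synapse_event_arrays(layout, trains, t0, dt, n_steps)
    sens_on = sens_syn is not None and len(sens_syn) > 0
    sens_arr = (np.asarray(sens_syn, dtype=np.int64) if sens_on
                else np.empty(0, dtype=np.int64))

    out = _core.run_core(
        asm["parent"], asm["gp_over_ci"], asm["gp_over_cp"], asm["inv_c"],
        asm["gl"], asm["el"],
        asm["gna"], asm["gk"], asm["gkm"], asm["gih"], asm["ena"], asm["ek"],
        asm["ehcn"], asm["vt"], asm["tau_km"], asm["has_gating"],
        asm["e_comp"], asm["e_w"], asm["i_comp"], asm["i_w"],
        asm["gamma"], asm["c_nmda"], asm["rho_nmda"], asm["nmda_on"],
        asm["e_e"], asm["e_i"],
        math.exp(-dt / spec.tau_ar), math.exp(-dt / spec.tau_ad),
        math.exp(-dt / spec.tau_nr), math.exp(-dt / spec.tau_nd),
        math.exp(-dt / spec.tau_gr), math.exp(-dt / spec.tau_gd),
        asm["inv_gmax_a"], asm["inv_gmax_n"], asm["inv_gmax_g"],
        ev_step, ev_syn,
        n_steps, dt, t0, np.ascontiguousarray(i_arr),
        geom.soma_index if inj_comp is None else int(inj_comp),
        rec_every, record == "all", stop_on_spike, lag_steps, chk_every,
        sens_on, sens_arr,
        st.v, st.m, st.h, st.n, st.p, st.q,
        st.s_ar, st.s_ad, st.s_nr, st.s_nd, st.s_gr, st.s_gd,
    )
    rec_out, spk_out, chk_out, fin_out, dv_final, step_stop, unstable_at = out
    rec_t, rec_vs, rec_va, rec_dvs = rec_out
    cross, v_lag = spk_out
    (chk_t, chk_v, chk_m, chk_h, chk_n, chk_p, chk_q,
     chk_sar, chk_sad, chk_snr, chk_snd, chk_sgr, chk_sgd) = chk_out
    (fv, fm, fh, fn, fp, fq,
     fsar, fsad, fsnr, fsnd, fsgr, fsgd) = fin_out

    if unstable_at >= 0:
        raise InstabilityError(f"non-finite state at t = {unstable_at:.3f} ms")

    final = SimState(t0 + step_stop * dt, fv, fm, fh, fn, fp, fq,
                     fsar, fsad, fsnr, fsnd, fsgr, fsgd)
    checkpoints = None
    if chk_every > 0:
        checkpoints = dict(t=chk_t, v=chk_v, m=chk_m, h=chk_h, n=chk_n,
                           p=chk_p, q=chk_q, s_ar=chk_sar, s_ad=chk_sad,
                           s_nr=chk_snr, s_nd=chk_snd, s_gr=chk_sgr,
                           s_gd=chk_sgd)
    rec = TraceRecord(
        t=rec_t, v_soma=rec_vs, v_all=rec_va if record == "all" else None,
        cross_times=cross, spike_times=cross - SPIKE_LAG_MS, v_at_spike=v_lag,
        final_state=final, stopped_early=step_stop < n_steps,
        checkpoints=checkpoints, dv_soma=rec_dvs if sens_on else None,
    )
    rec._dv_final = dv_final  # (n_tracked, n_comp) at termination
    return rec


# ---------------------------------------------------------------------------
# reference (dense numpy) right-hand side and step, used as numerical oracle

def rhs(state: SimState, layout: SynapseLayout, spec: BiophysicsSpec,
        geom: Geometry):
    """Time derivative of (v, gating) at the given state, dense evaluation.

    Synaptic activations are read from the state's kinetic variables; their
    own (linear) dynamics are exact exponentials and are not returned here.
    """
    asm = _assemble(geom, spec, layout)
    v = state.v
    n = geom.n_comp
    wa = np.zeros(n); wn = np.zeros(n); wg = np.zeros(n)
    inv_g1 = 1.0 / (1.0 + spec.gamma)
    np.add.at(wa, asm["e_comp"], asm["e_w"] * (state.s_ad - state.s_ar) * inv_g1)
    np.add.at(wn, asm["e_comp"],
              asm["e_w"] * (state.s_nd - state.s_nr) * spec.gamma * inv_g1)
    np.add.at(wg, asm["i_comp"], asm["i_w"] * (state.s_gd - state.s_gr))
    sn = nmda_gate(v, spec)
    inv_c = asm["inv_c"]
    dvdt = (-(wa + wn * sn) * inv_c * (v - spec.e_e)
            - wg * inv_c * (v - spec.e_i)
            - asm["gna"] * state.m ** 3 * state.h * (v - spec.e_na)
            - asm["gk"] * state.n ** 4 * (v - spec.e_k)
            - asm["gkm"] * state.p * (v - spec.e_k)
            - asm["gih"] * state.q * (v - spec.e_hcn)
            - asm["gl"] * (v - spec.e_l))
    # axial term via the capacitance-normalized coupling matrix
    G = _axial_operator(geom, spec)
    dvdt = dvdt + G @ v

    def gate_dot(x, fn, *args):
        ab = np.array([fn(float(vi), *args) for vi in v])
        return ab[:, 0] * (1 - x) - ab[:, 1] * x

    return dict(
        v=dvdt,
        m=gate_dot(state.m, _core.rates_m, spec.v_t),
        h=gate_dot(state.h, _core.rates_h, spec.v_t),
        n=gate_dot(state.n, _core.rates_n, spec.v_t),
        p=gate_dot(state.p, _core.rates_p, spec.tau_km),
        q=gate_dot(state.q, _core.rates_q),
    )


def _axial_operator(geom: Geometry, spec: BiophysicsSpec) -> sp.csr_matrix:
    cap = _effective_capacitance(geom, spec)
    n = geom.n_comp
    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    for i in range(1, n):
        p = int(geom.parent[i])
        g = geom.g_pair[i]
        rows += [i, p]; cols += [p, i]
        vals += [g / cap[i], g / cap[p]]
        diag[i] -= g / cap[i]; diag[p] -= g / cap[p]
    rows += list(range(n)); cols += list(range(n)); vals += list(diag)
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


def step(state: SimState, dt: float, layout: SynapseLayout,
         spec: BiophysicsSpec, geom: Geometry,
         i_inj: float = 0.0) -> SimState:
    """One semi-implicit update via a dense linear solve (reference path).

    Mirrors the compiled integrator exactly — synaptic decay, event-free
    staggered gating, frozen-conductance implicit voltage solve — but uses a
    dense ``numpy.linalg.solve`` instead of tree elimination, providing an
    independent check of the fast path.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    st = state.copy()
    for name, tau in (("s_ar", spec.tau_ar), ("s_ad", spec.tau_ad),
                      ("s_nr", spec.tau_nr), ("s_nd", spec.tau_nd),
                      ("s_gr", spec.tau_gr), ("s_gd", spec.tau_gd)):
        setattr(st, name, getattr(st, name) * math.exp(-dt / tau))
    asm = _assemble(geom, spec, layout)
    v = st.v
    n = geom.n_comp

    def gate_imp(x, fn, *args):
        ab = np.array([fn(float(vi), *args) for vi in v])
        return (x + dt * ab[:, 0]) / (1.0 + dt * (ab[:, 0] + ab[:, 1]))

    st.m = gate_imp(st.m, _core.rates_m, spec.v_t)
    st.h = gate_imp(st.h, _core.rates_h, spec.v_t)
    st.n = gate_imp(st.n, _core.rates_n, spec.v_t)
    st.p = gate_imp(st.p, _core.rates_p, spec.tau_km)
    st.q = gate_imp(st.q, _core.rates_q)

    wa = np.zeros(n); wn = np.zeros(n); wg = np.zeros(n)
    inv_g1 = 1.0 / (1.0 + spec.gamma)
    np.add.at(wa, asm["e_comp"], asm["e_w"] * (st.s_ad - st.s_ar) * inv_g1)
    np.add.at(wn, asm["e_comp"],
              asm["e_w"] * (st.s_nd - st.s_nr) * spec.gamma * inv_g1)
    np.add.at(wg, asm["i_comp"], asm["i_w"] * (st.s_gd - st.s_gr))
    sn = nmda_gate(v, spec)
    inv_c = asm["inv_c"]
    ge = (wa + wn * sn) * inv_c
    gi = wg * inv_c
    a = (asm["gl"] + ge + gi + asm["gna"] * st.m ** 3 * st.h
         + asm["gk"] * st.n ** 4 + asm["gkm"] * st.p + asm["gih"] * st.q)
    b = (asm["gl"] * spec.e_l + ge * spec.e_e + gi * spec.e_i
         + asm["gna"] * st.m ** 3 * st.h * spec.e_na
         + asm["gk"] * st.n ** 4 * spec.e_k + asm["gkm"] * st.p * spec.e_k
         + asm["gih"] * st.q * spec.e_hcn)
    b = b.copy()
    b[geom.soma_index] += i_inj * inv_c[geom.soma_index]
    G = _axial_operator(geom, spec).toarray()
    A = np.diag(1.0 + dt * a) - dt * G
    st.v = np.linalg.solve(A, v + dt * b)
    st.t = state.t + dt
    return st
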