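# Methods

## Compartmental model

A neuron is a tree of cylindrical compartments plus a lumped spherical
soma (radius 10 μm).  Dendritic branches longer than 10 μm are split
into `max(2, ceil(L/10))` equal cylinders.  Axial coupling between
adjacent compartments is expressed as a capacitance-normalized matrix
`G` (units ms⁻¹) with zero row sums; reciprocity holds in the form
`area_i · G_ij = area_j · G_ji`.  Optional spine scaling doubles the
membrane capacitance and leak conductance of dendritic compartments to
account for unmodelled spine area.

Units: mV, ms, μm, μS, nA, nF; conductance densities in mS/cm².  With
these units nA/μS = mV and all rates are ms⁻¹.

## Membrane and synapses

The soma carries transient Na⁺ and delayed-rectifier K⁺ currents
(threshold-shifted rate functions with `V_T = −55 mV`), a slow
non-inactivating M-type K⁺ current whose time constant is scaled so its
peak equals 200 ms, and (in the extended variant) an HCN current; the
extended variant also adds low-density dendritic Na⁺/K⁺/M channels.
Singular rate expressions are evaluated through a numerically safe
`x / (exp(x) − 1)` primitive.

Synapses are conductance-based.  Excitatory synapses combine AMPA
(rise 0.1 ms, decay 2 ms) and NMDA (rise 2 ms, decay 75 ms) components
with NMDA/AMPA peak ratio γ = 2; inhibitory synapses are GABA_A
(rise 1 ms, decay 5 ms, reversal −75 mV).  The NMDA gate is
`σ(v) = 1 / (1 + C·e^{−ρv})` with `C = 1/3.75`, `ρ = 0.062 mV⁻¹`.

Model variants: `active` (full model), `passive` (no dendritic
voltage-gated channels and the NMDA gate clamped to 1, preserving the
synaptic conductance budget while removing its nonlinearity), `point`
(all synapses relocated electrically to the soma), and `extended`
(dendritic spiking channels).

## Numerical integration

The solver is a semi-implicit staggered scheme: gating variables are
advanced with exponential/implicit updates at half steps, and the
voltage system — linear once conductances are frozen — is solved
implicitly each step by Hines elimination on the tree (O(n) per step).
The scheme is first-order in `dt` (verified by Richardson extrapolation,
ratio 2.0) and unconditionally stable for the passive subsystem; if the
state still diverges (NaN/Inf at the soma), the solver raises an
`InstabilityError` naming the time of failure.  Somatic spikes are
detected as upward 0 mV crossings; the reported spike time is 2 ms
before the crossing (spike initiation), and the full voltage vector at
that moment is recorded.

## Exact synaptic gradients

For selected synapses the forward sensitivity system is integrated
alongside the model: differentiating the full dynamics with respect to a
synaptic weight yields a coupled linear system for
`∂v/∂w` and the sensitivities of all gating and kinetic states.  The
result, `∂v_soma(t)/∂w_k`, matches central finite differences to
better than 1% relative error (test suite).

For learning, only the 150 ms before a somatic spike matters.  Runs can
record compact state checkpoints every 10 ms; the *spike-window
gradient* replays the model from the checkpoint preceding the window
with action potentials blocked and one dummy single-spike synapse per
in-window activation, producing per-event gradient records
`(synapse, Δt, v_dend, g, …)` where `g` is the event's contribution to
the somatic depolarization at the spike, `Δt` the time from the event to
the spike, and `v_dend` the local dendritic voltage at the spike.
Synchrony covariates (`e_sync`, `i_sync`) count other excitatory and
inhibitory activations within 100 ms on the same branch.

## Plasticity kernels

A campaign of random constant-rate Poisson runs (lognormal per-synapse
rates, redrawn weights) collects gradient records around isolated
somatic spikes.  Records are binned on a grid of Δt ∈ (0, 100] ms × 
v_dend ∈ [−80, 0] mV (1 ms × 1 mV) per stratum (basal/apical ×
excitatory/inhibitory), and a polynomial surface of degree 8×8 (degree
9 with 10 coefficients for temporal-only kernels) is fitted by weighted
least squares on normalized coordinates, with zero padding along the
grid boundaries.  At evaluation, kernels are clamped to the correct
sign (E ≥ 0, I ≤ 0) and to zero outside the grid domain.  Fit quality
is reported as held-out R² at the grid and at the record level.

## Stimulus ensembles and tasks

A feature is a sparse activation pattern: each synapse is active with
probability `λ_pop/λ_syn` (population rate over active-synapse rate;
the default rate code uses 2.5/40 Hz = 1/16).  Active synapses fire
inhomogeneous Poisson spikes during the 400 ms stimulus window: a
constant rate for the rate code (K = 0), or K Gaussian bursts with
width `σ₀ · (λ̄T/K)` whose in-window mass is renormalized (truncated
Gaussian) so the ensemble conserves the expected total spike count
`N_syn · λ_pop · T` exactly for every (λ_syn, K) preset.  The optimal
burst preset uses λ_syn = 20 Hz, K = 1 (one 8-spike burst, σ = 20 ms).
Background activity runs at 1.25 Hz including a 100 ms pre-stimulus
interval.  An `n × n` association task pairs X and Y features over
synapse halves with binary labels; the nonlinear 2×2 uses XOR-like
labels.  Stimulus duration can be compressed with rates rescaled to
preserve per-presentation spike counts.  Structured placement routes
feature-specific synapses onto shared or disjoint sets of first-order
branches with a controllable overlap.

## Learning

Offline rule: at each somatic spike during a presentation, every
in-window synaptic activation contributes `K(Δt, v_dend)` and the weight
changes by `Δw = −α · Ē · Σ K`, clipped to [0, 0.01 μS], with
`α₀ = 2·10⁻⁶/λ_syn` and a `1/(1 + epoch/1125)` learning-rate decay.
`Ē` is the running signed error (mean of the last N binary outputs minus
the label); preferred patterns additionally receive a somatic teaching
current `β·|Ē|`.  An exact variant (`mode="direct"`) uses the replayed
gradients `g` in place of the kernel estimate.

Online rule: the supervisor maintains exponentially averaged estimates
of the output rate `r` (τ = 1000 ms) and of a continuous error `E_p`
(τ = 500 ms) driven by rate thresholds (0.1 and 5 spikes/s) against the
current label, with Euler updates; weight updates use the same kernel
rule gated by `E_p`.

## Analysis

`analysis` provides branch-level spatial/temporal/spatiotemporal input
profiles and their correlations across patterns, a summation
nonlinearity index (peak response to a feature pair divided by the sum
of single-feature peak responses), voltage-trace correlations, a
cross-validated logistic decoder for labels, and Wilcoxon summaries for
paired comparisons.
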