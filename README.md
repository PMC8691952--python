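# dendrite-credit

Compartmental-neuron simulation and learning with voltage-dependent
synaptic plasticity: how a single neuron with nonlinear dendrites can be
trained to solve association tasks that a point neuron cannot.

## Scientific background

Cortical pyramidal neurons are not point integrators.  NMDA-receptor
conductances make summation within a dendritic branch supralinear:
clustered, co-active synapses depolarize their branch, relieve the
voltage-dependent NMDA gate, and recruit extra inward current, so the
somatic response to two inputs on one branch exceeds the sum of their
individual responses.  This gives a single neuron a hidden nonlinear
layer — provided learning can discover synaptic weights that exploit it.

The central obstacle is credit assignment: when the soma spikes, how much
did each synapse contribute?  This package answers that question exactly
and approximately:

- **Exactly**, by integrating the forward sensitivity equations of the
  full compartmental model, yielding the gradient of the somatic voltage
  with respect to every synaptic weight (`variational`).
- **Approximately**, by distilling those gradients into *plasticity
  kernels* `K(Δt, v_dend)`: the expected contribution of a synaptic
  activation as a function of its timing relative to the somatic spike
  and of the local dendritic voltage at the spike (`kernels`).  Both
  quantities are locally available at the synapse, so the kernel rule is
  biologically plausible.

A supervised rule then updates weights only at somatic spikes,
`Δw = −α · Ē · Σ K(Δt, v_dend)`, where `Ē` is a running signed error of
the neuron's binary output against the target label (`learning`).  The
voltage argument is what routes credit to synapses on strongly
depolarized branches; a temporal-only kernel `K(Δt)` is blind to this
spatial component of the gradient.

## Package layout

| Module        | Contents |
|---------------|----------|
| `morphology`  | Tree geometries: SWC reading, synthetic trees, uniform cables, compartmentalization, axial coupling matrices |
| `biophysics`  | Membrane model (Hodgkin–Huxley soma, M-current, HCN, AMPA/NMDA/GABA synapses), semi-implicit solver, synapse placement |
| `variational` | Forward sensitivity system (exact per-synapse gradients), spike-window gradient replay from checkpoints |
| `kernels`     | Random-input campaigns, spike-triggered-average grids, polynomial kernel fitting, kernel diagnostics |
| `inputs`      | Stimulus ensembles (rate code, burst codes), association tasks, structured synapse placement, noise models |
| `learning`    | Offline and online supervised training loops, supervisor error dynamics |
| `analysis`    | Input profiles and correlations, summation nonlinearity, label decoding, statistics |
| `workbench`   | End-to-end experiment presets with manifests and a CLI |

## Worked example

```python
import numpy as np
from dendrite_credit import biophysics as B
from dendrite_credit import inputs as I
from dendrite_credit import kernels as K
from dendrite_credit import learning as L
from dendrite_credit import morphology as M

# A small tree: lumped soma, basal and apical branches.
geom = M.synthetic_tree(8, 4, depth=2, seed=0)

# Active membrane: spiking soma, NMDA synapses on the dendrites.
spec = B.BiophysicsSpec(mode="active")
layout = B.place_synapses(geom, n_exc=200, n_inh=50, seed=1)

# A 2x2 association task: two X features and two Y features, each a
# random sparse activation pattern; labels mark preferred pairings.
task = I.make_task(I.InputEnsembleSpec(n_syn=250), n=2,
                   nonlinear_2x2=True, seed=2)

# Fit plasticity kernels from a random-input campaign: simulate, collect
# exact per-synapse gradients around isolated somatic spikes, bin them
# by (timing, local voltage), and fit a polynomial surface per stratum.
records = K.random_input_campaign(geom, spec, layout, n_runs=10,
                                  run_length=3000.0, seed=0)
kernels = K.fit_all_kernels(records, seed=0)

# Train with the kernel rule and evaluate.
cfg = L.TrainConfig(epochs=100, beta=0.3)
trained, curve = L.train_offline(geom, spec, layout, task, cfg,
                                 seed=3, kernels=kernels)
p_test = L.evaluate(geom, spec, trained, task, n_reps=10, seed=4)
print(f"test performance: {p_test:.2f}")
```

Exact gradients are available directly:

```python
trains = task.realize(0, 0, seed=5)
rec = B.simulate(geom, spec, layout, trains, horizon=500.0,
                 record_dt=1.0, sens_syn=np.arange(5))
# rec.dv_soma[t, k] == d v_soma(t) / d w_k, validated against finite
# differences to <1% in the test suite.
```

The command-line interface mirrors the workbench presets:

```sh
dendrite-credit preset fig1_summation --out runs/fig1
dendrite-credit morph --basal 8 --apical 4 --depth 2 --out geom.json
```

## Units

Voltages in mV, time in ms, lengths in μm, conductances in μS (densities
in mS/cm²), currents in nA, capacitance in nF.  With these choices
nA/μS = mV and the solver works in ms⁻¹ rates throughout.

## Reproduction

```sh
pip install --no-build-isolation -e .
pytest                                   # unit + acceptance tests
python scripts/acceptance.py --seed 1 --out acceptance.json
```

`scripts/acceptance.py` runs the package's desk-scale computations
(gradient oracle, cable analytics, solver convergence, input-ensemble
statistics, kernel recovery, learning, online estimator dynamics) and
writes the key quantities as JSON.  All of it runs on one CPU in a few
minutes; larger experiment presets are exposed through
`dendrite_credit.workbench` with `scale="full"`.

See `docs/methods.md` for the numerical methods and model equations.
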