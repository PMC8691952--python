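"""Experiment presets: end-to-end pipelines at desk or full scale.

Each preset chains input generation, simulation, kernel fitting, training,
and analysis into a deterministic-by-seed pipeline, writing its outputs and
a manifest (config hash, package version, seeds, result summary) into a
directory.  Desk-scale presets use a synthetic morphology and reduced
replications so each completes in minutes on one CPU; full-scale presets
mirror the original protocols and are long-running.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import analysis, kernels as kmod, learning, inputs as imod
from .biophysics import BiophysicsSpec, SynapseLayout, place_synapses
from .morphology import (DOMAIN_APICAL, DOMAIN_BASAL, Geometry,
                         synthetic_tree)

PRESET_NAMES = ("fig1_summation", "fig2_kernels", "fig3_2x2", "fig5_sweep",
                "fig7_duration", "online", "structured",
                "extended_conductances")


@dataclass
class ExperimentPreset:
    name: str
    scale: str = "desk"          # "desk" or "full"
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in PRESET_NAMES:
            raise ValueError(f"unknown preset {self.name!r}; "
                             f"choose from {PRESET_NAMES}")
        if self.scale not in ("desk", "full"):
            raise ValueError("scale must be 'desk' or 'full'")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def desk_assets(seed: int, n_e: int = 200, n_i: int = 50,
                mode: str = "active"):
    """Shared desk-scale geometry, spec, and layout."""
    geom = synthetic_tree(8, 4, depth=2, seed=seed)
    spec = BiophysicsSpec(mode=mode)
    layout = place_synapses(geom, n_e, n_i, seed=seed + 1)
    return geom, spec, layout


def _desk_kernels(geom, spec, layout, seed, n_runs=30, run_length=3000.0,
                  temporal_only=False):
    records = kmod.random_input_campaign(geom, spec, layout, n_runs=n_runs,
                                         run_length=run_length, seed=seed)
    return kmod.fit_all_kernels(records, temporal_only=temporal_only,
                                seed=seed), records


def _write(out_dir: Path, name: str, obj) -> str:
    path = out_dir / name
    if isinstance(obj, pd.DataFrame):
        obj.to_csv(path, index=False)
    else:
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2, default=_jsonable)
    return str(path)


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")


def run_preset(preset: ExperimentPreset | str, out_dir,
               overrides: dict | None = None) -> dict:
    """Execute a preset; returns (and writes) its manifest.

    Re-running a completed preset with an unchanged configuration is a
    no-op that returns the stored manifest.
    """
    if isinstance(preset, str):
        preset = ExperimentPreset(name=preset)
    if overrides:
        preset = ExperimentPreset(name=preset.name, scale=preset.scale,
                                  seed=preset.seed,
                                  params={**preset.params, **overrides})
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.json"
    if manifest_path.exists():
        with open(manifest_path) as fh:
            old = json.load(fh)
        if old.get("config_hash") == preset.config_hash() \
                and old.get("status") == "complete":
            return old
    t0 = time.time()
    runner = _RUNNERS[preset.name]
    results, artifacts = runner(preset, out_dir)
    manifest = dict(
        name=preset.name, scale=preset.scale, seed=preset.seed,
        params=preset.params, config_hash=preset.config_hash(),
        version=__version__, status="complete",
        runtime_s=round(time.time() - t0, 2),
        results=results, artifacts=artifacts,
    )
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=_jsonable)
    return manifest


# ---------------------------------------------------------------------------
# preset runners (desk defaults; params override sizes)

def _p(preset, key, default):
    return preset.params.get(key, default)


def _run_fig1(preset, out_dir):
    """Summation nonlinearity of the three model variants."""
    seed = preset.seed
    geom, _, layout = desk_assets(seed)
    spec_in = imod.InputEnsembleSpec(n_syn=layout.n_syn, lam_syn=40.0)
    task = imod.make_task(spec_in, 2, True, seed=seed + 2)
    n_reps = _p(preset, "n_reps", 5)
    ratios = {}
    for mode in ("active", "passive", "point"):
        spec = BiophysicsSpec(mode=mode)
        nl = analysis.summation_nonlinearity(
            geom, spec, layout, task, (0, 0),
            DOMAIN_BASAL if mode != "point" else DOMAIN_BASAL,
            n_reps=n_reps, seed=seed + 3)
        ratios[mode] = nl.ratio
    results = dict(ratios=ratios,
                   ordering_ok=bool(ratios["active"] > ratios["passive"]))
    return results, [_write(out_dir, "ratios.json", ratios)]


def _run_fig2(preset, out_dir):
    """Random-input campaign and kernel fits with held-out R^2."""
    seed = preset.seed
    geom, spec, layout = desk_assets(seed, n_e=_p(preset, "n_e", 400),
                                     n_i=_p(preset, "n_i", 100))
    ks, records = _desk_kernels(geom, spec, layout, seed,
                                n_runs=_p(preset, "n_runs", 30),
                                run_length=_p(preset, "run_length", 3000.0))
    r2 = {kmod.stratum_name(d, e): k.r2_holdout for (d, e), k in ks.items()}
    kpath = out_dir / "kernels.json"
    kmod.save_kernels(ks, kpath)
    arts = [str(kpath), _write(out_dir, "records.csv", records)]
    return dict(r2_holdout=r2, n_records=len(records)), arts


def _run_fig3(preset, out_dir):
    """2x2 rate-code association task across model variants."""
    seed = preset.seed
    results = {}
    curves = []
    for mode in _p(preset, "modes", ["active", "passive", "point"]):
        geom, spec, layout = desk_assets(seed, mode=mode)
        spec_in = imod.InputEnsembleSpec(n_syn=layout.n_syn, lam_syn=40.0)
        task = imod.make_task(spec_in, 2, True, seed=seed + 2)
        ks, _ = _desk_kernels(geom, spec, layout, seed + 3,
                              n_runs=_p(preset, "kernel_runs", 20))
        cfg = learning.TrainConfig(epochs=_p(preset, "epochs", 150),
                                   alpha0=_p(preset, "alpha0", None))
        trained, curve = learning.train_offline(geom, spec, layout, task,
                                                cfg, seed=seed + 4,
                                                kernels=ks)
        p_test = learning.evaluate(geom, spec, trained, task,
                                   n_reps=_p(preset, "test_reps", 10),
                                   seed=seed + 5)
        curve["mode"] = mode
        curves.append(curve)
        results[mode] = dict(p_test=p_test,
                             final_error=float(curve["total_error"].iloc[-1]))
    arts = [_write(out_dir, "curves.csv", pd.concat(curves))]
    return results, arts


def _run_fig5(preset, out_dir):
    """Multi-association sweep across input conditions."""
    seed = preset.seed
    n = _p(preset, "n", 3)
    results = {}
    for cond in _p(preset, "conditions", ["rate", "burst"]):
        geom, spec, layout = desk_assets(seed)
        if cond == "rate":
            spec_in = imod.InputEnsembleSpec(n_syn=layout.n_syn, lam_syn=40.0)
        else:
            spec_in = imod.optimal_burst_spec(n_syn=layout.n_syn)
        task = imod.make_task(spec_in, n, False, seed=seed + 2)
        ks, _ = _desk_kernels(geom, spec, layout, seed + 3,
                              n_runs=_p(preset, "kernel_runs", 20))
        cfg = learning.TrainConfig(epochs=_p(preset, "epochs", 100))
        trained, _curve = learning.train_offline(geom, spec, layout, task,
                                                 cfg, seed=seed + 4,
                                                 kernels=ks)
        p = learning.evaluate(geom, spec, trained, task,
                              n_reps=_p(preset, "test_reps", 5),
                              seed=seed + 5)
        results[cond] = p
    return results, [_write(out_dir, "ptest.json", results)]


def _run_fig7(preset, out_dir):
    """Duration-compression sweep on the burst code."""
    seed = preset.seed
    geom, spec, layout = desk_assets(seed)
    spec_in = imod.optimal_burst_spec(n_syn=layout.n_syn)
    base = imod.make_task(spec_in, 2, True, seed=seed + 2)
    ks, _ = _desk_kernels(geom, spec, layout, seed + 3,
                          n_runs=_p(preset, "kernel_runs", 20))
    cfg = learning.TrainConfig(epochs=_p(preset, "epochs", 80))
    results = {}
    for t_new in _p(preset, "durations", [400.0, 100.0]):
        task = imod.compress_duration(base, t_new)
        trained, _ = learning.train_offline(geom, spec, layout, task, cfg,
                                            seed=seed + 4, kernels=ks)
        results[str(t_new)] = learning.evaluate(
            geom, spec, trained, task, n_reps=_p(preset, "test_reps", 5),
            seed=seed + 5)
    return results, [_write(out_dir, "ptest.json", results)]


def _run_online(preset, out_dir):
    seed = preset.seed
    geom, spec, layout = desk_assets(seed)
    spec_in = imod.InputEnsembleSpec(n_syn=layout.n_syn, lam_syn=40.0,
                                     lam_bg=1.25)
    task = imod.make_task(spec_in, 2, True, seed=seed + 2)
    ks, _ = _desk_kernels(geom, spec, layout, seed + 3,
                          n_runs=_p(preset, "kernel_runs", 20))
    cfg = learning.TrainConfig()
    trained, log = learning.train_online(
        geom, spec, layout, task, cfg, kernels=ks,
        t_train=_p(preset, "t_train", 1500.0),
        n_presentations=_p(preset, "n_presentations", 20), seed=seed + 4)
    results = dict(n_presentations=int(len(log)),
                   mean_rate=float(log["r_final"].mean()))
    return results, [_write(out_dir, "online_log.csv", log)]


def _run_structured(preset, out_dir):
    seed = preset.seed
    geom, spec, layout = desk_assets(seed)
    spec_in = imod.InputEnsembleSpec(n_syn=layout.n_syn, lam_syn=40.0)
    task = imod.make_task(spec_in, 2, True, seed=seed + 2)
    results = {}
    for ov in _p(preset, "overlaps", [0.0, 1.0]):
        lay = imod.structured_placement(geom, task, layout, overlap=ov,
                                        model="active", seed=seed + 3)
        r = analysis.pair_profile_correlation(task, lay, geom, (0, 0),
                                              "spatial", DOMAIN_BASAL, "EE")
        results[str(ov)] = r
    return results, [_write(out_dir, "correlations.json", results)]


def _run_extended(preset, out_dir):
    """Kernel fit quality for the extended (dendritic-spike) variant."""
    seed = preset.seed
    geom, spec, layout = desk_assets(seed, n_e=_p(preset, "n_e", 400),
                                     n_i=_p(preset, "n_i", 100),
                                     mode="extended")
    ks, records = _desk_kernels(geom, spec, layout, seed,
                                n_runs=_p(preset, "n_runs", 30))
    r2 = {kmod.stratum_name(d, e): k.r2_holdout for (d, e), k in ks.items()}
    return dict(r2_holdout=r2, n_records=len(records)), \
        [_write(out_dir, "r2.json", r2)]


_RUNNERS = {
    "fig1_summation": _run_fig1,
    "fig2_kernels": _run_fig2,
    "fig3_2x2": _run_fig3,
    "fig5_sweep": _run_fig5,
    "fig7_duration": _run_fig7,
    "online": _run_online,
    "structured": _run_structured,
    "extended_conductances": _run_extended,
}
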