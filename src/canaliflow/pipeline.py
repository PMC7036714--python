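"""End-to-end orchestration: simulate -> quantify -> biophysics -> fit ->
predict -> report.

Stages communicate only through files inside a run directory, every
random draw derives from the seeds recorded in the manifest, and a rerun
with the same configuration reproduces the manifest checksums bit for
bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import biophysics as bp
from . import hippo
from . import image_quant as iq
from . import fitting
from .synthetic import (LobulePhantomSpec, TimeCourseSpec, write_fixtures,
                        generate_stimulus_trajectory, asdict_params)

__all__ = ["PipelineConfig", "run_pipeline", "report"]

log = logging.getLogger("canaliflow")
if not log.handlers:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(levelname)s %(message)s",
        datefmt="%Y-%m-%dT%H:%M:%S"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

STAGES = ("simulate", "quantify", "biophysics", "fit", "predict")


@dataclass
class PipelineConfig:
    """Single configuration object with per-stage blocks."""

    seed: int = 0
    resection_fraction: float = 0.68
    stages: tuple = STAGES
    # demo-sized phantom: large enough for 18 diameter zones, small
    # enough for an interactive run
    stack_shape: tuple = (32, 48, 260)
    n_zones_diameter: int = 18
    n_zones_intensity: int = 10
    noise_cv: float = 0.1
    fit_n_starts: int = 8
    inputs: dict = field(default_factory=dict)   # pre-existing input paths

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        if "stack_shape" in raw:
            raw["stack_shape"] = tuple(raw["stack_shape"])
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _record(manifest, stage, out: Path, files) -> None:
    manifest["stages"][stage] = {
        f.name: _sha256(f) for f in sorted(files)}


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Run the configured stages into ``out_dir``; returns the run dir.

    Referenced input paths are validated before any stage runs; a stage
    failure halts the pipeline with the stage name after writing the
    partial manifest.
    """
    run = Path(out_dir)
    run.mkdir(parents=True, exist_ok=True)
    for name, path in config.inputs.items():
        if not Path(path).exists():
            raise FileNotFoundError(f"input {name!r} not found: {path}")
    manifest = {"version": __version__, "seed": config.seed,
                "config": {**asdict(config),
                           "stack_shape": list(config.stack_shape),
                           "stages": list(config.stages)},
                "stages": {}}
    state: dict = {}
    try:
        for stage in config.stages:
            log.info("stage %s", stage)
            files = _STAGE_FUNCS[stage](config, run, state)
            _record(manifest, stage, run, files)
    except Exception:
        (run / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True))
        raise
    (run / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))
    return run


def _stage_simulate(config, run, state):
    phantom = LobulePhantomSpec(stack_shape=config.stack_shape,
                                n_zones=config.n_zones_diameter,
                                shot_noise=1.0, read_noise=2.0,
                                n_nuclei=60, seed=config.seed)
    tc = TimeCourseSpec(noise_cv=config.noise_cv,
                        resection_fraction=config.resection_fraction,
                        seed=config.seed + 1)
    write_fixtures(run / "sim", {"phantom": phantom, "timecourse": tc})
    traj = generate_stimulus_trajectory(
        config.resection_fraction,
        t_grid=np.asarray(tc.time_points)[np.asarray(tc.time_points) > 0])
    traj.to_csv(run / "sim" / "stimulus.csv", index=False)
    state["phantom_spec"] = phantom
    state["timecourse_spec"] = tc
    return list((run / "sim").iterdir())


def _stage_quantify(config, run, state):
    import tifffile
    sim = run / "sim"
    for required in ("phantom_bc.tif", "phantom_nuclei.tif",
                     "phantom_marker.tif"):
        if not (sim / required).exists():
            raise FileNotFoundError(f"quantify: missing {sim / required}")
    spec = state.get("phantom_spec") or LobulePhantomSpec(
        stack_shape=config.stack_shape, n_zones=config.n_zones_diameter)
    bc = tifffile.imread(sim / "phantom_bc.tif").astype(float)
    nuc = tifffile.imread(sim / "phantom_nuclei.tif").astype(float)
    marker = tifffile.imread(sim / "phantom_marker.tif").astype(float)
    seg = iq.segment_bc(bc, voxel_size=spec.voxel_size)
    diam = iq.measure_bc_diameter(seg, spec.cv_landmark, spec.pv_landmark,
                                  n_zones=config.n_zones_diameter,
                                  voxel_size=spec.voxel_size)
    nucprof = iq.measure_nuclear_intensity(
        nuc, nuc, spec.cv_landmark, spec.pv_landmark,
        n_zones=config.n_zones_intensity, voxel_size=spec.voxel_size)
    apical, apical_prof = iq.measure_apical_intensity(
        seg.mask, marker, voxel_size=spec.voxel_size,
        cv_landmark=spec.cv_landmark, pv_landmark=spec.pv_landmark,
        n_zones=config.n_zones_intensity)
    out = run / "quant"
    out.mkdir(exist_ok=True)
    diam.to_csv(out / "bc_diameter.csv")
    nucprof.to_csv(out / "nuclear_intensity.csv")
    apical_prof.to_csv(out / "apical_intensity.csv")
    (out / "apical_scalar.json").write_text(
        json.dumps({"apical_intensity": apical}))
    state["diameter_profile"] = diam
    return list(out.iterdir())


def _stage_biophysics(config, run, state):
    fold, mean, tp = bp.regeneration_tension_fold(config.resection_fraction)
    baseline = bp.CanalicularNetworkModel.baseline()
    pressure = bp.solve_pressure(replace(
        baseline,
        diameter_um=np.linspace(*bp.POST_PH_1P5D_DIAMETER_RANGE_UM,
                                baseline.n_zones),
        liver_mass_fraction=1.0 - config.resection_fraction))
    out = run / "biophysics"
    out.mkdir(exist_ok=True)
    pd.DataFrame({
        "zone": np.arange(1, baseline.n_zones + 1),
        "pressure_pa": pressure.pressure,
        "tension_n_per_m": tp.tension,
        "strain": tp.strain,
        "stimulus": tp.stimulus,
    }).to_csv(out / "tension.csv", index=False)
    (out / "summary.json").write_text(json.dumps(
        {"mean_tension_fold": mean,
         "cv_pv_pressure_ratio": bp.solve_pressure(baseline).cv_pv_ratio},
        indent=1, sort_keys=True))
    state["tension_fold"] = fold
    return list(out.iterdir())


def _stage_fit(config, run, state):
    data_csv = run / "sim" / "timecourse_yap_data.csv"
    stim_csv = run / "sim" / "stimulus.csv"
    for f in (data_csv, stim_csv):
        if not f.exists():
            raise FileNotFoundError(f"fit: missing {f}")
    ds = fitting.MeasurementDataSet.from_csv(data_csv)
    traj = pd.read_csv(stim_csv)
    cfg = fitting.FitConfig(n_starts=config.fit_n_starts,
                            seed=config.seed + 2)
    result = fitting.fit(ds, cfg, hippo.HippoParams.reference(),
                         fitting.row_stimuli(ds, traj))
    out = run / "fit"
    out.mkdir(exist_ok=True)
    (out / "fit.json").write_text(json.dumps({
        "free_values": result.free_values,
        "objective": result.objective,
        "success": result.success,
        "threshold": result.threshold.value if result.threshold else None,
        "threshold_alternatives": result.threshold.alternatives
        if result.threshold else {},
        "hill": result.curve.hill if result.curve else None,
        "n_starts": len(result.starts),
        "n_converged": sum(r["converged"] for r in result.starts),
    }, indent=1, sort_keys=True))
    state["fit_result"] = result
    return list(out.iterdir())


def _stage_predict(config, run, state):
    result = state.get("fit_result")
    params = result.params if result is not None \
        else hippo.HippoParams.reference()
    curve = hippo.stimulus_response(params)
    thr = hippo.activation_threshold(curve)
    out = run / "predict"
    out.mkdir(exist_ok=True)
    pd.DataFrame({"stimulus": curve.stimulus, "nuclear": curve.nuclear,
                  "total": curve.total}).to_csv(
        out / "stimulus_response.csv", index=False)
    (out / "threshold.json").write_text(json.dumps(
        {"threshold": thr.value, "method": thr.method,
         "alternatives": thr.alternatives, "hill": curve.hill},
        indent=1, sort_keys=True))
    _plot_curve(curve, thr, out / "stimulus_response.png")
    return list(out.iterdir())


def _plot_curve(curve, thr, path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(5, 3.5))
    sel = curve.stimulus <= 4
    ax.plot(curve.stimulus[sel], curve.nuclear[sel], "k-",
            label="nuclear YAP")
    ax.plot(curve.stimulus[sel], curve.total[sel], "b--", label="total YAP")
    if thr.value is not None:
        ax.axvline(thr.value, color="r", ls=":",
                   label=f"threshold {thr.value:.2f}")
    ax.set_xlabel("relative mechanical stimulus (fold)")
    ax.set_ylabel("normalized YAP")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120, metadata={"Software": "canaliflow"})
    plt.close(fig)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "quantify": _stage_quantify,
    "biophysics": _stage_biophysics,
    "fit": _stage_fit,
    "predict": _stage_predict,
}


def report(run_dir) -> str:
    """Human-readable summary of a run directory.

    Byte-identical across repeated calls on the same run directory; an
    incomplete run yields a partial report that is flagged as such.
    """
    run = Path(run_dir)
    manifest_path = run / "manifest.json"
    lines = [f"canaliflow run report: {run.name}", "=" * 40]
    complete = manifest_path.exists()
    manifest = json.loads(manifest_path.read_text()) if complete else {}
    done = set(manifest.get("stages", {}))
    missing = [s for s in STAGES if s not in done]
    if missing:
        lines.append(f"PARTIAL RUN - missing stages: {', '.join(missing)}")
    lines.append(f"seed: {manifest.get('seed', 'unknown')}")
    bio = run / "biophysics" / "summary.json"
    if bio.exists():
        s = json.loads(bio.read_text())
        lines.append(f"mean apical tension fold-change: "
                     f"{s['mean_tension_fold']:.3f}")
        lines.append(f"CV:PV pressure ratio: "
                     f"{s['cv_pv_pressure_ratio']:.1f}")
    quant = run / "quant" / "bc_diameter.csv"
    if quant.exists():
        df = pd.read_csv(quant)
        inc = df[(df["excluded"] == 0) & df["value"].notna()]
        lines.append(f"BC diameter (included zones): "
                     f"{inc['value'].min():.2f}-{inc['value'].max():.2f} um")
    fitj = run / "fit" / "fit.json"
    if fitj.exists():
        f = json.loads(fitj.read_text())
        lines.append(f"fit objective: {f['objective']:.4g} "
                     f"({f['n_converged']}/{f['n_starts']} starts converged)")
        if f.get("threshold") is not None:
            lines.append(f"activation threshold (tangent): "
                         f"{f['threshold']:.3f}-fold")
    predj = run / "predict" / "threshold.json"
    if predj.exists():
        p = json.loads(predj.read_text())
        lines.append(f"stimulus-response effective Hill coefficient: "
                     f"{p['hill']:.2f}")
        alts = {k: (f"{v:.3f}" if v is not None else "n/a")
                for k, v in p.get("alternatives", {}).items()}
        lines.append(f"threshold by method: {alts}")
    text = "\n".join(lines) + "\n"
    (run / "report.txt").write_text(text)
    return text
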