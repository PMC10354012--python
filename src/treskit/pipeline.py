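"""Declarative end-to-end runs: simulate -> analyze -> fit -> report.

A run configuration (YAML or JSON) names a sequence of stages, each with a
kind from the stage registry and a parameter map.  Stage seeds derive
deterministically from the master seed and the stage position, so partial
re-runs and replicate-count changes are reproducible.  Every produced file
is checksummed into the run manifest; identical configurations and seeds
yield identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Mapping

import pandas as pd
import yaml

from . import coupling, ephys, permeation
from .simulate import (
    CouplingSpec,
    DoseResponseModelSpec,
    PermeationModelConfig,
    m4_sf_coupling_spec,
    rb_config,
    simulate_displacements,
    simulate_dose_response,
    simulate_sf_permeation,
    t322a_config,
    wt_config,
)

__all__ = ["RunConfig", "RunReport", "run_pipeline", "make_demo_dataset", "fig7_like_config"]

log = logging.getLogger("treskit.pipeline")


@dataclass(frozen=True)
class StageSpec:
    name: str
    kind: str
    params: Mapping[str, Any] = field(default_factory=dict)


@dataclass(frozen=True)
class RunConfig:
    stages: tuple[StageSpec, ...]
    seed: int = 0
    outdir: Path = Path("run")

    @classmethod
    def from_dict(cls, payload: Mapping[str, Any]) -> "RunConfig":
        stages = tuple(
            StageSpec(name=s["name"], kind=s["kind"], params=dict(s.get("params", {})))
            for s in payload.get("stages", [])
        )
        return cls(
            stages=stages,
            seed=int(payload.get("seed", 0)),
            outdir=Path(payload.get("outdir", "run")),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        payload = yaml.safe_load(text)
        return cls.from_dict(payload)


@dataclass
class RunReport:
    master_seed: int
    stages: list[dict]
    manifest: dict[str, str]  # relative path -> sha256

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "master_seed": self.master_seed,
                    "stages": self.stages,
                    "manifest": self.manifest,
                },
                indent=1,
                default=str,
            )
        )


class _Context:
    def __init__(self, outdir: Path, seed: int):
        self.outdir = outdir
        self.seed = seed
        self.artifacts: dict[str, dict[str, Path]] = {}

    def artifact(self, stage: str, key: str = "main") -> Path:
        try:
            return self.artifacts[stage][key]
        except KeyError:
            raise KeyError(f"stage {stage!r} produced no artifact {key!r}") from None


def _permeation_config(params: Mapping[str, Any], seed: int) -> PermeationModelConfig:
    preset = params.get("preset", "wt")
    overrides = {
        k: v
        for k, v in params.items()
        if k not in ("preset", "input", "inner_scale")
    }
    overrides["seed"] = seed
    if preset == "wt":
        return wt_config(**overrides)
    if preset == "t322a":
        return t322a_config(params.get("inner_scale", 0.25), **overrides)
    if preset == "rb_wt":
        return rb_config("WT", **overrides)
    if preset == "rb_t322a":
        return rb_config("T322A", **overrides)
    raise ValueError(f"unknown permeation preset {preset!r}")


def _stage_simulate_permeation(ctx, stage, seed):
    config = _permeation_config(stage.params, seed)
    run = simulate_sf_permeation(config)
    path = ctx.outdir / f"{stage.name}.csv"
    run.write_csv(path)
    log.info(
        "stage %s: %d series, %d replicates, variant %s/%s",
        stage.name, len(run.series), config.n_replicates, config.variant, config.species,
    )
    return {"main": path}


def _stage_occupancy(ctx, stage, seed):
    series = permeation.read_ion_distance_table(ctx.artifact(stage.params["input"]))
    retained, report = permeation.apply_sf_exclusion(
        series,
        threshold=stage.params.get("threshold", 5.0),
        s4_offset=stage.params.get("s4_offset", permeation.DEFAULT_SITE_MAP["S4"]),
    )
    hist = permeation.compute_occupancy_histogram(
        retained,
        n_bins=stage.params.get("bins", 50),
        value_range=tuple(stage.params.get("range", (0.0, 16.0))),
        label=stage.name,
    )
    path = ctx.outdir / f"{stage.name}.tsv"
    hist.write_tsv(path)
    rpath = ctx.outdir / f"{stage.name}_exclusion.json"
    rpath.write_text(
        json.dumps(
            {"n_retained": report.n_retained, "n_excluded": report.n_excluded,
             "threshold_A": report.threshold_A},
            indent=1,
        )
    )
    log.info("stage %s: %d retained / %d excluded records (threshold %.2f A, %d bins)",
             stage.name, report.n_retained, report.n_excluded, report.threshold_A,
             stage.params.get("bins", 50))
    return {"main": path, "exclusion": rpath}


def _stage_delta(ctx, stage, seed):
    a = permeation.read_occupancy_tsv(ctx.artifact(stage.params["input_a"]))
    b = permeation.read_occupancy_tsv(ctx.artifact(stage.params["input_b"]))
    delta = permeation.compare_occupancy(a, b)
    path = ctx.outdir / f"{stage.name}.tsv"
    delta.write_tsv(path)
    return {"main": path}


def _stage_transitions(ctx, stage, seed):
    series = permeation.read_ion_distance_table(ctx.artifact(stage.params["input"]))
    inner_role = max(s.role for s in series)
    tables = [
        permeation.detect_transitions(
            s, hysteresis=stage.params.get("hysteresis", 0.5)
        )
        for s in series
        if s.role == inner_role
    ]
    summary = permeation.summarize_permeation(tables)
    path = ctx.outdir / f"{stage.name}.json"
    path.write_text(json.dumps(summary.to_json_dict(), indent=1))
    return {"main": path}


def _stage_simulate_displacements(ctx, stage, seed):
    spec = m4_sf_coupling_spec(
        coupling=stage.params.get("coupling", 0.8),
        n_frames=stage.params.get("n_frames", 5000),
        noise_sd=stage.params.get("noise_sd", 0.3),
        seed=seed,
    )
    series = simulate_displacements(spec)
    path = ctx.outdir / f"{stage.name}.tsv"
    series.write_tsv(path)
    return {"main": path}


def _stage_dccm(ctx, stage, seed):
    series = coupling.read_displacement_table(ctx.artifact(stage.params["input"]))
    dccm = coupling.compute_dccm(series)
    mpath = ctx.outdir / f"{stage.name}.tsv"
    ipath = ctx.outdir / f"{stage.name}.png"
    coupling.export_heatmap(dccm, mpath, ipath)
    return {"main": mpath, "heatmap": ipath}


def _stage_simulate_dose_response(ctx, stage, seed):
    spec_kw = dict(stage.params.get("model", {}))
    spec_kw["seed"] = seed
    spec = DoseResponseModelSpec(**spec_kw)
    df = simulate_dose_response(
        spec,
        concentrations=stage.params.get("concentrations", (0.1, 1, 10, 30, 100, 300)),
        n_replicates=stage.params.get("n_replicates", 5),
        construct=stage.params.get("construct", "WT"),
    )
    path = ctx.outdir / f"{stage.name}.csv"
    df.to_csv(path, index=False)
    return {"main": path}


def _stage_fit_hill(ctx, stage, seed):
    df = pd.read_csv(ctx.artifact(stage.params["input"]))
    fit = ephys.fit_hill(df)
    path = ctx.outdir / f"{stage.name}.json"
    path.write_text(
        json.dumps(
            {
                "e_max": fit.e_max, "ec50": fit.ec50, "h": fit.h,
                "se_e_max": fit.se_e_max, "se_ec50": fit.se_ec50, "se_h": fit.se_h,
                "residual_ss": fit.residual_ss, "converged": fit.converged,
            },
            indent=1,
        )
    )
    log.info("stage %s: EC50 %.3g uM, E_max %.3g %%, h %.3g",
             stage.name, fit.ec50, fit.e_max, fit.h)
    return {"main": path}


STAGE_KINDS: dict[str, Callable] = {
    "simulate_permeation": _stage_simulate_permeation,
    "occupancy": _stage_occupancy,
    "delta": _stage_delta,
    "transitions": _stage_transitions,
    "simulate_displacements": _stage_simulate_displacements,
    "dccm": _stage_dccm,
    "simulate_dose_response": _stage_simulate_dose_response,
    "fit_hill": _stage_fit_hill,
}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the configured stages in order, halting downstream on failure.

    Unknown stage kinds and dangling stage references are rejected before
    anything runs.  Stage *i* uses seed ``master_seed + i``.
    """
    names = set()
    for i, stage in enumerate(config.stages):
        if stage.kind not in STAGE_KINDS:
            raise ValueError(f"unknown stage kind {stage.kind!r} in stage {stage.name!r}")
        if stage.name in names:
            raise ValueError(f"duplicate stage name {stage.name!r}")
        for key in ("input", "input_a", "input_b"):
            ref = stage.params.get(key)
            if ref is not None and ref not in names:
                raise ValueError(
                    f"stage {stage.name!r} references {ref!r} before it is produced"
                )
        names.add(stage.name)

    config.outdir.mkdir(parents=True, exist_ok=True)
    ctx = _Context(config.outdir, config.seed)
    report = RunReport(master_seed=config.seed, stages=[], manifest={})
    failed = False
    for i, stage in enumerate(config.stages):
        entry = {
            "name": stage.name,
            "kind": stage.kind,
            "params": dict(stage.params),
            "seed": config.seed + i,
        }
        if failed:
            entry["status"] = "skipped"
            report.stages.append(entry)
            continue
        try:
            outputs = STAGE_KINDS[stage.kind](ctx, stage, config.seed + i)
            ctx.artifacts[stage.name] = outputs
            entry["status"] = "ok"
            entry["outputs"] = {k: str(v) for k, v in outputs.items()}
            for p in outputs.values():
                report.manifest[str(Path(p).relative_to(config.outdir))] = _sha256(Path(p))
        except Exception as exc:  # halt downstream, keep the partial report
            entry["status"] = "failed"
            entry["error"] = f"{type(exc).__name__}: {exc}"
            failed = True
        report.stages.append(entry)
    report.write(config.outdir / "report.json")
    return report


def fig7_like_config(outdir: str | Path, seed: int = 0, duration_ns: float = 30.0) -> RunConfig:
    """Demo run: wild-type and inner-filter-slowed occupancy, delta, transitions."""
    common = {"duration_ns": duration_ns, "n_replicates": 3}
    return RunConfig(
        seed=seed,
        outdir=Path(outdir),
        stages=(
            StageSpec("traj_wt", "simulate_permeation", {"preset": "wt", **common}),
            StageSpec("traj_mut", "simulate_permeation", {"preset": "t322a", **common}),
            StageSpec("occ_wt", "occupancy", {"input": "traj_wt"}),
            StageSpec("occ_mut", "occupancy", {"input": "traj_mut"}),
            StageSpec("delta_mut_wt", "delta", {"input_a": "occ_wt", "input_b": "occ_mut"}),
            StageSpec("transitions_wt", "transitions", {"input": "traj_wt"}),
        ),
    )


def make_demo_dataset(kind: str, seed: int, outdir: str | Path) -> list[Path]:
    """Write small seeded fixture files for tests and documentation.

    Kinds: ``permeation`` (short 3-replicate trajectory table), ``dccm``
    (block-coupled displacement table), ``screening`` / ``dose_response`` /
    ``inactivation`` (TEVC sweeps plus protocol JSON).
    """
    from .protocols import build_protocol_schedule
    from .simulate.tevc import EphysSimConfig, simulate_tevc_recording

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if kind == "permeation":
        run = simulate_sf_permeation(wt_config(duration_ns=10.0, n_replicates=1, seed=seed))
        path = outdir / "permeation_demo.csv"
        run.write_csv(path)
        return [path]
    if kind == "dccm":
        series = simulate_displacements(m4_sf_coupling_spec(n_frames=2000, seed=seed))
        path = outdir / "displacements_demo.tsv"
        series.write_tsv(path)
        return [path]
    if kind in ("screening", "dose_response", "inactivation"):
        schedule = build_protocol_schedule(kind)
        config = EphysSimConfig(schedule=schedule, sample_interval_ms=5.0, seed=seed)
        sweeps = simulate_tevc_recording(config)
        spath = outdir / f"{kind}_sweeps.csv"
        ppath = outdir / f"{kind}_protocol.json"
        sweeps.write_csv(spath)
        schedule.to_json(ppath)
        return [spath, ppath]
    raise ValueError(f"unknown demo dataset kind {kind!r}")
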