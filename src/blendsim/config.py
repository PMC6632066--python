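"""Run configuration and staged workflow execution.

A YAML/JSON config selects stages of the workflow (risk scoring,
response-surface fitting, operating-space mapping, calibration, the
blending demo) and supplies their inputs; ``run_workflow`` executes the
requested stages in dependency order and writes a provenance manifest
(seeds, inputs, per-stage outputs).  Every stochastic stage derives its
seed from the global seed plus a fixed stage offset so a config is
exactly reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = ["RunConfig", "run_workflow"]

STAGES = ("risk", "doe", "ospace", "calibrate", "blend")
_STAGE_SEED_OFFSET = {s: 1000 + 17 * k for k, s in enumerate(STAGES)}


class ConfigError(ValueError):
    """Invalid run configuration; message names the offending field."""


@dataclass
class RunConfig:
    """Validated workflow configuration."""

    stages: list[str]
    seed: int = 0
    out_dir: str = "runs"
    risk: dict = field(default_factory=dict)
    doe: dict = field(default_factory=dict)
    ospace: dict = field(default_factory=dict)
    calibrate: dict = field(default_factory=dict)
    blend: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for s in self.stages:
            if s not in STAGES:
                raise ConfigError(f"stages: unknown stage {s!r}")
        if "ospace" in self.stages and "doe" not in self.stages:
            raise ConfigError("stages: 'ospace' requires the 'doe' stage")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        known = {"stages", "seed", "out_dir", *STAGES}
        for key in raw:
            if key not in known:
                raise ConfigError(f"unknown config field {key!r}")
        return cls(**raw)

    def stage_seed(self, stage: str) -> int:
        return int(self.seed) + _STAGE_SEED_OFFSET[stage]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_workflow(config: RunConfig) -> dict:
    """Execute the configured stages; returns the provenance manifest."""
    from . import __version__, fixtures
    from .operating_space import PerturbationModel, operating_space_map
    from .risk import pareto_summary, score_register
    from .rsm import SpecLimits, fit_rsm

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}}
    artifacts: dict = {}

    if "risk" in config.stages:
        entries = fixtures.reference_register()
        conf = config.risk.get("confidence", 0.90)
        scored = score_register(entries)
        pareto = pareto_summary(entries, confidence=conf)
        scored.to_csv(out / "risk_scored.csv", index=False)
        pareto.to_csv(out / "risk_pareto.csv", index=False)
        manifest["stages"]["risk"] = dict(
            rows=len(scored), high=int((scored["level"] == "high").sum()),
            threshold=pareto.attrs["threshold"],
            outputs=["risk_scored.csv", "risk_pareto.csv"],
        )
        artifacts["risk"] = scored

    if "doe" in config.stages:
        runs = fixtures.reference_runs()
        factors = fixtures.reference_factors()
        term_sets = config.doe.get("terms", {
            "drug_content": ["x1", "x2", "x3", "x1x2", "x2x3"],
            "cu": ["x1", "x2", "x3", "x1x3", "x2x3"],
        })
        fits = {}
        stage_info = {}
        for resp, terms in term_sets.items():
            fit = fit_rsm(runs, resp, factors, terms)
            fits[resp] = fit
            stage_info[resp] = dict(
                params={k: round(v, 4) for k, v in fit.params.items()},
                rsquared=round(fit.rsquared, 4), F=round(fit.fvalue, 2),
            )
            (out / f"doe_{resp}_summary.txt").write_text(fit.summary() + "\n")
        manifest["stages"]["doe"] = stage_info
        artifacts["doe"] = fits

    if "ospace" in config.stages:
        fits = artifacts["doe"]
        factors = fixtures.reference_factors()
        specs = [SpecLimits("drug_content", lower=95.0, upper=105.0),
                 SpecLimits("cu", upper=5.0)]
        cfg = config.ospace
        grid = {
            "filling_level": np.linspace(30, 70, cfg.get("grid_points", 17)),
            "rotational_speed": np.linspace(15, 25, cfg.get("grid_points", 17)),
        }
        pert = PerturbationModel(draws=cfg.get("draws", 10_000),
                                 seed=config.stage_seed("ospace"))
        surface = operating_space_map(
            fits, specs, grid, factors, pert,
            fixed={"blending_time": cfg.get("blending_time", 24.0)},
        )
        surface.to_csv(out / "operating_space.csv", index=False)
        manifest["stages"]["ospace"] = dict(
            cells=len(surface), operating=int(surface["operating"].sum()),
            outputs=["operating_space.csv"],
        )
        artifacts["ospace"] = surface

    if "calibrate" in config.stages:
        from .bulk_tests import CalibrationTarget, calibrate
        cfg = config.calibrate
        mat = fixtures.desk_material(
            mu_s=cfg.get("mu_s_initial", 0.3), mu_r=cfg.get("mu_r_initial", 0.1))
        target = CalibrationTarget(
            static_angle_deg=cfg.get("static_angle_deg", 32.0),
            tolerance=cfg.get("tolerance", 0.10))
        result = calibrate(mat, target,
                           budget_iterations=cfg.get("budget", 10),
                           particle_budget=cfg.get("particles", 300),
                           seed=config.stage_seed("calibrate"))
        result.iterations.to_csv(out / "calibration_log.csv", index=False)
        manifest["stages"]["calibrate"] = dict(
            converged=bool(result.converged),
            worst_bias=round(float(result.worst_bias), 4),
            mu_s=result.material.pp.static_friction,
            mu_r=result.material.pp.rolling_friction,
            outputs=["calibration_log.csv"],
        )
        artifacts["calibrate"] = result

    if "blend" in config.stages:
        from .blending import run_blending, t_index_series
        cfg = config.blend
        system = fixtures.mini_scene(
            cfg.get("kind", "v_blender"), budget=cfg.get("particles", 1200),
            seed=config.stage_seed("blend"))
        rpm = system.walls[0].kin.omega * 60.0 / (2 * np.pi)
        rev = 60.0 / rpm
        revolutions = cfg.get("revolutions", 4)
        # sample at full revolutions (blender rest pose)
        snaps = run_blending(system, duration=revolutions * rev,
                             save_interval=rev)
        series = t_index_series(snaps, fixtures.reference_formulation(),
                                interval=rev)
        series.to_csv(out / "blend_metrics.csv", index=False)
        manifest["stages"]["blend"] = dict(
            particles=system.n, t_spec=series.attrs["t_spec"],
            final_cu=round(float(series["cu"].iloc[-1]), 3),
            outputs=["blend_metrics.csv"],
        )
        artifacts["blend"] = series

    for name in ("risk_scored.csv", "operating_space.csv", "blend_metrics.csv",
                 "calibration_log.csv"):
        p = out / name
        if p.exists():
            manifest.setdefault("checksums", {})[name] = _checksum(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
    return manifest
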