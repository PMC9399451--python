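"""End-to-end pipeline: configuration, orchestration, manifest.

A run reads a plain-text (YAML) configuration naming the occurrence CSV and
raster layers, then executes: alignment checks, per-pixel deduplication,
spatial thinning, coordinate-error pixel expansion, background sampling,
covariate extraction, grid evaluation, stepwise selection, bootstrap
uncertainty, and writes every stage's outputs plus a manifest of the seeds
consumed.  One master seed spawns independent named substreams so stages are
reproducible in isolation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import environment, evaluate, maxent, occurrences, uncertainty
from .maxent import ModelConfig
from .occurrences import OccurrenceSet
from .raster import CATEGORICAL, LayerStack, align_check, read_raster, write_raster

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]

_STAGES = ("thinning", "error", "background", "grid", "replicates")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (kept below 2**31)."""
    ss = np.random.SeedSequence([int(master_seed), sum(map(ord, stage))])
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass
class RunConfig:
    """Validated run configuration (see examples/ for a template)."""

    occurrences: str
    layers: dict[str, str]  # name -> raster path
    kinds: dict[str, str]  # name -> continuous | categorical
    out_dir: str
    seed: int
    thin_dist: float = 100.0
    thin_reps: int = 10
    n_background: int = 10000
    feature_classes: tuple = evaluate.DEFAULT_FEATURE_CLASSES
    multipliers: tuple = evaluate.DEFAULT_MULTIPLIERS
    max_folds: int | None = 25
    n_bootstrap: int = 10
    bootstrap_fraction: float = 0.8
    n_hinge_knots: int = 50
    expand_errors: bool = True
    fit_options: dict = field(default_factory=dict)  # tol/kkt_tol/max_iter overrides

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a master seed is mandatory")
        missing = [p for p in [self.occurrences, *self.layers.values()] if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")
        uncovered = set(self.layers) - set(self.kinds)
        if uncovered:
            raise ValueError(f"layers without a declared kind: {sorted(uncovered)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["feature_classes"] = tuple(raw.get("feature_classes", evaluate.DEFAULT_FEATURE_CLASSES))
        raw["multipliers"] = tuple(raw.get("multipliers", evaluate.DEFAULT_MULTIPLIERS))
        return cls(**raw)


def _load_stack(config: RunConfig) -> LayerStack:
    stack = LayerStack()
    for name, path in config.layers.items():
        stack.add(name, read_raster(path), config.kinds[name])
    return stack


def _presence_cells(occ: OccurrenceSet, grid, expand: bool) -> pd.DataFrame:
    """Presence pixels: one row per cell, error windows expanded if asked."""
    cells: set[tuple[int, int]] = set()
    for _, rec in occ.records.iterrows():
        if expand:
            cells |= occurrences.expand_error_pixels(rec, grid)
        else:
            r, c = grid.cell_of(rec["x"], rec["y"])
            cells.add((int(r), int(c)))
    rows = np.array(sorted(cells))
    x, y = grid.center_of(rows[:, 0], rows[:, 1])
    return pd.DataFrame({"x": x, "y": y})


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the manifest dict.

    Stage order: dedup -> spatial thinning -> coordinate-error pixel
    expansion -> stack checks -> background sampling -> covariate extraction
    -> configuration-grid evaluation -> stepwise selection -> bootstrap
    surfaces and importance tables.  All tables are CSV, surfaces are
    rasters, and a manifest records seeds and stage counts.  A hard error in
    any stage aborts with the stage name; outputs written so far remain.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "seeds": {}}
    for s in _STAGES:
        manifest["seeds"][s] = stage_seed(config.seed, s)

    stage = "load"
    try:
        stack = _load_stack(config)
        report = align_check(stack)
        (out / "align_report.json").write_text(json.dumps(report, indent=1))
        occ = occurrences.read_occurrences(config.occurrences)
        manifest["stages"]["load"] = {"n_records": len(occ), "n_layers": len(stack.names)}

        stage = "dedup"
        occ = occurrences.deduplicate(occ, stack.grid)
        manifest["stages"]["dedup"] = dict(occ.provenance)

        stage = "thinning"
        occ = occurrences.spatial_thin(
            occ, thin_dist=config.thin_dist, n_reps=config.thin_reps,
            seed=manifest["seeds"]["thinning"],
        )
        pd.DataFrame(
            {"replicate": range(config.thin_reps), "size": occ.provenance["thin_replicate_sizes"]}
        ).to_csv(out / "thinning_report.csv", index=False)
        occurrences.write_occurrences(occ, out / "occurrences_thinned.csv")
        manifest["stages"]["thinning"] = {
            "retained": occ.provenance["thin_retained"],
            "removed": occ.provenance["thin_removed"],
        }

        stage = "error_expansion"
        pres_points = _presence_cells(occ, stack.grid, config.expand_errors)
        manifest["stages"]["error_expansion"] = {"presence_pixels": len(pres_points)}

        stage = "background"
        bg_points = environment.sample_background(
            stack, n=config.n_background, seed=manifest["seeds"]["background"]
        )
        bg_points.to_csv(out / "background_points.csv", index=False)

        stage = "extract"
        pres_table = environment.extract(stack, pres_points, role="presence")
        bg_table = environment.extract(stack, bg_points, role="background")
        table = pd.concat([pres_table, bg_table], ignore_index=True)
        manifest["stages"]["extract"] = {
            "presence_rows": len(pres_table), "background_rows": len(bg_table),
        }

        stage = "grid"
        grid_result, models = evaluate.run_grid(
            table,
            config.kinds,
            feature_classes=config.feature_classes,
            multipliers=config.multipliers,
            seed=manifest["seeds"]["grid"],
            max_folds=config.max_folds,
            n_hinge_knots=config.n_hinge_knots,
            **config.fit_options,
        )
        grid_result.to_frame().to_csv(out / "grid_results.csv", index=False)
        manifest["stages"]["grid"] = {"n_configurations": len(grid_result)}

        stage = "selection"
        chosen, audit = evaluate.stepwise_select(grid_result)
        (out / "selection_audit.json").write_text(json.dumps(audit, indent=1))
        manifest["stages"]["selection"] = {"chosen": chosen.config.label}

        stage = "bootstrap"
        reps = uncertainty.bootstrap_replicates(
            chosen.config,
            table,
            config.kinds,
            stack=stack,
            n_reps=config.n_bootstrap,
            fraction=config.bootstrap_fraction,
            seed=manifest["seeds"]["replicates"],
            n_hinge_knots=config.n_hinge_knots,
            **config.fit_options,
        )
        surfaces = uncertainty.aggregate_surfaces(reps)
        for name in ("mean", "min", "max", "range"):
            write_raster(getattr(surfaces, name), out / f"suitability_{name}.asc")
        importance = uncertainty.aggregate_importance(
            reps, seed=manifest["seeds"]["replicates"]
        )
        importance.to_csv(out / "importance.csv", index=False)
        manifest["stages"]["bootstrap"] = {
            "n_replicates": config.n_bootstrap,
            "n_converged": len(reps.converged()),
            "surfaces": 4,
            "tables": 2,
        }
    except Exception as exc:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    log.info("pipeline complete: outputs in %s", out)
    return manifest
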