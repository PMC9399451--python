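"""Bootstrap uncertainty mapping and variable importance.

Refits the selected configuration on repeated 80% subsamples of the
presences, maps cellwise mean/min/max/range of the cloglog suitability
surfaces across replicates, and aggregates two variable-importance measures:
percent contribution (objective-gain accounting along the training path) and
permutation importance (drop in training AUC when one variable is shuffled).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import evaluate, maxent
from .maxent import MaxentModel, ModelConfig
from .raster import LayerStack, RasterGrid

log = logging.getLogger(__name__)

__all__ = [
    "Replicate",
    "ReplicateSet",
    "SuitabilitySurfaces",
    "bootstrap_replicates",
    "predict_surface",
    "aggregate_surfaces",
    "permutation_importance",
    "aggregate_importance",
]


@dataclass
class Replicate:
    indices: np.ndarray  # retained presence row indices
    model: MaxentModel
    table: pd.DataFrame  # the replicate's training rows (presence + background)
    surface: RasterGrid | None = None

    @property
    def converged(self) -> bool:
        return self.model.converged


@dataclass
class ReplicateSet:
    config: ModelConfig
    subsample_fraction: float
    replicates: list[Replicate] = field(default_factory=list)

    def converged(self) -> list[Replicate]:
        reps = [r for r in self.replicates if r.converged]
        n_bad = len(self.replicates) - len(reps)
        if n_bad:
            log.warning("%d of %d replicates excluded (non-convergent)", n_bad, len(self.replicates))
        return reps


@dataclass
class SuitabilitySurfaces:
    """Cellwise aggregates of cloglog suitability across replicates."""

    mean: RasterGrid
    min: RasterGrid
    max: RasterGrid
    range: RasterGrid  # max - min


def predict_surface(
    model: MaxentModel,
    stack: LayerStack,
    kinds: dict[str, str],
    chunk_rows: int = 40,
) -> RasterGrid:
    """Cloglog suitability over every grid cell, computed in row chunks."""
    grid = stack.grid
    out = np.full(grid.shape, np.nan)
    names = stack.names
    for r0 in range(0, grid.height, chunk_rows):
        r1 = min(r0 + chunk_rows, grid.height)
        block = {n: stack[n].values[r0:r1].ravel() for n in names}
        df = pd.DataFrame(block)
        ok = ~df.isna().any(axis=1)
        if ok.any():
            x = maxent.design_matrix(model, df.loc[ok], kinds)
            vals = np.full(len(df), np.nan)
            vals[ok.to_numpy()] = maxent.predict_cloglog(model, x)
            out[r0:r1] = vals.reshape(r1 - r0, grid.width)
    return grid.copy_with(out)


def bootstrap_replicates(
    config: ModelConfig,
    table: pd.DataFrame,
    kinds: dict[str, str],
    stack: LayerStack | None = None,
    n_reps: int = 10,
    fraction: float = 0.8,
    seed: int | None = None,
    compute_surfaces: bool = True,
    n_hinge_knots: int = 50,
    replace: bool = False,
    **fit_kwargs,
) -> ReplicateSet:
    """Fit the chosen configuration on repeated presence subsamples.

    Each replicate draws floor(fraction * n) presences without replacement
    (the default; set ``replace=True`` for a classical bootstrap draw) from
    a fresh seed stream, refits, and (optionally, when ``stack`` is given)
    predicts a cloglog surface.  ``table`` is the full training table
    (presence + background rows with a ``role`` column); the background is
    shared across replicates.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    pres = table[table["role"] == "presence"].reset_index(drop=True)
    bg = table[table["role"] == "background"].reset_index(drop=True)
    n = len(pres)
    k = math.floor(fraction * n)
    if k < 2:
        raise ValueError(f"subsample of {k} presences is too small to fit")
    streams = np.random.SeedSequence(seed).spawn(n_reps)
    out = ReplicateSet(config=config, subsample_fraction=fraction)
    for rep_i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        idx = np.sort(rng.choice(n, size=k, replace=replace))
        rep_table = pd.concat([pres.iloc[idx], bg], ignore_index=True)
        expansion = maxent.build_features(rep_table, config, kinds, n_hinge_knots=n_hinge_knots)
        model = maxent.fit(expansion, config, **fit_kwargs)
        surface = None
        if compute_surfaces and stack is not None and model.converged:
            surface = predict_surface(model, stack, kinds)
        out.replicates.append(Replicate(indices=idx, model=model, table=rep_table, surface=surface))
        if not model.converged:
            log.warning("bootstrap replicate %d did not converge", rep_i)
    return out


def aggregate_surfaces(reps: ReplicateSet) -> SuitabilitySurfaces:
    """Cellwise mean, min, max and range over converged replicate surfaces."""
    surfaces = [r.surface for r in reps.converged() if r.surface is not None]
    if not surfaces:
        raise ValueError("no converged replicate has a surface")
    cube = np.stack([s.values for s in surfaces])
    ref = surfaces[0]
    return SuitabilitySurfaces(
        mean=ref.copy_with(cube.mean(axis=0)),
        min=ref.copy_with(cube.min(axis=0)),
        max=ref.copy_with(cube.max(axis=0)),
        range=ref.copy_with(cube.max(axis=0) - cube.min(axis=0)),
    )


def permutation_importance(
    model: MaxentModel,
    table: pd.DataFrame,
    kinds: dict[str, str],
    seed: int | None = None,
) -> dict[str, float]:
    """Permutation importance: normalized training-AUC drop per variable.

    Each variable's values are permuted once across all training rows
    (presences and background together; categorical labels move whole), the
    model is re-scored without refitting, and the drop in training AUC is
    recorded (negative drops floored at zero) then normalized to percents.
    An all-zero result is returned un-normalized and flagged.
    """
    rng = np.random.default_rng(seed)
    pres_mask = (table["role"] == "presence").to_numpy()
    x = maxent.design_matrix(model, table, kinds)
    s = x @ model.weights
    base = evaluate.auc(s[pres_mask], s[~pres_mask])
    drops: dict[str, float] = {}
    for var in model.expansion.variables:
        shuffled = table.copy()
        shuffled[var] = rng.permutation(shuffled[var].to_numpy())
        xp = maxent.design_matrix(model, shuffled, kinds)
        sp = xp @ model.weights
        drop = base - evaluate.auc(sp[pres_mask], sp[~pres_mask])
        drops[var] = max(drop, 0.0)
    total = sum(drops.values())
    if total == 0:
        log.warning("permutation_importance: no variable changed the AUC")
        return drops
    return {v: 100.0 * d / total for v, d in drops.items()}


def aggregate_importance(reps: ReplicateSet, seed: int | None = None) -> pd.DataFrame:
    """Mean percent contribution and permutation importance across replicates.

    Returns one row per variable with the arithmetic means over converged
    replicates, in a table with the conventional two importance columns.
    """
    converged = reps.converged()
    if not converged:
        raise ValueError("no converged replicates")
    streams = np.random.SeedSequence(seed).spawn(len(converged))
    contrib: list[dict[str, float]] = []
    perm: list[dict[str, float]] = []
    for rep, ss in zip(converged, streams):
        contrib.append(maxent.percent_contribution(rep.model))
        kinds = _kinds_of(rep)
        perm.append(
            permutation_importance(
                rep.model, rep.table, kinds, seed=int(ss.generate_state(1)[0] % 2**31)
            )
        )
    variables = sorted({v for d in contrib for v in d})
    rows = [
        {
            "Variable": v,
            "Percent contribution": float(np.mean([d.get(v, 0.0) for d in contrib])),
            "Percent permutation importance": float(np.mean([d.get(v, 0.0) for d in perm])),
        }
        for v in variables
    ]
    return pd.DataFrame(rows)


def _kinds_of(rep: Replicate) -> dict[str, str]:
    kinds: dict[str, str] = {}
    for f in rep.model.expansion.features:
        kinds[f.variable] = "categorical" if f.kind == "category" else "continuous"
    return kinds
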