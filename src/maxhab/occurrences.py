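"""Presence-record processing: dedup, error expansion, thinning, summaries.

Occurrence records live in a :class:`OccurrenceSet`, a thin wrapper around a
pandas DataFrame with columns ``x, y, error_m, source_id, year``.  All
distances are planar Euclidean on projected coordinates (meters).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .raster import CATEGORICAL, LayerStack, RasterGrid

log = logging.getLogger(__name__)

__all__ = [
    "OccurrenceSet",
    "read_occurrences",
    "write_occurrences",
    "deduplicate",
    "expand_error_pixels",
    "spatial_thin",
    "unit_occupancy",
    "topo_summary",
]

_COLUMNS = ["x", "y", "error_m", "source_id", "year"]


@dataclass
class OccurrenceSet:
    """Ordered presence records, optionally registered to a raster grid."""

    records: pd.DataFrame
    grid_ref: RasterGrid | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.records.copy()
        if "error_m" not in df.columns:
            df["error_m"] = 0.0
        if "source_id" not in df.columns:
            df["source_id"] = [f"r{i}" for i in range(len(df))]
        if "year" not in df.columns:
            df["year"] = pd.NA
        missing = [c for c in ("x", "y") if c not in df.columns]
        if missing:
            raise ValueError(f"occurrence table lacks columns {missing}")
        if not np.isfinite(df[["x", "y"]].to_numpy(dtype=float)).all():
            raise ValueError("occurrence coordinates must be finite")
        if (df["error_m"].to_numpy(dtype=float) < 0).any():
            raise ValueError("error radii must be nonnegative")
        self.records = df[_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def xy(self) -> np.ndarray:
        return self.records[["x", "y"]].to_numpy(dtype=float)


def read_occurrences(path) -> OccurrenceSet:
    """Read an occurrence CSV (columns x, y[, error_m, source_id, year]).

    Malformed coordinate or radius entries are rejected with their line
    numbers (header = line 1).
    """
    df = pd.read_csv(path)
    bad_lines = []
    for col in ("x", "y", "error_m"):
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        bad_lines.extend(int(i) + 2 for i in bad)  # +2: header + 0-base
        df[col] = coerced
    if bad_lines:
        raise ValueError(f"{path}: non-numeric values on lines {sorted(set(bad_lines))}")
    return OccurrenceSet(records=df)


def write_occurrences(occ: OccurrenceSet, path) -> None:
    occ.records.to_csv(path, index=False)


def deduplicate(occ: OccurrenceSet, grid: RasterGrid) -> OccurrenceSet:
    """Keep one record per occupied grid cell (first by input order).

    Records falling outside the grid extent are excluded with a warning.
    The removed-record count is stored in provenance and logged.
    """
    df = occ.records
    row, col = grid.cell_of(df["x"].to_numpy(), df["y"].to_numpy())
    inside = grid.in_bounds(row, col)
    n_outside = int((~inside).sum())
    if n_outside:
        log.warning("deduplicate: excluded %d records outside the grid extent", n_outside)
    df = df.loc[inside].copy()
    cell_id = row[inside] * grid.width + col[inside]
    keep = ~pd.Series(cell_id).duplicated().to_numpy()
    n_removed = int((~keep).sum())
    if n_removed:
        log.info("deduplicate: removed %d duplicate-cell records", n_removed)
    out = df.loc[keep].reset_index(drop=True)
    prov = dict(occ.provenance)
    prov.update({"dedup_removed": n_removed, "dedup_outside": n_outside})
    return OccurrenceSet(records=out, grid_ref=grid, provenance=prov)


def expand_error_pixels(record: pd.Series, grid: RasterGrid) -> set[tuple[int, int]]:
    """Cells treated as presences for one record, given its coordinate error.

    Returns the square window of cells centered on the record's cell with
    half-width ``h = ceil(error_m / (2 * cell_size))``; a 10 m error on a 5 m
    grid yields the 3x3 window of 9 cells.  The window is clipped at the grid
    edge (clip logged).
    """
    row, col = grid.cell_of(record["x"], record["y"])
    row, col = int(row), int(col)
    if not grid.in_bounds(row, col):
        raise ValueError("record lies outside the grid extent")
    err = float(record.get("error_m", 0.0) or 0.0)
    h = math.ceil(err / (2.0 * grid.cell_size)) if err > 0 else 0
    r0, r1 = row - h, row + h
    c0, c1 = col - h, col + h
    if r0 < 0 or c0 < 0 or r1 >= grid.height or c1 >= grid.width:
        log.info("expand_error_pixels: window clipped at grid edge")
    cells = {
        (r, c)
        for r in range(max(r0, 0), min(r1, grid.height - 1) + 1)
        for c in range(max(c0, 0), min(c1, grid.width - 1) + 1)
    }
    return cells


def _thin_once(xy: np.ndarray, thin_dist: float, rng: np.random.Generator) -> np.ndarray:
    """One thinning replicate; returns indices (into xy) of retained records.

    While any pair is closer than ``thin_dist``, remove one record chosen
    uniformly among those with the most neighbors within ``thin_dist``.
    """
    n = len(xy)
    if n <= 1:
        return np.arange(n)
    close = squareform(pdist(xy)) < thin_dist
    np.fill_diagonal(close, False)
    alive = np.ones(n, dtype=bool)
    counts = close.sum(axis=1)
    while True:
        active = counts[alive]
        if not active.size or active.max() == 0:
            break
        alive_idx = np.flatnonzero(alive)
        worst = alive_idx[counts[alive_idx] == active.max()]
        drop = rng.choice(worst)
        alive[drop] = False
        counts[close[drop]] -= 1
    return np.flatnonzero(alive)


def spatial_thin(
    occ: OccurrenceSet,
    thin_dist: float = 100.0,
    n_reps: int = 10,
    seed: int | None = None,
) -> OccurrenceSet:
    """Spatially thin records so no pair is closer than ``thin_dist`` meters.

    Runs ``n_reps`` stochastic replicates of greedy max-neighbor removal and
    returns the replicate retaining the most records (uniform random among
    ties).  The output never contains a pair at distance < ``thin_dist``.
    """
    if thin_dist <= 0:
        raise ValueError("thin_dist must be positive")
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    if len(occ) == 0:
        return OccurrenceSet(records=occ.records.copy(), grid_ref=occ.grid_ref)
    rng = np.random.default_rng(seed)
    xy = occ.xy
    reps = [_thin_once(xy, thin_dist, rng) for _ in range(n_reps)]
    sizes = np.array([len(r) for r in reps])
    best = np.flatnonzero(sizes == sizes.max())
    chosen = reps[rng.choice(best)]
    kept = np.zeros(len(xy), dtype=bool)
    kept[chosen] = True
    out_df = occ.records.loc[kept].reset_index(drop=True)
    # hard invariant: no surviving pair closer than thin_dist
    if len(out_df) > 1:
        assert pdist(out_df[["x", "y"]].to_numpy()).min() >= thin_dist
    prov = dict(occ.provenance)
    prov.update(
        {
            "thin_dist": thin_dist,
            "thin_replicate_sizes": sizes.tolist(),
            "thin_retained": int(sizes.max()),
            "thin_removed": int(len(xy) - sizes.max()),
        }
    )
    log.info(
        "spatial_thin: retained %d of %d records (replicate sizes %s)",
        sizes.max(), len(xy), sizes.tolist(),
    )
    return OccurrenceSet(records=out_df, grid_ref=occ.grid_ref, provenance=prov)


def unit_occupancy(
    occ: OccurrenceSet,
    categorical_layer: RasterGrid,
    min_count: int = 10,
) -> pd.DataFrame:
    """Per-class occurrence counts vs. areal availability.

    Returns one row per class present in the layer: occurrence count,
    percent of occurrences, percent of (non-missing) study-area cells, and
    the occupancy ratio occurrence_pct / area_pct.  ``presented`` flags the
    classes whose count is strictly greater than ``min_count`` (the display
    filter); the full table is always returned.
    """
    row, col = categorical_layer.cell_of(occ.records["x"].to_numpy(), occ.records["y"].to_numpy())
    inside = categorical_layer.in_bounds(row, col)
    codes = categorical_layer.values[row[inside], col[inside]]
    codes = codes[~np.isnan(codes)].astype(int)

    layer_vals = categorical_layer.values[~np.isnan(categorical_layer.values)].astype(int)
    classes, area_counts = np.unique(layer_vals, return_counts=True)
    occ_counts = np.array([(codes == c).sum() for c in classes])

    n_occ = occ_counts.sum()
    occurrence_pct = 100.0 * occ_counts / n_occ if n_occ else np.zeros_like(occ_counts, dtype=float)
    area_pct = 100.0 * area_counts / area_counts.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(area_pct > 0, occurrence_pct / area_pct, np.nan)
    return pd.DataFrame(
        {
            "unit": classes,
            "occurrence_count": occ_counts,
            "occurrence_pct": occurrence_pct,
            "area_pct": area_pct,
            "ratio": ratio,
            "presented": occ_counts > min_count,
        }
    )


def topo_summary(occ: OccurrenceSet, **layers: RasterGrid) -> pd.DataFrame:
    """Mean, SD (population), min, max of each layer at occurrence cells.

    Occurrences on missing-data cells are excluded per layer and logged.
    Layers are passed as keyword arguments, e.g. ``topo_summary(occ,
    slope=slope_grid, curvature=curv_grid)``.
    """
    rows = []
    for name, layer in layers.items():
        r, c = layer.cell_of(occ.records["x"].to_numpy(), occ.records["y"].to_numpy())
        inside = layer.in_bounds(r, c)
        vals = layer.values[r[inside], c[inside]]
        n_missing = int(np.isnan(vals).sum() + (~inside).sum())
        if n_missing:
            log.info("topo_summary: %s: excluded %d records (outside/missing)", name, n_missing)
        vals = vals[~np.isnan(vals)]
        rows.append(
            {
                "layer": name,
                "n": len(vals),
                "mean": float(np.mean(vals)) if len(vals) else np.nan,
                "sd": float(np.std(vals)) if len(vals) else np.nan,  # population SD
                "min": float(np.min(vals)) if len(vals) else np.nan,
                "max": float(np.max(vals)) if len(vals) else np.nan,
            }
        )
    return pd.DataFrame(rows)
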