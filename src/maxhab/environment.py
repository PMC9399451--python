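"""Derived environmental layers and covariate extraction.

Implements the raster derivations the analysis needs — percent slope and its
spatial derivative (curvature) by Horn's 3x3 operator, Euclidean distance to
geologic contacts, bilinear downscaling of coarse climate normals — plus
uniform background sampling and point-wise covariate extraction into a flat
table.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator

from .raster import CATEGORICAL, CONTINUOUS, LayerStack, RasterGrid

log = logging.getLogger(__name__)

__all__ = [
    "compute_slope",
    "compute_curvature",
    "distance_to_contacts",
    "downscale",
    "sample_background",
    "extract",
]

# Horn's weighted-difference kernels for d/dx and d/dy on a 3x3 window.
_HORN_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
_HORN_Y = np.array([[1, 2, 1], [0, 0, 0], [-1, -2, -1]], dtype=float)


def _horn_gradients(values: np.ndarray, cell_size: float):
    """Horn 3x3 gradients; edges use clamped (edge-replicated) neighborhoods.

    Cells with any NaN in their 3x3 neighborhood come out NaN.
    """
    gx = ndimage.correlate(values, _HORN_X, mode="nearest") / (8.0 * cell_size)
    gy = ndimage.correlate(values, _HORN_Y, mode="nearest") / (8.0 * cell_size)
    return gx, gy


def compute_slope(dem: RasterGrid) -> RasterGrid:
    """Percent slope: 100 * sqrt(gx^2 + gy^2) with Horn gradients.

    Cells whose 3x3 neighborhood touches missing data are marked missing.
    """
    gx, gy = _horn_gradients(dem.values, dem.cell_size)
    slope = 100.0 * np.hypot(gx, gy)
    # any missing value in the 3x3 neighborhood marks the cell missing
    nan_near = ndimage.binary_dilation(np.isnan(dem.values), structure=np.ones((3, 3), bool))
    slope[nan_near] = np.nan
    return dem.copy_with(slope)


def compute_curvature(slope: RasterGrid) -> RasterGrid:
    """Change in slope (first spatial derivative of the slope layer).

    Applies the same operator as :func:`compute_slope` to the slope raster:
    100 * gradient magnitude of the slope values per horizontal meter, so a
    slope field rising linearly at rate ``r`` per meter maps to ``100 * r``.
    """
    return compute_slope(slope)


def distance_to_contacts(categorical: RasterGrid) -> RasterGrid:
    """Euclidean distance (m) from each cell center to the nearest contact.

    A contact (boundary) cell has at least one 4-neighbor of a different
    class; boundary cells get distance 0.  A single-class layer has no
    contacts: every cell is returned missing, with a warning logged.
    """
    vals = categorical.values
    boundary = np.zeros(vals.shape, dtype=bool)
    # compare each cell with its 4-neighbors; NaN cells never form contacts
    same_row = vals[:, 1:] != vals[:, :-1]
    valid_row = ~np.isnan(vals[:, 1:]) & ~np.isnan(vals[:, :-1])
    d = same_row & valid_row
    boundary[:, 1:] |= d
    boundary[:, :-1] |= d
    same_col = vals[1:, :] != vals[:-1, :]
    valid_col = ~np.isnan(vals[1:, :]) & ~np.isnan(vals[:-1, :])
    d = same_col & valid_col
    boundary[1:, :] |= d
    boundary[:-1, :] |= d

    if not boundary.any():
        log.warning("distance_to_contacts: single-class layer, no contacts exist")
        return categorical.copy_with(np.full(vals.shape, np.nan))

    dist = ndimage.distance_transform_edt(~boundary) * categorical.cell_size
    dist = np.where(np.isnan(vals), np.nan, dist)
    return categorical.copy_with(dist)


def downscale(coarse: RasterGrid, target_grid: RasterGrid, kind: str = CONTINUOUS) -> RasterGrid:
    """Bilinear interpolation of coarse cell-center values onto target cell centers.

    Points outside the coarse cell-center support are clamped to the nearest
    edge before interpolating (nearest-edge extrapolation).  Categorical
    layers are rejected: class codes cannot be interpolated.
    """
    if kind == CATEGORICAL:
        raise ValueError("downscale applies to continuous layers only")
    # coarse cell-center coordinate axes
    cy = coarse.origin[1] - (np.arange(coarse.height) + 0.5) * coarse.cell_size
    cx = coarse.origin[0] + (np.arange(coarse.width) + 0.5) * coarse.cell_size
    # RegularGridInterpolator needs ascending axes; rows descend in y
    interp = RegularGridInterpolator(
        (cy[::-1], cx), coarse.values[::-1, :], method="linear", bounds_error=False
    )
    ty = target_grid.origin[1] - (np.arange(target_grid.height) + 0.5) * target_grid.cell_size
    tx = target_grid.origin[0] + (np.arange(target_grid.width) + 0.5) * target_grid.cell_size
    ty_c = np.clip(ty, cy.min(), cy.max())
    tx_c = np.clip(tx, cx.min(), cx.max())
    yy, xx = np.meshgrid(ty_c, tx_c, indexing="ij")
    fine = interp(np.stack([yy.ravel(), xx.ravel()], axis=1)).reshape(target_grid.shape)
    return target_grid.copy_with(fine)


def sample_background(stack: LayerStack, n: int = 10000, seed: int | None = None) -> pd.DataFrame:
    """Uniform draw of ``n`` distinct non-missing cells; returns cell centers.

    Presence cells are not excluded (standard presence-background practice).
    A cell is available when no layer is missing there.
    """
    rng = np.random.default_rng(seed)
    grid = stack.grid
    valid = np.ones(grid.shape, dtype=bool)
    for name in stack.names:
        valid &= ~np.isnan(stack[name].values)
    idx = np.flatnonzero(valid.ravel())
    if n > idx.size:
        raise ValueError(
            f"requested {n} background points but only {idx.size} non-missing cells exist"
        )
    chosen = rng.choice(idx, size=n, replace=False)
    row, col = np.unravel_index(chosen, grid.shape)
    x, y = grid.center_of(row, col)
    return pd.DataFrame({"x": x, "y": y})


def extract(stack: LayerStack, points: pd.DataFrame, role: str | None = None) -> pd.DataFrame:
    """Nearest-cell-center covariate lookup for every point.

    ``points`` needs columns x, y; any extra columns are carried through.
    Points outside the grid extent, and rows with a missing value in any
    layer, are dropped (counts logged).  If ``role`` is given, a ``role``
    column is added.
    """
    grid = stack.grid
    row, col = grid.cell_of(points["x"].to_numpy(), points["y"].to_numpy())
    inside = grid.in_bounds(row, col)
    n_outside = int((~inside).sum())
    if n_outside:
        log.warning("extract: dropped %d points outside the grid extent", n_outside)
    out = points.loc[inside].reset_index(drop=True).copy()
    row, col = row[inside], col[inside]
    for name in stack.names:
        out[name] = stack[name].values[row, col]
    covars = out[stack.names]
    keep = ~covars.isna().any(axis=1)
    n_missing = int((~keep).sum())
    if n_missing:
        log.warning("extract: dropped %d points on missing-data cells", n_missing)
    out = out.loc[keep].reset_index(drop=True)
    if role is not None:
        out["role"] = role
    return out
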