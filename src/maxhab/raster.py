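"""Raster grids and aligned layer stacks.

A :class:`RasterGrid` is a single-band raster on a projected grid: a 2-D
array of cell values (continuous reals or integer class codes), a cell size
in meters, and the projected coordinate of the upper-left corner.  Cells are
addressed row-major from the upper-left origin; a point falls in the cell
``col = floor((x - x0) / cell_size)``, ``row = floor((y0 - y) / cell_size)``
(half-open cell intervals).  Missing data are NaN internally, translated to
a nodata sentinel on write.

A :class:`LayerStack` is an ordered mapping of named, geometrically
identical layers, each declared continuous or categorical.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RasterGrid",
    "LayerStack",
    "GridMismatchError",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_geotiff",
    "write_geotiff",
    "read_raster",
    "write_raster",
    "align_check",
]

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"


class GridMismatchError(ValueError):
    """Raised when layers that must share a grid geometry do not."""


@dataclass
class RasterGrid:
    """Single-band raster on a projected grid (meters)."""

    values: np.ndarray  # 2-D float array; NaN marks missing cells
    cell_size: float
    origin: tuple[float, float]  # (x0, y0) of the upper-left corner

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if not self.cell_size > 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def same_geometry(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.allclose(self.origin, other.origin)
        )

    # --- coordinate <-> cell conversions -------------------------------

    def cell_of(self, x, y):
        """Row/col indices of the cells containing points (x, y).

        Uses half-open cell intervals from the upper-left origin.  No
        bounds check: callers decide how to treat out-of-grid indices.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin[0]) / self.cell_size).astype(int)
        row = np.floor((self.origin[1] - y) / self.cell_size).astype(int)
        return row, col

    def center_of(self, row, col):
        """Projected coordinates of cell centers for row/col indices."""
        row = np.asarray(row)
        col = np.asarray(col)
        x = self.origin[0] + (col + 0.5) * self.cell_size
        y = self.origin[1] - (row + 0.5) * self.cell_size
        return x, y

    def in_bounds(self, row, col):
        row = np.asarray(row)
        col = np.asarray(col)
        return (row >= 0) & (row < self.height) & (col >= 0) & (col < self.width)

    def missing_fraction(self) -> float:
        return float(np.isnan(self.values).mean())

    def copy_with(self, values: np.ndarray) -> "RasterGrid":
        return RasterGrid(values=np.asarray(values, dtype=float), cell_size=self.cell_size, origin=self.origin)


@dataclass
class LayerStack:
    """Named raster covariates sharing one grid geometry.

    ``kinds[name]`` is ``"continuous"`` or ``"categorical"``.  Categorical
    layers hold integer class codes stored as floats (NaN = missing).
    """

    layers: dict[str, RasterGrid] = field(default_factory=dict)
    kinds: dict[str, str] = field(default_factory=dict)

    def add(self, name: str, grid: RasterGrid, kind: str = CONTINUOUS) -> None:
        if kind not in (CONTINUOUS, CATEGORICAL):
            raise ValueError(f"unknown layer kind {kind!r}")
        if self.layers:
            ref = next(iter(self.layers.values()))
            if not ref.same_geometry(grid):
                raise GridMismatchError(f"layer {name!r} does not match stack geometry")
        self.layers[name] = grid
        self.kinds[name] = kind

    def __getitem__(self, name: str) -> RasterGrid:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def grid(self) -> RasterGrid:
        """Reference grid (the first layer)."""
        if not self.layers:
            raise ValueError("empty stack has no grid")
        return next(iter(self.layers.values()))

    def continuous_names(self) -> list[str]:
        return [n for n in self.layers if self.kinds[n] == CONTINUOUS]

    def categorical_names(self) -> list[str]:
        return [n for n in self.layers if self.kinds[n] == CATEGORICAL]


def align_check(stack: LayerStack) -> dict:
    """Verify all layers share one geometry; report per-layer diagnostics.

    Returns a report dict with per-layer missing fractions and, for
    categorical layers, the class legend (sorted unique codes).  Raises
    :class:`GridMismatchError` naming the offending layers on any geometry
    mismatch.
    """
    if not stack.layers:
        return {"layers": {}, "ok": True}
    names = stack.names
    ref_name, ref = names[0], stack[names[0]]
    bad = [n for n in names[1:] if not ref.same_geometry(stack[n])]
    if bad:
        raise GridMismatchError(
            f"layers {bad} do not match the geometry of {ref_name!r}"
        )
    report: dict = {"ok": True, "layers": {}}
    for n in names:
        g = stack[n]
        entry = {"missing_fraction": g.missing_fraction(), "kind": stack.kinds[n]}
        if stack.kinds[n] == CATEGORICAL:
            vals = g.values[~np.isnan(g.values)]
            entry["legend"] = sorted(int(v) for v in np.unique(vals))
        report["layers"][n] = entry
    return report


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O (plain-text interchange format)
# ---------------------------------------------------------------------------

def write_ascii_grid(grid: RasterGrid, path, nodata: float = -9999.0) -> None:
    vals = np.where(np.isnan(grid.values), nodata, grid.values)
    y_ll = grid.origin[1] - grid.height * grid.cell_size
    with open(path, "w") as fh:
        fh.write(f"NCOLS {grid.width}\n")
        fh.write(f"NROWS {grid.height}\n")
        fh.write(f"XLLCORNER {grid.origin[0]!r}\n")
        fh.write(f"YLLCORNER {y_ll!r}\n")
        fh.write(f"CELLSIZE {grid.cell_size!r}\n")
        fh.write(f"NODATA_VALUE {nodata!r}\n")
        np.savetxt(fh, vals, fmt="%.10g")


def read_ascii_grid(path) -> RasterGrid:
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].upper() in {
                "NCOLS", "NROWS", "XLLCORNER", "YLLCORNER", "XLLCENTER",
                "YLLCENTER", "CELLSIZE", "NODATA_VALUE",
            }:
                header[parts[0].upper()] = float(parts[1])
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        vals = np.loadtxt(fh, ndmin=2)
    ncols = int(header["NCOLS"])
    nrows = int(header["NROWS"])
    cell = header["CELLSIZE"]
    if "XLLCORNER" in header:
        x_ll, y_ll = header["XLLCORNER"], header["YLLCORNER"]
    else:  # cell-center registration
        x_ll = header["XLLCENTER"] - cell / 2
        y_ll = header["YLLCENTER"] - cell / 2
    if vals.shape != (nrows, ncols):
        raise ValueError(f"ASCII grid body {vals.shape} does not match header ({nrows}, {ncols})")
    nodata = header.get("NODATA_VALUE")
    if nodata is not None:
        vals = np.where(vals == nodata, np.nan, vals)
    origin = (x_ll, y_ll + nrows * cell)
    return RasterGrid(values=vals, cell_size=cell, origin=origin)


# ---------------------------------------------------------------------------
# GeoTIFF I/O through tifffile (single band, float32, georeferencing via
# ModelPixelScale + ModelTiepoint tags, nodata via GDAL_NODATA)
# ---------------------------------------------------------------------------

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


def write_geotiff(grid: RasterGrid, path, nodata: float = -9999.0) -> None:
    import tifffile

    vals = np.where(np.isnan(grid.values), nodata, grid.values).astype(np.float32)
    scale = (grid.cell_size, grid.cell_size, 0.0)
    tiepoint = (0.0, 0.0, 0.0, grid.origin[0], grid.origin[1], 0.0)
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, scale, True),
        (_TAG_TIEPOINT, "d", 6, tiepoint, True),
        (_TAG_GDAL_NODATA, "s", 0, str(nodata), True),
    ]
    tifffile.imwrite(path, vals, extratags=extratags)


def read_geotiff(path) -> RasterGrid:
    import tifffile

    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        vals = page.asarray().astype(float)
        tags = page.tags
        try:
            scale = tags[_TAG_PIXEL_SCALE].value
            tiepoint = tags[_TAG_TIEPOINT].value
        except KeyError as exc:
            raise ValueError(f"{path}: missing georeferencing tags") from exc
        nodata_tag = tags.get(_TAG_GDAL_NODATA)
    if vals.ndim != 2:
        raise ValueError(f"{path}: expected a single-band raster")
    if not np.isclose(scale[0], scale[1]):
        raise ValueError(f"{path}: non-square cells are not supported")
    if nodata_tag is not None:
        nodata = float(str(nodata_tag.value).strip().split()[0])
        vals = np.where(vals == nodata, np.nan, vals)
    origin = (float(tiepoint[3]), float(tiepoint[4]))
    return RasterGrid(values=vals, cell_size=float(scale[0]), origin=origin)


def read_raster(path) -> RasterGrid:
    """Read a raster by extension: .asc/.txt → ASCII grid, .tif/.tiff → GeoTIFF."""
    p = str(path).lower()
    if p.endswith((".tif", ".tiff")):
        return read_geotiff(path)
    return read_ascii_grid(path)


def write_raster(grid: RasterGrid, path, nodata: float = -9999.0) -> None:
    p = str(path).lower()
    if p.endswith((".tif", ".tiff")):
        write_geotiff(grid, path, nodata=nodata)
    else:
        write_ascii_grid(grid, path, nodata=nodata)


def write_legend(legend: dict, path) -> None:
    """Write a categorical legend (code -> label) as sidecar JSON."""
    with open(path, "w") as fh:
        json.dump({str(k): v for k, v in legend.items()}, fh, indent=1)


def read_legend(path) -> dict:
    with open(path) as fh:
        return {int(k): v for k, v in json.load(fh).items()}
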