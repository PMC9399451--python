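"""Virtual landscapes with known suitability structure.

Generates raster covariate stacks that mimic the statistical structure of a
mountain study area — a contiguous categorical geology mosaic, a smooth
elevation field with derived slope/curvature, a distance-to-contact layer,
and spatially autocorrelated seasonal climate normals simulated on a coarse
grid and downscaled — together with a log-linear ground-truth suitability
surface (a "virtual species") used for parameter-recovery testing, and
presence sampling with optional coordinate error.

Defaults emulate a high-elevation volcanic landscape scaled down to a
400 x 400 cell desk-size domain: analysis cells of 5 m, elevation spanning
2200-3100 m, ~24 geologic units, and climate normals calibrated to 643 mm
total annual precipitation and -2.4 / 12.3 C annual minimum / maximum
temperature normals.  Climate is simulated on a 16x coarser grid (25 x 25
coarse cells over the default domain), preserving the coarse-climate-versus-
fine-terrain structure of such studies at this domain size: what matters
statistically is that the climate field keeps enough spatial degrees of
freedom across the extent to be distinguishable from the other smooth
fields, as real seasonal normals are over a full-size study area.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from . import environment
from .occurrences import OccurrenceSet
from .raster import CATEGORICAL, CONTINUOUS, LayerStack, RasterGrid

log = logging.getLogger(__name__)

__all__ = [
    "ClimateNormal",
    "LandscapeParams",
    "TruthModel",
    "generate_landscape",
    "sample_presences",
    "inject_coordinate_error",
]


@dataclass(frozen=True)
class ClimateNormal:
    """Requested statistics for one climate layer.

    mean and spatial_sd are enforced exactly on the downscaled (fine) grid;
    correlation_length (meters) sets the Gaussian smoothing scale of the
    coarse random field; lapse couples the layer to elevation (units per
    meter of elevation, applied around the mean elevation; default 0).
    """

    mean: float
    spatial_sd: float
    correlation_length: float = 200.0
    lapse: float = 0.0


def _default_climate() -> dict[str, ClimateNormal]:
    # Total precipitation split so the monsoon season dominates and the two
    # seasons sum to the 643 mm annual normal; temperature normals follow
    # the study area's printed -2.4 / 12.3 C annual min/max.
    return {
        "precip_summer": ClimateNormal(mean=354.0, spatial_sd=30.0),
        "precip_winter": ClimateNormal(mean=289.0, spatial_sd=35.0),
        "tmax_winter": ClimateNormal(mean=12.3, spatial_sd=1.5),
        "tmin_winter": ClimateNormal(mean=-2.4, spatial_sd=1.5),
        "tmin_summer": ClimateNormal(mean=4.6, spatial_sd=1.2),
    }


@dataclass
class LandscapeParams:
    """Parameters of the virtual landscape generator."""

    grid_width: int = 400
    grid_height: int = 400
    cell_size: float = 5.0
    n_units: int = 24
    unit_dominance: float = 0.29
    climate_coarse_factor: int = 16
    elevation_range: tuple[float, float] = (2200.0, 3100.0)
    elevation_correlation_length: float = 400.0
    climate_normals: dict[str, ClimateNormal] = field(default_factory=_default_climate)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_width < 16 or self.grid_height < 16:
            raise ValueError("grid dimensions must be at least 16 cells")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.climate_coarse_factor < 1:
            raise ValueError("climate_coarse_factor must be >= 1")
        if self.n_units < 2:
            raise ValueError("n_units must be >= 2")
        lo, hi = self.elevation_range
        if not lo < hi:
            raise ValueError("elevation_range must satisfy min < max")
        if self.elevation_correlation_length <= 0:
            raise ValueError("correlation length must be positive")
        for name, cn in self.climate_normals.items():
            if cn.correlation_length <= 0:
                raise ValueError(f"{name}: correlation length must be positive")


@dataclass
class TruthModel:
    """Known log-linear suitability surface of the virtual species.

    coefficients maps layer name -> terms: for the categorical layer a dict
    of per-class offsets, for continuous layers a dict with "linear" and/or
    "quadratic" weights applied to the grid-standardized layer.  truth_raw
    holds relative occurrence rates over cells (nonnegative, sums to 1).
    """

    coefficients: dict
    intercept: float
    truth_raw: np.ndarray

    def __post_init__(self) -> None:
        total = np.nansum(self.truth_raw)
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"truth_raw must sum to 1, sums to {total}")
        if np.nanmin(self.truth_raw) < 0:
            raise ValueError("truth_raw must be nonnegative")

    @property
    def dominant_variables(self) -> list[str]:
        """Layer names ordered by total absolute coefficient weight."""
        weight = {
            name: sum(abs(v) for v in terms.values())
            for name, terms in self.coefficients.items()
        }
        return sorted(weight, key=weight.get, reverse=True)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def _smooth_field(shape: tuple[int, int], sigma_cells: float, rng: np.random.Generator) -> np.ndarray:
    """Spatially autocorrelated field: Gaussian-filtered white noise."""
    noise = rng.standard_normal(shape)
    if sigma_cells > 0:
        noise = ndimage.gaussian_filter(noise, sigma=sigma_cells, mode="reflect")
    return noise


def _standardize(values: np.ndarray, mean: float, sd: float) -> np.ndarray:
    """Affinely rescale to exact mean and spatial SD (population)."""
    v = values - values.mean()
    s = v.std()
    if s > 0 and sd > 0:
        v *= sd / s
    elif sd > 0:
        log.warning("degenerate field: cannot impose a nonzero spatial SD")
    return v + mean


def _power_mosaic(shape, seeds_rc, weights) -> np.ndarray:
    """Additively weighted Voronoi (power diagram) class assignment.

    Cells of a power diagram are convex, so every class is one connected
    region — contiguity by construction, no salt-and-pepper noise.
    """
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    best = None
    labels = np.zeros(shape, dtype=int)
    for k, ((sr, sc), w) in enumerate(zip(seeds_rc, weights)):
        d2 = (rows - sr) ** 2 + (cols - sc) ** 2 - w
        if best is None:
            best = d2
        else:
            take = d2 < best
            labels[take] = k
            best = np.minimum(best, d2)
    return labels


def _categorical_mosaic(params: LandscapeParams, rng: np.random.Generator) -> np.ndarray:
    """Contiguous class mosaic with the largest class near unit_dominance.

    Seeds are placed uniformly; the first seed receives an additive power
    weight calibrated by bisection so its cell covers the requested area
    fraction.
    """
    shape = (params.grid_height, params.grid_width)
    n_cells = shape[0] * shape[1]
    seeds = np.column_stack(
        [rng.uniform(0, shape[0], params.n_units), rng.uniform(0, shape[1], params.n_units)]
    )

    def dominant_fraction(w: float) -> float:
        weights = np.zeros(params.n_units)
        weights[0] = w
        labels = _power_mosaic(shape, seeds, weights)
        return (labels == 0).sum() / n_cells

    lo, hi = 0.0, float(shape[0] ** 2 + shape[1] ** 2)
    target = params.unit_dominance
    if dominant_fraction(0.0) >= target:
        w_star = 0.0
    else:
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if dominant_fraction(mid) < target:
                lo = mid
            else:
                hi = mid
            if abs(dominant_fraction(0.5 * (lo + hi)) - target) < 0.005:
                break
        w_star = 0.5 * (lo + hi)
    weights = np.zeros(params.n_units)
    weights[0] = w_star
    labels = _power_mosaic(shape, seeds, weights)
    # class codes 1..n_units (some units can be swallowed by the dominant
    # cell at extreme dominance; all survivors stay contiguous)
    return labels + 1


def _coarse_shape(params: LandscapeParams) -> tuple[int, int]:
    f = params.climate_coarse_factor
    ch = math.ceil(params.grid_height / f)
    cw = math.ceil(params.grid_width / f)
    if params.grid_height % f or params.grid_width % f:
        log.warning(
            "climate_coarse_factor %d does not divide the grid; coarse grid padded to %dx%d",
            f, ch, cw,
        )
    return ch, cw


def default_truth_coefficients(
    categorical: np.ndarray,
    n_favored: int = 4,
    class_offset: float = 2.0,
) -> dict:
    """Default truth: geologic-unit offsets plus a dominant quadratic
    winter-maximum-temperature response and a weaker winter-minimum term.

    The favored classes are the ``n_favored`` mid-frequency units (largest
    excluded), so favored classes stay rarer than baseline and occupancy
    ratios of roughly 3+ emerge.
    """
    classes, counts = np.unique(categorical[~np.isnan(categorical)].astype(int), return_counts=True)
    order = np.argsort(counts)[::-1]
    favored = [int(classes[i]) for i in order[1 : 1 + n_favored]]
    if not favored:  # two-class degenerate mosaic
        favored = [int(classes[order[0]])]
    return {
        "geology": {c: class_offset for c in favored},
        "tmax_winter": {"linear": 0.0, "quadratic": -2.4},
        "tmin_winter": {"linear": 0.4},
    }


def _truth_surface(stack: LayerStack, coefficients: dict, intercept: float = 0.0) -> np.ndarray:
    eta = np.full(stack.grid.shape, intercept, dtype=float)
    for name, terms in coefficients.items():
        if name not in stack:
            raise ValueError(f"truth coefficient names a missing layer {name!r}")
        vals = stack[name].values
        if stack.kinds[name] == CATEGORICAL:
            for code, off in terms.items():
                eta = eta + np.where(vals == code, off, 0.0)
        else:
            z = (vals - np.nanmean(vals)) / (np.nanstd(vals) or 1.0)
            eta = eta + terms.get("linear", 0.0) * z + terms.get("quadratic", 0.0) * z**2
    eta = eta - np.nanmax(eta)
    raw = np.exp(eta)
    raw[np.isnan(raw)] = 0.0
    return raw / raw.sum()


def generate_landscape(
    params: LandscapeParams,
    truth_coefficients: dict | None = None,
) -> tuple[LayerStack, TruthModel]:
    """Generate the covariate stack and ground-truth suitability surface.

    Layers: ``geology`` (categorical mosaic), ``elevation`` (smooth field
    spanning the requested range), ``slope`` and ``curvature`` (derived),
    ``dist_contact`` (distance to geologic contacts), and one layer per
    climate normal (coarse autocorrelated fields, downscaled bilinearly,
    then calibrated to the exact requested mean and spatial SD).
    """
    rng = np.random.default_rng(params.seed)
    shape = (params.grid_height, params.grid_width)
    origin = (0.0, params.grid_height * params.cell_size)
    stack = LayerStack()

    geology = _categorical_mosaic(params, rng)
    geo_grid = RasterGrid(values=geology.astype(float), cell_size=params.cell_size, origin=origin)
    stack.add("geology", geo_grid, CATEGORICAL)

    sigma_elev = params.elevation_correlation_length / params.cell_size
    elev = _smooth_field(shape, sigma_elev, rng)
    lo, hi = params.elevation_range
    rng_span = elev.max() - elev.min()
    elev = lo + (elev - elev.min()) / (rng_span or 1.0) * (hi - lo)
    elev_grid = RasterGrid(values=elev, cell_size=params.cell_size, origin=origin)
    stack.add("elevation", elev_grid, CONTINUOUS)

    slope = environment.compute_slope(elev_grid)
    stack.add("slope", slope, CONTINUOUS)
    stack.add("curvature", environment.compute_curvature(slope), CONTINUOUS)
    stack.add("dist_contact", environment.distance_to_contacts(geo_grid), CONTINUOUS)

    ch, cw = _coarse_shape(params)
    coarse_cell = params.cell_size * params.climate_coarse_factor
    coarse_origin = (0.0, ch * coarse_cell)  # covers the fine grid (padded)
    for name, cn in params.climate_normals.items():
        sigma = cn.correlation_length / coarse_cell
        coarse = _smooth_field((ch, cw), sigma, rng)
        coarse = _standardize(coarse, cn.mean, cn.spatial_sd)
        coarse_grid = RasterGrid(values=coarse, cell_size=coarse_cell, origin=coarse_origin)
        fine = environment.downscale(coarse_grid, elev_grid)
        vals = fine.values
        if cn.lapse:
            vals = vals + cn.lapse * (elev - elev.mean())
        vals = _standardize(vals, cn.mean, cn.spatial_sd)
        stack.add(name, elev_grid.copy_with(vals), CONTINUOUS)

    coeffs = truth_coefficients if truth_coefficients is not None else default_truth_coefficients(geology)
    truth = TruthModel(coefficients=coeffs, intercept=0.0, truth_raw=_truth_surface(stack, coeffs))
    return stack, truth


def sample_presences(
    truth: TruthModel,
    stack: LayerStack,
    n: int = 189,
    seed: int | None = None,
    distinct: bool = True,
) -> OccurrenceSet:
    """Draw presence cells with probability proportional to truth_raw.

    With ``distinct=True`` (default) cells are drawn without replacement,
    matching the one-record-per-pixel deduplication applied downstream; with
    ``distinct=False`` cells are drawn independently (used for frequency-
    recovery checks).  Records are placed at cell centers with zero error.
    """
    rng = np.random.default_rng(seed)
    grid = stack.grid
    p = truth.truth_raw.ravel()
    support = np.flatnonzero(p > 0)
    if distinct:
        if n > support.size:
            raise ValueError(
                f"requested {n} distinct presences but only {support.size} cells have positive rate"
            )
        # Gumbel top-k: exact weighted sampling without replacement
        keys = np.log(p[support]) + rng.gumbel(size=support.size)
        chosen = support[np.argsort(keys)[::-1][:n]]
    else:
        chosen = rng.choice(p.size, size=n, replace=True, p=p)
    row, col = np.unravel_index(chosen, grid.shape)
    x, y = grid.center_of(row, col)
    df = pd.DataFrame({"x": x, "y": y, "error_m": 0.0})
    df["source_id"] = [f"sim{i}" for i in range(n)]
    return OccurrenceSet(records=df, grid_ref=grid, provenance={"sampled_cells": chosen.tolist()})


def inject_coordinate_error(
    occ: OccurrenceSet,
    error_radii: list[float],
    seed: int | None = None,
) -> OccurrenceSet:
    """Assign each record an error radius and jitter it uniformly in a disk.

    Radii are drawn (with replacement) from ``error_radii``; a record with
    radius r moves to a point uniform on the disk of radius r around its
    original coordinates.  Original coordinates are kept in provenance.
    """
    radii = np.asarray(error_radii, dtype=float)
    if (radii < 0).any():
        raise ValueError("error radii must be nonnegative")
    rng = np.random.default_rng(seed)
    n = len(occ)
    r_assign = radii[rng.integers(0, len(radii), size=n)]
    u = rng.uniform(size=n)
    theta = rng.uniform(0, 2 * np.pi, size=n)
    rho = r_assign * np.sqrt(u)
    df = occ.records.copy()
    prov = dict(occ.provenance)
    prov["original_xy"] = df[["x", "y"]].to_numpy().tolist()
    df["x"] = df["x"] + rho * np.cos(theta)
    df["y"] = df["y"] + rho * np.sin(theta)
    df["error_m"] = r_assign
    return OccurrenceSet(records=df, grid_ref=occ.grid_ref, provenance=prov)
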