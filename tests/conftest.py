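import numpy as np
import pandas as pd
import pytest

from maxhab import environment, maxent, simulate
from maxhab.raster import CATEGORICAL, CONTINUOUS, LayerStack, RasterGrid
from maxhab.simulate import ClimateNormal, LandscapeParams


def small_params(seed: int = 7, **overrides) -> LandscapeParams:
    """A fast 64x64 landscape preserving the full layer roster."""
    defaults = dict(
        grid_width=64,
        grid_height=64,
        cell_size=5.0,
        n_units=6,
        unit_dominance=0.3,
        climate_coarse_factor=16,
        elevation_correlation_length=100.0,
        climate_normals={
            "precip_summer": ClimateNormal(354.0, 30.0, 200.0),
            "tmax_winter": ClimateNormal(12.3, 1.5, 200.0),
            "tmin_winter": ClimateNormal(-2.4, 1.5, 200.0),
        },
        seed=seed,
    )
    defaults.update(overrides)
    return LandscapeParams(**defaults)


@pytest.fixture(scope="session")
def small_landscape():
    return simulate.generate_landscape(small_params())


@pytest.fixture(scope="session")
def training_table(small_landscape):
    """Presence + background covariate table from the small landscape."""
    stack, truth = small_landscape
    occ = simulate.sample_presences(truth, stack, n=60, seed=11)
    bg = environment.sample_background(stack, n=800, seed=12)
    pres = environment.extract(stack, occ.records[["x", "y"]], role="presence")
    back = environment.extract(stack, bg, role="background")
    table = pd.concat([pres, back], ignore_index=True)
    kinds = {n: stack.kinds[n] for n in stack.names}
    return table, kinds


@pytest.fixture(scope="session")
def fitted_lq(training_table):
    table, kinds = training_table
    config = maxent.ModelConfig("LQ", 1.0)
    expansion = maxent.build_features(table, config, kinds)
    model = maxent.fit(expansion, config)
    return model, expansion


def make_grid(values, cell_size=5.0, origin=None) -> RasterGrid:
    values = np.asarray(values, dtype=float)
    if origin is None:
        origin = (0.0, values.shape[0] * cell_size)
    return RasterGrid(values=values, cell_size=cell_size, origin=origin)


def make_binary_expansion(bg_feature, pres_feature) -> maxent.FeatureExpansion:
    """Hand-built single-feature expansion for closed-form fit checks."""
    xb = np.asarray(bg_feature, dtype=float).reshape(-1, 1)
    xp = np.asarray(pres_feature, dtype=float).reshape(-1, 1)
    return maxent.FeatureExpansion(
        features=[maxent.Feature("f", "linear")],
        norm_min=np.array([0.0]),
        norm_max=np.array([1.0]),
        x_presence=xp,
        x_background=xb,
    )
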