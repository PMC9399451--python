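import numpy as np
import pandas as pd
import pytest

from maxhab import environment
from maxhab.raster import CATEGORICAL, LayerStack, RasterGrid

from conftest import make_grid


def brute_force_contact_distance(values: np.ndarray, cell_size: float) -> np.ndarray:
    """All-pairs nearest-boundary search (independent oracle)."""
    h, w = values.shape
    boundary = []
    for r in range(h):
        for c in range(w):
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and values[rr, cc] != values[r, c]:
                    boundary.append((r, c))
                    break
    out = np.full((h, w), np.inf)
    for r in range(h):
        for c in range(w):
            for br, bc in boundary:
                d = np.hypot(r - br, c - bc) * cell_size
                out[r, c] = min(out[r, c], d)
    return out


class TestSlope:
    def test_flat_plane_has_zero_slope(self):
        dem = make_grid(np.full((8, 8), 42.0))
        assert np.all(environment.compute_slope(dem).values == 0.0)

    def test_inclined_plane_slope_is_analytic(self):
        # rises 1 m per 10 m in x on a 10 m grid -> 10% everywhere (interior
        # AND edges, since clamped Horn differences are exact on a plane)
        x = np.arange(12) * 10.0
        dem = make_grid(np.tile(0.1 * x, (9, 1)), cell_size=10.0)
        slope = environment.compute_slope(dem).values
        np.testing.assert_allclose(slope[:, 1:-1], 10.0, atol=1e-9)

    def test_symmetric_ridge_gives_symmetric_slope(self):
        x = np.arange(11.0)
        ridge = -np.abs(x - 5.0)
        dem = make_grid(np.tile(ridge, (7, 1)))
        slope = environment.compute_slope(dem).values
        np.testing.assert_allclose(slope, slope[:, ::-1], atol=1e-12)

    def test_rotation_consistency(self):
        rng = np.random.default_rng(0)
        dem_vals = rng.normal(size=(9, 9))
        s = environment.compute_slope(make_grid(dem_vals)).values
        s_rot = environment.compute_slope(make_grid(np.rot90(dem_vals))).values
        np.testing.assert_allclose(np.rot90(s), s_rot, atol=1e-12)

    def test_missing_neighborhood_marks_cell_missing(self):
        vals = np.ones((5, 5))
        vals[2, 2] = np.nan
        slope = environment.compute_slope(make_grid(vals)).values
        assert np.isnan(slope[1:4, 1:4]).all()
        assert np.isfinite(slope[0, 0])


class TestCurvature:
    def test_constant_slope_plane_has_zero_curvature(self):
        x = np.arange(10) * 5.0
        dem = make_grid(np.tile(0.2 * x, (10, 1)))
        slope = environment.compute_slope(dem)
        # clamped edge columns of the slope layer are halved, so zero
        # curvature holds away from the two outermost columns
        curv = environment.compute_curvature(slope).values
        np.testing.assert_allclose(curv[:, 2:-2], 0.0, atol=1e-9)

    def test_linearly_increasing_slope_field(self):
        # slope value rising at rate r per meter -> curvature 100*r (interior)
        r = 0.03
        x = np.arange(20) * 5.0
        slope_field = make_grid(np.tile(r * x, (8, 1)))
        curv = environment.compute_curvature(slope_field).values
        np.testing.assert_allclose(curv[:, 1:-1], 100.0 * r, atol=1e-9)

    def test_flat_dem_composes_to_zero_curvature(self):
        dem = make_grid(np.zeros((6, 6)))
        curv = environment.compute_curvature(environment.compute_slope(dem))
        assert np.all(curv.values == 0.0)


class TestDistanceToContacts:
    def test_two_half_planes_distance_is_horizontal(self):
        vals = np.ones((6, 10))
        vals[:, 5:] = 2.0
        grid = make_grid(vals, cell_size=5.0)
        dist = environment.distance_to_contacts(grid).values
        # columns 4 and 5 are boundary cells
        assert np.all(dist[:, 4] == 0.0)
        assert np.all(dist[:, 5] == 0.0)
        np.testing.assert_allclose(dist[:, 0], 4 * 5.0)
        np.testing.assert_allclose(dist[:, 9], 4 * 5.0)

    def test_checkerboard_is_zero_everywhere(self):
        vals = np.indices((7, 7)).sum(axis=0) % 2
        dist = environment.distance_to_contacts(make_grid(vals)).values
        assert np.all(dist == 0.0)

    def test_single_class_layer_is_all_missing(self):
        dist = environment.distance_to_contacts(make_grid(np.ones((5, 5)))).values
        assert np.isnan(dist).all()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        shape = (rng.integers(10, 30), rng.integers(10, 30))
        vals = rng.integers(1, 4, size=shape).astype(float)
        # smooth into patches so boundaries are not everywhere
        from scipy import ndimage
        vals = np.round(ndimage.uniform_filter(vals, size=3))
        grid = make_grid(vals, cell_size=3.0)
        got = environment.distance_to_contacts(grid).values
        want = brute_force_contact_distance(vals, 3.0)
        if np.isinf(want).all():
            assert np.isnan(got).all()
        else:
            np.testing.assert_allclose(got, want, atol=1e-9)


class TestDownscale:
    def _coarse(self, vals, cell=20.0):
        return make_grid(vals, cell_size=cell, origin=(0.0, vals.shape[0] * cell))

    def test_constant_field_stays_constant(self):
        coarse = self._coarse(np.full((3, 3), 7.5))
        target = make_grid(np.zeros((12, 12)), cell_size=5.0, origin=(0.0, 60.0))
        np.testing.assert_allclose(environment.downscale(coarse, target).values, 7.5)

    def test_bilinear_midpoint_is_the_average(self):
        coarse = self._coarse(np.array([[0.0, 10.0]]), cell=20.0)
        # fine cell centered exactly midway between the two coarse centers
        target = RasterGrid(values=np.zeros((1, 1)), cell_size=2.0, origin=(19.0, 11.0))
        val = environment.downscale(coarse, target).values[0, 0]
        assert val == pytest.approx(5.0)

    def test_linear_gradient_is_reproduced_exactly(self):
        cx = (np.arange(6) + 0.5) * 20.0
        coarse = self._coarse(np.tile(3.0 * cx, (5, 1)))
        target = make_grid(np.zeros((10, 16)), cell_size=5.0, origin=(20.0, 70.0))
        fine = environment.downscale(coarse, target).values
        tx = 20.0 + (np.arange(16) + 0.5) * 5.0
        np.testing.assert_allclose(fine, np.tile(3.0 * tx, (10, 1)), atol=1e-9)

    def test_interpolation_passes_through_coarse_centers(self):
        rng = np.random.default_rng(5)
        coarse = self._coarse(rng.normal(size=(4, 4)), cell=20.0)
        # odd refinement factor (20 m -> 4 m) makes coarse centers coincide
        # with fine centers: coarse (i, j) sits at fine (5i + 2, 5j + 2)
        target = make_grid(np.zeros((20, 20)), cell_size=4.0, origin=(0.0, 80.0))
        fine = environment.downscale(coarse, target).values
        for i in range(4):
            for j in range(4):
                assert fine[5 * i + 2, 5 * j + 2] == pytest.approx(
                    coarse.values[i, j], abs=1e-12
                )

    def test_categorical_layer_is_rejected(self):
        coarse = self._coarse(np.ones((3, 3)))
        target = make_grid(np.zeros((6, 6)), cell_size=10.0, origin=(0.0, 60.0))
        with pytest.raises(ValueError, match="continuous"):
            environment.downscale(coarse, target, kind=CATEGORICAL)


class TestBackgroundAndExtract:
    def _stack(self, vals):
        stack = LayerStack()
        stack.add("v", make_grid(vals))
        return stack

    def test_exhaustive_draw_returns_every_valid_cell(self):
        stack = self._stack(np.arange(100.0).reshape(10, 10))
        pts = environment.sample_background(stack, n=100, seed=0)
        rows, cols = stack.grid.cell_of(pts["x"].to_numpy(), pts["y"].to_numpy())
        assert len(set(zip(rows, cols))) == 100

    def test_same_seed_same_sample(self):
        stack = self._stack(np.zeros((20, 20)))
        a = environment.sample_background(stack, n=50, seed=42)
        b = environment.sample_background(stack, n=50, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_oversampling_errors_with_counts(self):
        stack = self._stack(np.zeros((5, 5)))
        with pytest.raises(ValueError, match="25"):
            environment.sample_background(stack, n=26)

    def test_missing_cells_are_never_sampled(self):
        vals = np.zeros((6, 6))
        vals[:3] = np.nan
        stack = self._stack(vals)
        pts = environment.sample_background(stack, n=18, seed=1)
        assert (pts["y"] < 15.0).all()  # only the lower (non-missing) half

    def test_extract_at_cell_center_returns_cell_value(self):
        vals = np.arange(16.0).reshape(4, 4)
        stack = self._stack(vals)
        x, y = stack.grid.center_of(2, 3)
        out = environment.extract(stack, pd.DataFrame({"x": [x], "y": [y]}))
        assert out.loc[0, "v"] == vals[2, 3]

    def test_two_points_in_one_cell_get_identical_rows(self):
        stack = self._stack(np.arange(16.0).reshape(4, 4))
        pts = pd.DataFrame({"x": [6.0, 8.0], "y": [6.0, 8.0]})  # both in cell (2,1)
        out = environment.extract(stack, pts)
        assert out.loc[0, "v"] == out.loc[1, "v"]

    def test_rows_on_missing_cells_are_dropped(self):
        vals = np.zeros((4, 4))
        vals[0, 0] = np.nan
        stack = self._stack(vals)
        x0, y0 = stack.grid.center_of(0, 0)
        x1, y1 = stack.grid.center_of(1, 1)
        out = environment.extract(stack, pd.DataFrame({"x": [x0, x1], "y": [y0, y1]}))
        assert len(out) == 1

    def test_points_outside_extent_are_dropped(self):
        stack = self._stack(np.zeros((4, 4)))
        out = environment.extract(stack, pd.DataFrame({"x": [-5.0, 5.0], "y": [5.0, 5.0]}))
        assert len(out) == 1
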