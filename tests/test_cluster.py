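import numpy as np
import pytest

from lagclust.cluster import (
    Grid,
    ORGrid,
    PermutationResult,
    classify_cells,
    contours_to_geojson,
    extract_contours,
    make_grid,
    percent_elevation,
    permutation_null,
    predict_or_map,
)
from lagclust.gam import SpatialLogitGAM, fit_null

from conftest import brute_force_loess


class TestGrid:
    def test_default_grid_is_2500_cells(self):
        pts = np.array([[0.0, 0.0], [10.0, 8.0]])
        grid = make_grid(pts)
        assert grid.nx == grid.ny == 50
        assert grid.n_cells == 2500
        assert grid.bbox == (0.0, 0.0, 10.0, 8.0)

    def test_cell_center_convention_unit_square(self):
        grid = make_grid(np.array([[0.0, 0.0], [1.0, 1.0]]), nx=2, ny=2)
        centers = grid.centers()
        expected = {(0.25, 0.25), (0.75, 0.25), (0.25, 0.75), (0.75, 0.75)}
        assert {tuple(np.round(c, 10)) for c in centers} == expected

    def test_mask_flags_cells_outside_boundary(self):
        from shapely.geometry import box

        grid = make_grid(np.array([[0.0, 0.0], [1.0, 1.0]]), nx=4, ny=4,
                         boundary=box(0.0, 0.0, 0.5, 1.0))
        assert grid.mask.sum() == 8  # right half of the square flagged

    def test_degenerate_bbox_fails(self):
        with pytest.raises(ValueError, match="degenerate"):
            make_grid(np.array([[1.0, 1.0], [1.0, 2.0]]))


def test_percent_elevation_convention():
    """An OR of 1.8 reads as risk elevated 80% vs the whole study area."""
    assert percent_elevation(1.8) == pytest.approx(80.0)
    assert percent_elevation(1.0) == pytest.approx(0.0)
    assert percent_elevation(0.5) == pytest.approx(-50.0)


def _perm_result(count_ge, count_le, n_perm=999):
    grid = Grid(nx=1, ny=1, bbox=(0, 0, 1, 1))
    og = ORGrid(grid=grid, log_odds=np.zeros((1, 1)), odds_ratio=np.ones((1, 1)),
                null_odds=1.0)
    return PermutationResult(n_perm=n_perm, seed=0, alpha=0.025, observed=og,
                             count_ge=np.array([[count_ge]]),
                             count_le=np.array([[count_le]]))


class TestRankRules:
    def test_observed_above_all_permutations_is_hot(self):
        # rank 1/1000: upper tail (0+1)/(999+1) = 0.001 <= 0.025
        assert classify_cells(_perm_result(0, 999))[0, 0] == 1

    def test_boundary_count_24_is_hot_25_is_neutral(self):
        # (24+1)/1000 = 0.025 <= alpha -> hot; (25+1)/1000 = 0.026 -> neutral
        assert classify_cells(_perm_result(24, 975))[0, 0] == 1
        assert classify_cells(_perm_result(25, 974))[0, 0] == 0

    def test_median_is_neutral(self):
        assert classify_cells(_perm_result(500, 499))[0, 0] == 0

    def test_cold_symmetric(self):
        assert classify_cells(_perm_result(999, 0))[0, 0] == -1
        assert classify_cells(_perm_result(974, 25))[0, 0] == 0

    def test_masked_cells_stay_neutral(self):
        r = _perm_result(0, 999)
        object.__setattr__(r.observed.grid, "mask", np.array([[True]]))
        assert classify_cells(r)[0, 0] == 0

    def test_tail_probabilities_add_one_rule(self):
        r = _perm_result(25, 974)
        assert r.upper_p[0, 0] == pytest.approx(0.026)


class TestContours:
    def _grid(self, n=10):
        return Grid(nx=n, ny=n, bbox=(0.0, 0.0, 10.0, 10.0))

    def test_all_neutral_gives_no_contours(self):
        assert extract_contours(np.zeros((10, 10), int), self._grid()) == []

    def test_single_hot_block_gives_one_closed_polygon(self):
        cls = np.zeros((10, 10), int)
        cls[3:6, 3:6] = 1
        conts = extract_contours(cls, self._grid())
        assert len(conts) == 1
        assert conts[0].kind == "high" and conts[0].closed
        # contour encloses the block's cell centers (3.5..5.5 in data coords)
        xs, ys = conts[0].vertices[:, 0], conts[0].vertices[:, 1]
        assert xs.min() < 3.5 and xs.max() > 5.5
        assert ys.min() < 3.5 and ys.max() > 5.5

    def test_two_disjoint_blocks_give_two_polygons(self):
        cls = np.zeros((10, 10), int)
        cls[1:3, 1:3] = 1
        cls[7:9, 7:9] = 1
        assert len(extract_contours(cls, self._grid())) == 2

    def test_hot_and_cold_separately_contoured(self):
        cls = np.zeros((10, 10), int)
        cls[1:3, 1:3] = 1
        cls[7:9, 7:9] = -1
        kinds = sorted(c.kind for c in extract_contours(cls, self._grid()))
        assert kinds == ["high", "low"]

    def test_geojson_roundtrip_labels_pointwise(self, tmp_path):
        cls = np.zeros((10, 10), int)
        cls[4:6, 4:6] = 1
        gj = contours_to_geojson(extract_contours(cls, self._grid()),
                                 tmp_path / "contours.geojson")
        assert gj["features"][0]["properties"]["class"] == "high"
        assert "pointwise" in gj["features"][0]["properties"]["inference"]


class TestORMap:
    def test_null_model_gives_unit_or_everywhere(self):
        y = np.array([1, 0, 1, 0, 1, 0, 0, 0], float)
        coords = np.random.default_rng(0).uniform(0, 1, (8, 2))
        res = SpatialLogitGAM(y, coords, exog=None, span=None).fit()
        null = fit_null(y)
        og = predict_or_map(res, null, make_grid(coords, nx=5, ny=5))
        np.testing.assert_allclose(og.odds_ratio, 1.0, atol=1e-10)

    def test_crude_or_map_matches_loess_oracle_composition(self, eight_points):
        pts, _ = eight_points
        y = np.array([1, 0, 1, 1, 0, 0, 1, 0], float)
        res = SpatialLogitGAM(y, pts, exog=None, span=0.8).fit()
        null = fit_null(y)
        grid = make_grid(pts, nx=6, ny=6)
        og = predict_or_map(res, null, grid)
        smooth = brute_force_loess(pts, res._resid_target, grid.centers(), 0.8,
                                   prior_weights=res._weights)
        eta = res.params[0] + (smooth - res._center)
        expected = np.exp(eta) / null.odds
        assert np.max(np.abs(og.odds_ratio.ravel() - expected)) < 1e-8

    def test_or_frame_schema(self, eight_points):
        pts, _ = eight_points
        y = np.array([1, 0, 1, 1, 0, 0, 1, 0], float)
        res = SpatialLogitGAM(y, pts, exog=None, span=0.8).fit()
        og = predict_or_map(res, fit_null(y), make_grid(pts, nx=3, ny=3))
        df = og.to_frame()
        assert list(df.columns) == ["x", "y", "log_odds", "odds_ratio", "masked"]
        assert len(df) == 9


class TestPermutationNull:
    def _data(self, n=80, seed=0):
        rng = np.random.default_rng(seed)
        coords = rng.uniform(0, 10, (n, 2))
        y = np.zeros(n)
        y[: n // 2] = 1
        rng.shuffle(y)
        return y, coords

    def test_seeded_determinism(self):
        y, coords = self._data()
        grid = make_grid(coords, nx=8, ny=8)
        r1 = permutation_null(y, coords, grid, span=0.7, n_perm=19, seed=5)
        r2 = permutation_null(y, coords, grid, span=0.7, n_perm=19, seed=5)
        np.testing.assert_array_equal(r1.count_ge, r2.count_ge)
        np.testing.assert_array_equal(r1.count_le, r2.count_le)

    def test_counts_bounded_and_complementary(self):
        y, coords = self._data(seed=1)
        grid = make_grid(coords, nx=8, ny=8)
        r = permutation_null(y, coords, grid, span=0.7, n_perm=19, seed=6)
        assert r.count_ge.max() <= 19 and r.count_le.max() <= 19
        # every permutation is counted in at least one tail (ties in both)
        assert np.all(r.count_ge + r.count_le >= 19)

    def test_observed_grid_carried(self):
        y, coords = self._data(seed=2)
        grid = make_grid(coords, nx=8, ny=8)
        r = permutation_null(y, coords, grid, span=0.7, n_perm=9, seed=7)
        assert r.observed.odds_ratio.shape == (8, 8)
        assert np.all(r.observed.odds_ratio > 0)
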