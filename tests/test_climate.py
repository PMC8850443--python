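import numpy as np
import pytest

from cropclim.climate import (
    ClimateGrid,
    GridError,
    MissingDataError,
    ScenarioTrajectory,
    WeightGrid,
    area_weighted_mean,
    build_climatology,
    co2_concentration,
    extract_point,
    precip_change_from_relative,
    read_grid_csv,
    write_grid_csv,
)

LATS = np.array([39.75, 40.25, 40.75, 41.25])
LONS = np.array([-90.75, -90.25, -89.75])


def temp_grid(values=None):
    if values is None:
        values = np.arange(12, dtype=float).reshape(4, 3)
    return ClimateGrid("annual_mean_temp_C", LATS, LONS, values)


class TestGridValidation:
    def test_shape_mismatch(self):
        with pytest.raises(GridError):
            ClimateGrid("annual_mean_temp_C", LATS, LONS, np.zeros((2, 2)))

    def test_bad_cell_center_convention(self):
        with pytest.raises(GridError, match="convention"):
            ClimateGrid("annual_mean_temp_C", LATS + 0.1, LONS, np.zeros((4, 3)))

    def test_unknown_variable(self):
        with pytest.raises(GridError):
            ClimateGrid("wind", LATS, LONS, np.zeros((4, 3)))

    def test_temperature_range(self):
        with pytest.raises(GridError):
            temp_grid(np.full((4, 3), 100.0))

    def test_negative_precip(self):
        with pytest.raises(GridError):
            ClimateGrid("annual_total_precip_mm", LATS, LONS, np.full((4, 3), -1.0))

    def test_negative_weights(self):
        with pytest.raises(GridError):
            WeightGrid(LATS, LONS, np.full((4, 3), -1.0))


class TestClimatology:
    def test_constant_field(self):
        fields = [np.full((4, 3), 15.0)] * 10
        grid = build_climatology(fields, list(range(2001, 2011)), (2001, 2010), LATS, LONS, "annual_mean_temp_C")
        assert np.allclose(grid.values, 15.0)
        assert grid.period_label == "2001-2010"

    def test_two_year_mean(self):
        fields = [np.full((4, 3), 10.0), np.full((4, 3), 20.0)]
        grid = build_climatology(fields, [2001, 2002], (2001, 2002), LATS, LONS, "annual_mean_temp_C")
        assert np.allclose(grid.values, 15.0)

    def test_window_outside_series(self):
        fields = [np.full((4, 3), 10.0)]
        with pytest.raises(GridError, match="window"):
            build_climatology(fields, [1999], (2001, 2010), LATS, LONS, "annual_mean_temp_C")

    def test_commutes_with_subsetting(self):
        rng = np.random.default_rng(0)
        fields = [rng.uniform(0, 30, size=(4, 3)) for _ in range(5)]
        years = list(range(2001, 2006))
        full = build_climatology(fields, years, (2001, 2005), LATS, LONS, "annual_mean_temp_C")
        sub = build_climatology(
            [f[:2, :2] for f in fields], years, (2001, 2005), LATS[:2], LONS[:2], "annual_mean_temp_C"
        )
        assert np.allclose(full.values[:2, :2], sub.values)


class TestExtractPoint:
    def test_cell_center(self):
        assert extract_point(temp_grid(), 40.25, -90.25) == 4.0

    def test_same_cell_same_value(self):
        g = temp_grid()
        assert extract_point(g, 40.10, -90.40) == extract_point(g, 40.45, -90.15)

    def test_boundary_resolves_north_east(self):
        # 40.5 sits between rows 1 and 2 -> north cell (row 2)
        g = temp_grid()
        assert extract_point(g, 40.5, -90.25) == 7.0
        assert extract_point(g, 40.25, -90.5) == 4.0  # east cell (col 1)

    def test_masked_cell(self):
        values = np.arange(12, dtype=float).reshape(4, 3)
        values[1, 1] = np.nan
        with pytest.raises(MissingDataError):
            extract_point(temp_grid(values), 40.25, -90.25)

    def test_outside_extent(self):
        with pytest.raises(GridError):
            extract_point(temp_grid(), 10.0, -90.25)


class TestAreaWeightedMean:
    def weights(self, arr):
        return WeightGrid(LATS, LONS, np.asarray(arr, dtype=float))

    def test_uniform_weights_is_plain_mean(self):
        g = temp_grid()
        w = self.weights(np.ones((4, 3)))
        mask = np.ones((4, 3), dtype=bool)
        assert area_weighted_mean(g, w, mask) == pytest.approx(g.values.mean())

    def test_hand_weighted_example(self):
        values = np.zeros((4, 3))
        values[0, 0], values[0, 1] = 10.0, 20.0
        wts = np.zeros((4, 3))
        wts[0, 0], wts[0, 1] = 1.0, 3.0
        mask = np.zeros((4, 3), dtype=bool)
        mask[0, :2] = True
        assert area_weighted_mean(temp_grid(values), self.weights(wts), mask) == pytest.approx(17.5)

    def test_single_cell_equals_extract_point(self):
        g = temp_grid()
        mask = np.zeros((4, 3), dtype=bool)
        mask[2, 1] = True
        got = area_weighted_mean(g, self.weights(np.ones((4, 3))), mask)
        assert got == extract_point(g, 40.75, -90.25)

    def test_invariant_to_weight_scaling(self):
        rng = np.random.default_rng(1)
        g = temp_grid(rng.uniform(0, 30, (4, 3)))
        wts = rng.uniform(0, 5, (4, 3))
        mask = np.ones((4, 3), dtype=bool)
        a = area_weighted_mean(g, self.weights(wts), mask)
        b = area_weighted_mean(g, self.weights(wts * 7.3), mask)
        assert a == pytest.approx(b)

    def test_within_value_range(self):
        rng = np.random.default_rng(2)
        g = temp_grid(rng.uniform(0, 30, (4, 3)))
        wts = rng.uniform(0, 5, (4, 3))
        mask = rng.random((4, 3)) > 0.4
        got = area_weighted_mean(g, self.weights(wts), mask)
        assert g.values[mask].min() <= got <= g.values[mask].max()

    def test_zero_total_weight(self):
        mask = np.ones((4, 3), dtype=bool)
        with pytest.raises(GridError, match="weight"):
            area_weighted_mean(temp_grid(), self.weights(np.zeros((4, 3))), mask)

    def test_empty_mask(self):
        with pytest.raises(GridError, match="mask"):
            area_weighted_mean(temp_grid(), self.weights(np.ones((4, 3))), np.zeros((4, 3), bool))


class TestCo2:
    traj = ScenarioTrajectory("RCP8.5", ((2005, 379.0), (2050, 541.0), (2100, 936.0)))

    def test_tabulated_year_exact(self):
        assert co2_concentration(self.traj, 2050) == 541.0

    def test_midpoint_interpolation(self):
        assert co2_concentration(self.traj, 2075) == pytest.approx((541.0 + 936.0) / 2)

    def test_outside_span(self):
        with pytest.raises(ValueError):
            co2_concentration(self.traj, 1700)

    def test_monotone_input_monotone_output(self):
        years = np.linspace(2005, 2100, 25)
        ppm = [co2_concentration(self.traj, y) for y in years]
        assert all(b >= a for a, b in zip(ppm, ppm[1:]))

    @pytest.mark.parametrize(
        "points",
        [
            ((2050, 500.0),),  # too few
            ((2050, 500.0), (2050, 510.0)),  # not increasing
            ((2050, -5.0), (2100, 500.0)),  # non-positive ppm
        ],
    )
    def test_trajectory_validation(self, points):
        with pytest.raises(ValueError):
            ScenarioTrajectory("x", points)


class TestPrecipChange:
    def test_positive(self):
        assert precip_change_from_relative(10.0, 800.0) == pytest.approx(80.0)

    def test_zero(self):
        assert precip_change_from_relative(0.0, 1234.0) == 0.0

    def test_negative(self):
        assert precip_change_from_relative(-25.0, 400.0) == pytest.approx(-100.0)

    def test_negative_base_rejected(self):
        with pytest.raises(ValueError):
            precip_change_from_relative(10.0, -1.0)


def test_grid_csv_round_trip(tmp_path):
    values = np.arange(12, dtype=float).reshape(4, 3)
    values[3, 2] = np.nan
    grid = temp_grid(values)
    path = write_grid_csv(grid, tmp_path / "g.csv")
    back = read_grid_csv(path, "annual_mean_temp_C")
    assert np.allclose(back.lats, grid.lats)
    assert np.allclose(back.lons, grid.lons)
    assert np.allclose(back.values, grid.values, equal_nan=True)
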