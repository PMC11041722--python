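"""Seasonal counting, regional averaging, and trend statistics."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

import burnwindows as bw
from burnwindows import trends


def _bool_grid(values, start):
    time = pd.date_range(start, periods=values.shape[0], freq="D")
    coords = {"time": time,
              "lat": np.linspace(35, 45, values.shape[1]),
              "lon": np.linspace(238, 252, values.shape[2])}
    return xr.DataArray(values, coords=coords, dims=("time", "lat", "lon"))


class TestSeasonalCounts:
    def test_all_true_calendar_lengths(self):
        days = _bool_grid(np.ones((365, 1, 1), bool), "1981-01-01")  # non-leap
        assert int(bw.seasonal_counts(days, "annual").sel(year=1981).squeeze()) == 365
        assert int(bw.seasonal_counts(days, "JJA").sel(year=1981).squeeze()) == 92

    def test_december_attaches_to_following_winter(self):
        days = _bool_grid(np.ones((3 * 365 + 1, 1, 1), bool), "1983-06-01")
        djf = bw.seasonal_counts(days, "DJF")
        # DJF 1984 = Dec 1983 + Jan/Feb 1984 (leap year -> 29-day February)
        assert int(djf.sel(year=1984).squeeze()) == 31 + 31 + 29

    def test_incomplete_boundary_seasons_dropped(self):
        # 1981-01-15 .. 1982-02-18 covers no complete calendar year
        days = _bool_grid(np.ones((400, 1, 1), bool), "1981-01-15")
        with pytest.raises(ValueError, match="no complete"):
            bw.seasonal_counts(days, "annual")
        # but a complete embedded season (JJA 1981) is retained
        jja = bw.seasonal_counts(days, "JJA")
        assert list(jja.year.values) == [1981]

    def test_first_winter_without_december_dropped(self, weather):
        rx = xr.ones_like(weather.tmax, dtype=bool)
        djf = bw.seasonal_counts(rx, "DJF")
        assert djf.year.values.min() == 1982  # Dec 1980 is absent

    def test_random_booleans_match_masked_tally(self, rng):
        vals = rng.random((3 * 365, 2, 2)) < 0.4
        days = _bool_grid(vals, "1981-01-01")
        got = bw.seasonal_counts(days, "MAM")
        months = days.time.dt.month.values
        years = days.time.dt.year.values
        for year in got.year.values:
            sel = (years == year) & np.isin(months, (3, 4, 5))
            np.testing.assert_array_equal(got.sel(year=year).values,
                                          vals[sel].sum(axis=0))


class TestRegionalMean:
    def test_uniform_field_passes_through(self):
        counts = xr.DataArray(np.full((2, 4, 4), 7.0),
                              coords={"year": [1981, 1982],
                                      "lat": np.linspace(33, 47, 4),
                                      "lon": np.linspace(237, 255, 4)},
                              dims=("year", "lat", "lon"))
        out = bw.regional_mean(counts, bw.WUS_DOMAIN)
        np.testing.assert_allclose(out.values, 7.0)

    def test_two_band_grid_matches_hand_computed_weights(self):
        lat = np.array([30.0, 60.0])
        counts = xr.DataArray(np.array([[[10.0], [20.0]]]),
                              coords={"year": [2000], "lat": lat, "lon": [100.0]},
                              dims=("year", "lat", "lon"))
        region = bw.RegionBox("box", 0.0, 90.0, 0.0, 360.0)
        w0, w1 = np.cos(np.deg2rad(30.0)), np.cos(np.deg2rad(60.0))
        expected = (10.0 * w0 + 20.0 * w1) / (w0 + w1)
        assert float(bw.regional_mean(counts, region).squeeze()) == pytest.approx(expected)

    def test_land_mask_excludes_cells(self):
        counts = xr.DataArray(np.array([[[10.0, 50.0]]]),
                              coords={"year": [2000], "lat": [40.0],
                                      "lon": [240.0, 241.0]},
                              dims=("year", "lat", "lon"))
        mask = xr.DataArray(np.array([[True, False]]),
                            coords={"lat": [40.0], "lon": [240.0, 241.0]},
                            dims=("lat", "lon"))
        region = bw.RegionBox("box", 30.0, 50.0, 230.0, 250.0)
        assert float(bw.regional_mean(counts, region, land_mask=mask).squeeze()) == 10.0

    def test_region_outside_grid_errors(self):
        counts = xr.DataArray(np.ones((1, 2, 2)),
                              coords={"year": [2000], "lat": [40.0, 41.0],
                                      "lon": [240.0, 241.0]},
                              dims=("year", "lat", "lon"))
        with pytest.raises(ValueError):
            bw.regional_mean(counts, bw.RegionBox("off", 0.0, 5.0, 10.0, 20.0))


class TestLinearTrend:
    def test_exact_fit_on_noiseless_line(self):
        years = np.arange(1981, 2021)
        series = pd.Series(2.0 + 0.5 * np.arange(40), index=years)
        tr = bw.linear_trend(series)
        assert tr.slope == pytest.approx(0.5)
        assert tr.accumulated == pytest.approx(19.5)
        assert tr.baseline == pytest.approx(2.0)
        assert tr.percent == pytest.approx(100.0 * 19.5 / 2.0)

    def test_constant_series_has_zero_trend(self):
        tr = bw.linear_trend(pd.Series(np.full(10, 5.0), index=np.arange(10)))
        assert tr.slope == 0.0 and tr.accumulated == 0.0

    def test_percent_times_baseline_recovers_accumulated(self, rng):
        series = pd.Series(50 + rng.normal(0, 3, 30), index=np.arange(1981, 2011))
        tr = bw.linear_trend(series)
        assert tr.percent / 100.0 * tr.baseline == pytest.approx(tr.accumulated)

    def test_type_one_error_rate_near_five_percent(self):
        rng = np.random.default_rng(99)
        years = np.arange(1981, 2021)
        hits = 0
        for _ in range(1000):
            tr = bw.linear_trend(pd.Series(rng.normal(0, 1, 40), index=years))
            hits += tr.p_value < 0.05
        assert abs(hits / 1000 - 0.05) < 0.02

    def test_input_validation(self):
        with pytest.raises(ValueError):
            bw.linear_trend(pd.Series([1.0, 2.0]))
        with pytest.raises(ValueError):
            bw.linear_trend(pd.Series([1.0, 2.0, 3.0], index=[5, 5, 5]))


class TestRunningMean:
    def test_interior_of_linear_series_unchanged(self):
        y = np.arange(10.0)
        out = bw.running_mean(y, 5)
        np.testing.assert_allclose(out[2:-2], y[2:-2])

    def test_constant_series_unchanged_including_endpoints(self):
        out = bw.running_mean(np.full(8, 3.0), 5)
        np.testing.assert_allclose(out, 3.0)

    def test_impulse_spreads_one_fifth(self):
        y = np.zeros(11)
        y[5] = 1.0
        out = bw.running_mean(y, 5)
        np.testing.assert_allclose(out[3:8], 0.2)

    def test_endpoints_use_truncated_windows(self):
        y = np.arange(10.0)
        out = bw.running_mean(y, 5)
        assert out[0] == pytest.approx(np.mean(y[:3]))
        assert len(out) == len(y)


class TestEpochDifference:
    @staticmethod
    def _counts(rng):
        return xr.DataArray(rng.poisson(30, (20, 3, 3)).astype(float),
                            coords={"year": np.arange(1981, 2001),
                                    "lat": np.arange(3.0), "lon": np.arange(3.0)},
                            dims=("year", "lat", "lon"))

    def test_identical_epochs_are_zero(self, rng):
        counts = self._counts(rng)
        with pytest.warns(UserWarning, match="overlap"):
            diff = bw.epoch_difference(counts, (1981, 1990), (1981, 1990))
        np.testing.assert_allclose(diff.values, 0.0)

    def test_constant_shift_recovered(self, rng):
        counts = self._counts(rng)
        shifted = counts.copy()
        shifted.loc[dict(year=slice(1991, 2000))] = counts.sel(
            year=slice(1991, 2000)) - 5.0
        base = bw.epoch_difference(counts, (1981, 1990), (1991, 2000))
        moved = bw.epoch_difference(shifted, (1981, 1990), (1991, 2000))
        np.testing.assert_allclose((moved - base).values, -5.0)

    def test_matches_brute_force_means(self, rng):
        counts = self._counts(rng)
        diff = bw.epoch_difference(counts, (1981, 1990), (1991, 2000))
        expected = (counts.values[10:].mean(axis=0) - counts.values[:10].mean(axis=0))
        np.testing.assert_allclose(diff.values, expected)

    def test_epoch_outside_range_errors(self, rng):
        with pytest.raises(ValueError):
            bw.epoch_difference(self._counts(rng), (1970, 1980), (1991, 2000))


class TestEnsembleStatistics:
    def test_identical_members(self):
        s = pd.Series(np.linspace(50, 30, 21), index=np.arange(1981, 2002))
        out = bw.ensemble_statistics([s, s, s], threshold=10, direction="decrease")
        pd.testing.assert_series_equal(out["mean_series"], s, check_names=False)
        assert out["n_agree"] == 3
        assert bw.ensemble_statistics([s, s, s], 30, "decrease")["n_agree"] == 0

    def test_constructed_accumulated_changes(self):
        years = np.arange(1981, 2021)
        members = [pd.Series(50 + c * np.linspace(0, 1, 40), index=years)
                   for c in (-12.0, -11.0, -3.0)]
        out = bw.ensemble_statistics(members, threshold=10, direction="decrease")
        assert out["n_agree"] == 2
        np.testing.assert_allclose(sorted(out["accumulated_changes"]),
                                   [-12, -11, -3], atol=1e-9)

    def test_permutation_invariance_and_ragged_error(self):
        years = np.arange(2000, 2010)
        a = pd.Series(np.arange(10.0), index=years)
        b = pd.Series(np.arange(10.0)[::-1], index=years)
        n1 = bw.ensemble_statistics([a, b], 5, "decrease")["n_agree"]
        n2 = bw.ensemble_statistics([b, a], 5, "decrease")["n_agree"]
        assert n1 == n2 == 1
        with pytest.raises(ValueError):
            bw.ensemble_statistics([a, a.iloc[:5]], 5)


class TestInterannualSd:
    def test_constant_counts_give_zero(self):
        counts = xr.DataArray(np.full((5, 2, 2), 30.0),
                              coords={"year": np.arange(5), "lat": [0, 1.0],
                                      "lon": [0, 1.0]}, dims=("year", "lat", "lon"))
        np.testing.assert_allclose(bw.interannual_sd(counts).values, 0.0)

    def test_alternating_counts_closed_form(self):
        vals = np.tile(np.array([10.0, 20.0]), 5)
        counts = xr.DataArray(vals[:, None, None],
                              coords={"year": np.arange(10), "lat": [0.0],
                                      "lon": [0.0]}, dims=("year", "lat", "lon"))
        expected = np.std(vals, ddof=1)  # = 5.270 for n=10 alternating
        assert float(bw.interannual_sd(counts).squeeze()) == pytest.approx(expected)

    def test_matches_brute_force_per_cell(self, rng):
        counts = xr.DataArray(rng.poisson(25, (15, 3, 3)).astype(float),
                              coords={"year": np.arange(15), "lat": np.arange(3.0),
                                      "lon": np.arange(3.0)},
                              dims=("year", "lat", "lon"))
        got = bw.interannual_sd(counts).values
        expected = counts.values.std(axis=0, ddof=1)
        np.testing.assert_allclose(got, expected)

    def test_single_year_errors(self):
        counts = xr.DataArray(np.ones((1, 1, 1)),
                              coords={"year": [2000], "lat": [0.0], "lon": [0.0]},
                              dims=("year", "lat", "lon"))
        with pytest.raises(ValueError):
            bw.interannual_sd(counts)


def test_trend_recovery_on_binomial_rxday_series():
    """OLS slope is unbiased for counts with binomial day-level noise."""
    rng = np.random.default_rng(7)
    n_days, beta, p0 = 180, 0.25, 0.30
    years = np.arange(1981, 2021)
    slopes = []
    for _ in range(200):
        p = np.clip(p0 + beta * (years - years[0]) / n_days, 0, 1)
        counts = rng.binomial(n_days, p)
        slopes.append(bw.linear_trend(pd.Series(counts.astype(float),
                                                index=years)).slope)
    mean_slope = np.mean(slopes)
    se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
    assert abs(mean_slope - beta) < 2 * se + 1e-9
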