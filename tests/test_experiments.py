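"""Windowed fit/forecast/validate protocol, proxy correlation, station
averaging and lag analyses."""

import numpy as np
import pandas as pd
import pytest

import ibexdyn as ib

from conftest import DATA


class TestRunWindowed:
    def test_self_consistent_series_rarely_alarms(self, default_spec):
        """Without an intervention the model validates its own data over
        the alarm-bell horizon: most replicates see no band exit in the
        four forecast years (over long horizons even a calibrated 90%
        band is eventually left, so exit rarity is a short-horizon
        property)."""
        no_exit = 0
        n_rep = 60
        for s in ib.child_seeds(1001, n_rep):
            spec = default_spec.with_(seed=int(s), n_years=24)
            clim = ib.generate_climate(spec)
            obs, _ = ib.generate_census(spec, clim)
            exp = ib.run_windowed(obs, clim, spec.variant,
                                  spec.start_year + 20, n_real=500,
                                  seed=int(s) + 1)
            assert exp.fit_window == (spec.start_year, spec.start_year + 20)
            no_exit += exp.report.first_exit_year is None
        assert no_exit / n_rep > 0.5

    def test_intervention_detected_near_changepoint(self, default_spec):
        tau = default_spec.start_year + 15
        spec = default_spec.with_(n_years=20, seed=13, changepoint_year=tau,
                                  removal_rate=0.2)
        clim = ib.generate_climate(spec)
        obs, _ = ib.generate_census(spec, clim)
        exp = ib.run_windowed(obs, clim, spec.variant, tau - 1,
                              n_real=1000, seed=2)
        assert exp.report.first_exit_year is not None
        assert tau <= exp.report.first_exit_year <= tau + 3

    def test_result_components_consistent(self, generated):
        spec, clim, obs, _ = generated
        exp = ib.run_windowed(obs, clim, spec.variant,
                              spec.start_year + 12, n_real=200, seed=4)
        assert exp.model.variant == exp.variant
        assert exp.forecast.seed == exp.seed
        assert exp.forecast.n_real == exp.n_real
        assert exp.forecast_window[0] == exp.fit_window[1] + 1
        assert set(exp.report.years) <= set(exp.forecast.years)

    def test_fit_end_at_series_end_degenerates_gracefully(self, generated):
        spec, clim, obs, _ = generated
        exp = ib.run_windowed(obs, clim, spec.variant,
                              int(obs.year.max()), n_real=50, seed=1)
        assert exp.forecast_window is None
        assert exp.report.years.size == 0
        assert np.isnan(exp.report.coverage)
        assert exp.report.first_exit_year is None

    def test_too_short_fit_window_propagates(self, generated):
        spec, clim, obs, _ = generated
        with pytest.raises(ib.TooFewObservationsError):
            ib.run_windowed(obs, clim, spec.variant, spec.start_year + 3)


class TestProxyCorrelation:
    def _series(self, years, vals):
        return ib.ClimateSeries(years, vals)

    def test_identical_series_give_one(self):
        a = self._series([1925, 1926, 1927, 1928], [400, 350, 500, 450])
        assert ib.proxy_correlation(a, a).r_squared == pytest.approx(1.0)

    def test_affine_invariance_and_symmetry(self):
        years = np.array([1925, 1926, 1927, 1928, 1929])
        vals = np.array([400.0, 350, 500, 450, 300])
        a = self._series(years, vals)
        b = self._series(years, 2 * vals + 7)
        assert ib.proxy_correlation(a, b).r_squared == pytest.approx(1.0)
        ab = ib.proxy_correlation(a, b).r_squared
        ba = ib.proxy_correlation(b, a).r_squared
        assert ab == pytest.approx(ba, rel=1e-12)

    def test_six_pair_fixture_matches_direct_formula(self):
        df = pd.read_csv(DATA / "proxy_pairs.csv")
        a = self._series(df["year"], df["station_avg_mm"])
        b = self._series(df["year"], df["snow_proxy_mm"])
        rep = ib.proxy_correlation(a, b)
        x, y = df["station_avg_mm"].to_numpy(float), df["snow_proxy_mm"].to_numpy(float)
        xc, yc = x - x.mean(), y - y.mean()
        r2 = (xc @ yc) ** 2 / ((xc @ xc) * (yc @ yc))  # Pearson, by hand
        assert rep.n_pairs == 6
        assert rep.r_squared == pytest.approx(r2, abs=1e-10)

    def test_too_few_pairs_rejected(self):
        a = self._series([1925, 1926], [400, 350])
        with pytest.raises(ValueError, match="at least 3"):
            ib.proxy_correlation(a, a)

    def test_window_restricts_pairs(self):
        years = np.arange(1922, 1939)
        rng = np.random.default_rng(0)
        a = self._series(years, rng.uniform(200, 600, years.size))
        b = self._series(years, rng.uniform(200, 600, years.size))
        rep = ib.proxy_correlation(a, b, window=(1925, 1930))
        assert rep.n_pairs == 6 and rep.window == (1925, 1930)


class TestStationAverage:
    def test_single_station_is_identity(self):
        s = ib.ClimateSeries([1925, 1926], [400.0, 350.0])
        avg = ib.station_average([s])
        np.testing.assert_allclose(avg.precip, s.precip)
        assert list(avg.n_stations) == [1, 1]

    def test_two_stations_mean(self):
        s1 = ib.ClimateSeries([1925], [100.0])
        s2 = ib.ClimateSeries([1925], [300.0])
        avg = ib.station_average([s1, s2])
        assert avg.precip[0] == pytest.approx(200.0)

    def test_missing_year_uses_available_stations(self):
        s1 = ib.ClimateSeries([1925, 1926], [100.0, 200.0])
        s2 = ib.ClimateSeries([1925, 1926], [300.0, 400.0])
        s3 = ib.ClimateSeries([1925], [200.0])  # misses 1926
        avg = ib.station_average([s1, s2, s3])
        assert avg.precip[avg.year == 1926][0] == pytest.approx(300.0)
        assert avg.n_stations[avg.year == 1926][0] == 2
        assert avg.n_stations[avg.year == 1925][0] == 3

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        stations = [ib.ClimateSeries(np.arange(1922, 1939),
                                     rng.uniform(200, 600, 17))
                    for _ in range(3)]
        a = ib.station_average(stations)
        b = ib.station_average(stations[::-1])
        np.testing.assert_allclose(a.precip, b.precip, rtol=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            ib.station_average([])


class TestLaggedCorrelation:
    def _coupled(self, n=30, lag=1, seed=0):
        """Population changes exactly reproduce warden changes lag years
        earlier."""
        rng = np.random.default_rng(seed)
        years = np.arange(1920, 1920 + n)
        w = 40 + np.cumsum(rng.integers(-3, 4, size=n))
        pop = np.empty(n)
        pop[0] = 2000
        dw = np.diff(w)
        for t in range(1, n):
            dpop = dw[t - 1 - lag] if t - 1 - lag >= 0 else 0
            pop[t] = pop[t - 1] + dpop
        return (ib.WardenSeries(years, np.maximum(w, 1)),
                ib.PopulationSeries(years, pop))

    def test_perfect_lag_one_coupling(self):
        wardens, pop = self._coupled(lag=1)
        assert ib.lagged_correlation(wardens, pop, lag=1) == pytest.approx(1.0)

    def test_lag_zero_weaker_than_lag_one_on_coupled_series(self):
        wardens, pop = self._coupled(lag=1)
        c1 = ib.lagged_correlation(wardens, pop, lag=1)
        c0 = ib.lagged_correlation(wardens, pop, lag=0)
        assert c0 < c1

    def test_independent_noise_brackets_zero(self):
        """On long independent series the lag-1 change correlation sits
        inside a 95% permutation interval around zero."""
        rng = np.random.default_rng(2)
        years = np.arange(1800, 2000)
        driver = ib.WardenSeries(years, 40 + rng.normal(0, 5, 200).cumsum() % 30 + 5)
        resp = ib.PopulationSeries(years, 2000 + np.abs(rng.normal(0, 50, 200).cumsum()))
        obs = ib.lagged_correlation(driver, resp, lag=1)
        dw = np.diff(driver.wardens)[:-1]
        dp = np.diff(resp.count)[1:]
        perms = np.array([
            np.corrcoef(rng.permutation(dw), dp)[0, 1] for _ in range(500)
        ])
        lo, hi = np.quantile(perms, [0.025, 0.975])
        assert lo <= obs <= hi

    def test_too_few_pairs_rejected(self):
        w = ib.WardenSeries([1930, 1931, 1932], [40, 41, 39])
        p = ib.PopulationSeries([1930, 1931, 1932], [100, 110, 120])
        with pytest.raises(ValueError, match="need 3"):
            ib.lagged_correlation(w, p, lag=1)

    def test_levels_mode_available(self):
        wardens, pop = self._coupled(lag=1)
        c = ib.lagged_correlation(wardens, pop, lag=1, use_changes=False)
        assert -1.0 <= c <= 1.0


class TestSeasonalConsistency:
    def test_identical_counts_give_one(self):
        s = ib.PopulationSeries([1930, 1931, 1932], [100, 120, 110],
                                season="spring")
        a = ib.PopulationSeries([1930, 1931, 1932], [100, 120, 110],
                                season="autumn")
        assert ib.seasonal_consistency(s, a) == pytest.approx(1.0)

    def test_proportional_counts_with_small_noise_strongly_correlated(self):
        rng = np.random.default_rng(9)
        years = np.arange(1920, 1950)
        spring = rng.uniform(2000, 4000, years.size)
        autumn = 0.9 * spring + rng.normal(0, 0.01 * spring.mean(), years.size)
        c = ib.seasonal_consistency(
            ib.PopulationSeries(years, spring, season="spring"),
            ib.PopulationSeries(years, autumn, season="autumn"))
        assert c > 0.95

    def test_disjoint_years_rejected(self):
        s = ib.PopulationSeries([1930, 1931, 1932], [100, 120, 110])
        a = ib.PopulationSeries([1940, 1941, 1942], [100, 120, 110])
        with pytest.raises(ValueError, match="common years"):
            ib.seasonal_consistency(s, a)
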