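"""Cumulative models, CTMI temperature response, fitting, optimal HRT."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biogaskit.kinetics import (
    BatchKineticsParams,
    BatchSeries,
    TemperatureResponse,
    cumulative_model,
    first_order_cumulative,
    fit_kinetics,
    gompertz_cumulative,
    optimal_hrt,
    read_series_csv,
    simulate_batch,
    temperature_factor,
    write_series_csv,
)

GOMPERTZ_REF = BatchKineticsParams(b0=100.0, rmax=10.0, lag=5.0)


class TestCumulativeModels:
    def test_gompertz_value_at_lag(self):
        # B(lag) = b0 * exp(-e)
        assert gompertz_cumulative(GOMPERTZ_REF, 5.0) == pytest.approx(
            100.0 * math.exp(-math.e), rel=1e-12
        )

    def test_gompertz_approaches_asymptote(self):
        assert gompertz_cumulative(GOMPERTZ_REF, 200.0) == pytest.approx(
            100.0, rel=1e-3
        )

    def test_first_order_origin_and_half_life(self):
        p = BatchKineticsParams(b0=100.0, k=0.1, model_id="first_order")
        assert first_order_cumulative(p, 0.0) == 0.0
        assert first_order_cumulative(p, math.log(2) / 0.1) == pytest.approx(50.0)
        assert first_order_cumulative(p, 10.0) == pytest.approx(63.212, abs=1e-3)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            gompertz_cumulative(GOMPERTZ_REF, -1.0)

    @given(
        b0=st.floats(1.0, 1000.0),
        rmax=st.floats(0.1, 100.0),
        lag=st.floats(0.0, 20.0),
        k=st.floats(0.01, 2.0),
        model=st.sampled_from(["gompertz", "first_order"]),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_and_bounded(self, b0, rmax, lag, k, model):
        """All cumulative models are non-decreasing and bounded by b0."""
        p = BatchKineticsParams(b0=b0, rmax=rmax, lag=lag, k=k, model_id=model)
        t = np.linspace(0.0, 120.0, 300)
        y = np.asarray(cumulative_model(p, t))
        assert np.all(np.diff(y) >= -1e-9 * b0)
        assert np.all(y <= b0 * (1 + 1e-12))


class TestTemperatureFactor:
    def test_unity_at_optimum(self):
        assert temperature_factor(35.0) == 1.0

    @pytest.mark.parametrize("T", [45.0, 50.0, 10.0, 0.0])
    def test_zero_at_and_beyond_cardinal_bounds(self, T):
        assert temperature_factor(T) == 0.0

    def test_psychrophilic_value_by_direct_formula(self):
        # (25-45)(25-10)^2 / {25 * [25*(25-35) - (-10)*(45-50)]} = -4500/-7500
        assert temperature_factor(25.0) == pytest.approx(0.6, rel=1e-12)

    def test_invalid_cardinal_ordering(self):
        with pytest.raises(ValueError):
            TemperatureResponse(t_min=35.0, t_opt=35.0, t_max=45.0)


class TestSimulateBatch:
    times = np.arange(0.0, 31.0)

    def test_optimum_temperature_reproduces_unscaled_model(self):
        s = simulate_batch(GOMPERTZ_REF, TemperatureResponse(), 35.0, self.times)
        expected = np.asarray(cumulative_model(GOMPERTZ_REF, self.times))
        np.testing.assert_allclose(s.cumulative_biogas, expected, rtol=1e-14)

    def test_psychrophilic_curve_below_mesophilic(self):
        # Rate scaling slows the curve from the lag onward; before the lag
        # both parameterizations produce only the small sub-lag tail
        # (bounded by B(lag) = b0*exp(-e)) where pointwise ordering flips.
        s25 = simulate_batch(GOMPERTZ_REF, TemperatureResponse(), 25.0, self.times)
        s35 = simulate_batch(GOMPERTZ_REF, TemperatureResponse(), 35.0, self.times)
        after_lag = self.times >= GOMPERTZ_REF.lag
        assert np.all(
            s25.cumulative_biogas[after_lag] <= s35.cumulative_biogas[after_lag] + 1e-9
        )
        # before the lag both curves stay below the lag-time value b0*exp(-e)
        cap = GOMPERTZ_REF.b0 * math.exp(-math.e) + 1e-9
        assert np.all(s25.cumulative_biogas[~after_lag] < cap)
        assert np.all(s35.cumulative_biogas[~after_lag] < cap)

    def test_thermophilic_boundary_is_dead_and_flagged(self):
        s = simulate_batch(GOMPERTZ_REF, TemperatureResponse(), 45.0, self.times)
        assert np.all(s.cumulative_biogas == 0.0)
        assert "no_production" in s.flags

    def test_time_to_95_percent_longer_when_cold(self):
        def t95(T):
            f = temperature_factor(T)
            return optimal_hrt(GOMPERTZ_REF.scaled_rate(f), q=0.95)

        assert t95(25.0) > t95(35.0)

    def test_methane_series_is_fraction_times_biogas(self):
        s = simulate_batch(
            GOMPERTZ_REF, TemperatureResponse(), 35.0, self.times, methane_fraction=0.5
        )
        np.testing.assert_allclose(
            s.cumulative_methane, 0.5 * s.cumulative_biogas, rtol=1e-14
        )


class TestFitKinetics:
    def _series(self, y, t=None):
        t = np.arange(0.0, 31.0) if t is None else t
        return BatchSeries(
            times=t,
            cumulative_biogas=np.maximum.accumulate(np.clip(y, 0, None)),
            methane_fraction=np.full(len(t), 0.41),
        )

    def test_exact_data_recovery(self):
        t = np.arange(0.0, 31.0)
        y = np.asarray(cumulative_model(GOMPERTZ_REF, t))
        r = fit_kinetics(self._series(y, t))
        assert r.converged
        assert r.params.b0 == pytest.approx(100.0, rel=1e-6)
        assert r.params.rmax == pytest.approx(10.0, rel=1e-6)
        assert r.params.lag == pytest.approx(5.0, rel=1e-6)
        assert r.sse < 1e-12

    def test_first_order_exact_recovery(self):
        t = np.arange(0.0, 31.0)
        p = BatchKineticsParams(b0=200.0, k=0.12, model_id="first_order")
        y = np.asarray(cumulative_model(p, t))
        r = fit_kinetics(self._series(y, t), model_id="first_order")
        assert r.params.b0 == pytest.approx(200.0, rel=1e-6)
        assert r.params.k == pytest.approx(0.12, rel=1e-6)

    def test_noisy_recovery_within_5_percent(self):
        rng = np.random.default_rng(7)
        t = np.arange(0.0, 31.0)
        y = np.asarray(cumulative_model(GOMPERTZ_REF, t)) + 2.0 * rng.standard_normal(
            len(t)
        )
        r = fit_kinetics(self._series(y, t))
        assert r.params.b0 == pytest.approx(100.0, rel=0.05)

    def test_too_few_observations(self):
        t = np.array([0.0, 1.0, 2.0])
        with pytest.raises(ValueError, match="4"):
            fit_kinetics(self._series(np.array([0.0, 1.0, 2.0]), t))

    def test_random_init_is_seed_deterministic(self):
        rng = np.random.default_rng(3)
        t = np.arange(0.0, 31.0)
        y = np.asarray(cumulative_model(GOMPERTZ_REF, t)) + rng.standard_normal(len(t))
        s = self._series(y, t)
        r1 = fit_kinetics(s, init_strategy="random", seed=11)
        r2 = fit_kinetics(s, init_strategy="random", seed=11)
        assert r1.params == r2.params

    def test_stderr_reported(self):
        rng = np.random.default_rng(5)
        t = np.arange(0.0, 31.0)
        y = np.asarray(cumulative_model(GOMPERTZ_REF, t)) + rng.standard_normal(len(t))
        r = fit_kinetics(self._series(y, t))
        assert set(r.stderr) == {"b0", "rmax", "lag"}
        assert r.stderr["b0"] is not None and r.stderr["b0"] > 0


class TestOptimalHrt:
    def test_first_order_closed_form(self):
        p = BatchKineticsParams(b0=100.0, k=0.1, model_id="first_order")
        assert optimal_hrt(p, q=0.95) == pytest.approx(math.log(20) / 0.1, abs=0.02)

    def test_gompertz_peak_rate_at_inflection(self):
        """Peak daily rate occurs at t = lag + b0/(rmax*e); cross-check by grid."""
        t_star = optimal_hrt(GOMPERTZ_REF, criterion="peak_daily_rate")
        assert t_star == pytest.approx(5.0 + 100.0 / (10.0 * math.e), abs=0.01)
        grid = np.linspace(0.0, 40.0, 40001)
        rates = np.gradient(np.asarray(cumulative_model(GOMPERTZ_REF, grid)), grid)
        assert t_star == pytest.approx(grid[np.argmax(rates)], abs=0.01)

    def test_hrt_monotone_in_q(self):
        qs = [0.5, 0.8, 0.9, 0.95, 0.99]
        ts = [optimal_hrt(GOMPERTZ_REF, q=q) for q in qs]
        assert ts == sorted(ts)

    @pytest.mark.parametrize("q", [0.0, 1.0, -0.2, 1.5])
    def test_invalid_q(self, q):
        with pytest.raises(ValueError):
            optimal_hrt(GOMPERTZ_REF, q=q)

    def test_first_order_peak_rate_is_at_start(self):
        p = BatchKineticsParams(b0=100.0, k=0.1, model_id="first_order")
        assert optimal_hrt(p, criterion="peak_daily_rate") == 0.0


class TestSeriesCsv:
    def test_round_trip(self, tmp_path):
        s = simulate_batch(
            GOMPERTZ_REF, TemperatureResponse(), 35.0, np.arange(0.0, 31.0, 7.0),
            reactor_id="r1", ph=8.5, loading_ratio="1:3",
        )
        path = tmp_path / "series.csv"
        write_series_csv([s], path)
        [back] = read_series_csv(path)
        np.testing.assert_allclose(back.cumulative_biogas, s.cumulative_biogas)
        assert back.reactor_id == "r1"
        assert back.ph == 8.5
        assert back.loading_ratio == "1:3"

    def test_missing_columns_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("reactor_id,day\nr0,1\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_series_csv(p)


def test_batch_series_rejects_decreasing_cumulative():
    with pytest.raises(ValueError):
        BatchSeries(
            times=np.array([0.0, 1.0, 2.0]),
            cumulative_biogas=np.array([0.0, 5.0, 4.0]),
            methane_fraction=np.array([0.4, 0.4, 0.4]),
        )
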