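import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from maizephen import (
    OutsideThermalLimits,
    PhaseNotCompletedError,
    TemperatureSeries,
    accumulate_development,
    daily_mean_temperature,
    duration_at_constant_temperature,
    evaluate_rate,
    predict_cycle,
    predict_phase_duration,
)
from conftest import brute_force_duration

# linear degree-day parameters giving exactly r = 0.02/day at 25 °C
DD_R002 = np.array([5.0, 1000.0])


def constant_series(T, n=400):
    return TemperatureSeries.constant(T, n)


class TestDailyMeanTemperature:
    def test_midpoint(self):
        assert daily_mean_temperature(20.0, 20.0) == 20.0
        # Kiboswa-like extremes
        assert daily_mean_temperature(17.0, 29.4) == pytest.approx(23.2)

    def test_sine_mode_on_constant_day(self):
        assert daily_mean_temperature(20.0, 20.0, method="sine") == 20.0

    def test_inverted_extremes_rejected(self):
        with pytest.raises(ValueError):
            daily_mean_temperature(25.0, 20.0)


class TestSeriesValidation:
    def test_gap_in_dates_rejected(self):
        dates = np.array(["2004-03-01", "2004-03-02", "2004-03-04"], dtype="datetime64[D]")
        with pytest.raises(ValueError, match="one day"):
            TemperatureSeries(dates, np.zeros(3) + 15, np.zeros(3) + 25)

    def test_tmin_above_tmax_rejected(self):
        with pytest.raises(ValueError, match="tmin > tmax"):
            TemperatureSeries.constant(20.0, 5, half_range=-1.0)

    def test_csv_round_trip(self, tmp_path):
        s = TemperatureSeries.constant(22.0, 10, half_range=5.0)
        p = tmp_path / "w.csv"
        s.to_csv(p)
        s2 = TemperatureSeries.from_csv(p)
        np.testing.assert_array_equal(s.dates, s2.dates)
        np.testing.assert_allclose(s.tmin, s2.tmin)

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "w.csv"
        p.write_text("date,tmin\n2004-01-01,12\n")
        with pytest.raises(ValueError, match="tmax"):
            TemperatureSeries.from_csv(p)


class TestAccumulation:
    def test_constant_rate_inverts_exactly(self):
        # r(25) = 0.02 with the degree-day curve -> 50.0 days
        d = accumulate_development(constant_series(25.0), "linear_dd", DD_R002)
        assert d == pytest.approx(50.0, abs=1e-9)

    def test_three_day_interpolation(self):
        # rates 0.4/day: cumulative 0.4, 0.8, 1.2 -> crosses 1 at 2.5 days
        series = constant_series(25.0, 5)
        theta = np.array([5.0, 50.0])  # r = 20/50 = 0.4
        d = accumulate_development(series, "linear_dd", theta)
        assert d == pytest.approx(2.5, abs=1e-12)

    def test_no_development_below_base_temperature(self):
        with pytest.raises(PhaseNotCompletedError) as e:
            accumulate_development(constant_series(5.0, 30), "linear_dd", DD_R002)
        assert e.value.final_d == 0.0

    def test_trajectory_nondecreasing(self):
        rng = np.random.default_rng(42)
        mid = 20.0 + 8.0 * rng.standard_normal(300)
        series = TemperatureSeries(
            np.datetime64("2004-01-01") + np.arange(300), mid - 5.0, mid + 5.0)
        _, cum = accumulate_development(series, "briere1", [2e-5, 9.0, 40.0],
                                        return_trajectory=True)
        assert np.all(np.diff(cum) >= 0.0)

    def test_matches_brute_force_day_loop(self):
        rng = np.random.default_rng(7)
        theta = np.array([2e-5, 9.0, 40.0])
        for _ in range(20):
            mid = rng.uniform(18.0, 30.0) + 6.0 * np.sin(
                2 * np.pi * np.arange(400) / 365.0 + rng.uniform(0, 6.28))
            series = TemperatureSeries(
                np.datetime64("2004-01-01") + np.arange(400), mid - 5.0, mid + 5.0)
            rates = evaluate_rate("briere1", theta, series.driving_temperature())
            assert accumulate_development(series, "briere1", theta) == pytest.approx(
                brute_force_duration(rates), abs=1e-9)

    def test_permuting_equal_days_leaves_duration_unchanged(self):
        mid = np.array([20.0, 24.0, 24.0, 28.0] * 20)
        series = TemperatureSeries(
            np.datetime64("2004-01-01") + np.arange(mid.size), mid - 4, mid + 4)
        swapped = mid.copy()
        swapped[[1, 2]] = swapped[[2, 1]]  # equal-temperature days
        series2 = TemperatureSeries(series.dates, swapped - 4, swapped + 4)
        theta = np.array([2e-5, 9.0, 40.0])
        assert accumulate_development(series, "briere1", theta) == \
            accumulate_development(series2, "briere1", theta)

    def test_duration_monotone_below_optimum(self):
        # warmer (but sub-optimal) constant temperature -> shorter phase
        durations = [accumulate_development(constant_series(T), "briere1",
                                            [2e-5, 9.0, 40.0])
                     for T in np.linspace(15.0, 32.0, 10)]
        assert np.all(np.diff(durations) < 0)

    def test_sine_mode_differs_when_curve_is_nonlinear(self):
        series = TemperatureSeries.constant(25.0, 400, half_range=8.0)
        theta = np.array([2e-5, 9.0, 40.0])
        d_mean = accumulate_development(series, "briere1", theta)
        d_sine = accumulate_development(series, "briere1", theta,
                                        temperature_method="sine")
        assert d_mean != d_sine  # Jensen gap of the nonlinear rate curve


class TestCycle:
    def test_zero_offset_total_is_sum_of_phases(self):
        series = constant_series(25.0, 300)
        cyc = predict_cycle(series, "linear_dd", DD_R002, emergence_offset=0)
        assert cyc.total_days == pytest.approx(cyc.vp_days + cyc.rp_days)

    def test_offset_shifts_total_exactly(self):
        series = constant_series(25.0, 300)
        c7 = predict_cycle(series, "linear_dd", DD_R002, emergence_offset=7)
        c10 = predict_cycle(series, "linear_dd", DD_R002, emergence_offset=10)
        assert c10.total_days - c7.total_days == pytest.approx(3.0)

    def test_constant_temperature_phases_invert_rates(self):
        series = constant_series(25.0, 300)
        vp_theta = np.array([5.0, 1000.0])   # r = 0.02
        rp_theta = np.array([5.0, 800.0])    # r = 0.025
        cyc = predict_cycle(series, "linear_dd", vp_theta, rp_theta,
                            emergence_offset=0)
        assert cyc.vp_days == pytest.approx(50.0, abs=1e-9)
        assert cyc.rp_days == pytest.approx(40.0, abs=1e-9)
        assert cyc.total_days == pytest.approx(90.0, abs=1e-9)

    def test_reproductive_phase_starts_after_flowering(self):
        series = constant_series(25.0, 300)
        cyc = predict_cycle(series, "linear_dd", DD_R002, emergence_offset=7)
        vp = predict_phase_duration(series, "linear_dd", DD_R002, start_day=7)
        flowering_idx = 7 + int(np.ceil(vp))
        assert cyc.flowering == series.dates[flowering_idx]

    def test_offset_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="emergence_offset"):
            predict_cycle(constant_series(25.0), "linear_dd", DD_R002,
                          emergence_offset=31)


class TestConstantTemperatureDuration:
    def test_inverts_rate(self):
        assert duration_at_constant_temperature("linear_dd", DD_R002, 25.0) == \
            pytest.approx(50.0)

    def test_outside_limits_signalled(self):
        with pytest.raises(OutsideThermalLimits):
            duration_at_constant_temperature("briere1", [2e-5, 9.0, 40.0], 9.0)

    @given(T=st.floats(min_value=15.0, max_value=35.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_agrees_with_accumulation_on_constant_series(self, T):
        theta = [2e-5, 9.0, 40.0]
        d = duration_at_constant_temperature("briere1", theta, T)
        acc = accumulate_development(constant_series(T, int(d) + 3), "briere1", theta)
        assert acc == pytest.approx(d, abs=1e-9)
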