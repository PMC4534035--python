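"""Climate data model, solar estimation, cycling, downscaling, generator."""

import math

import numpy as np
import pandas as pd
import pytest

from standclim.climate import (
    ClimateSeries, DailyClimateRecord, ScenarioDeltas, SyntheticClimateParams,
    cycle_reference, downscale_direct, estimate_solar, extraterrestrial_radiation,
    generate_synthetic_climate, growing_season_mean_temperature, month_of_doy,
    snow_fraction_from_temperature,
)


class TestSolarEstimation:
    def test_zero_diurnal_range_gives_minimum_transmissivity(self):
        assert estimate_solar(15.0, 15.0, 50.0, 1000.0, 172) == 0.0

    def test_winter_insolation_below_summer(self):
        winter = estimate_solar(0.0, -12.0, 50.0, 1000.0, 355)
        summer = estimate_solar(20.0, 8.0, 50.0, 1000.0, 172)
        assert winter < summer

    def test_bounded_by_extraterrestrial_and_monotone_in_range(self):
        ra = extraterrestrial_radiation(50.0, 172)
        prev = 0.0
        for dt in (2.0, 6.0, 10.0, 14.0):
            rs = estimate_solar(10.0 + dt, 10.0, 50.0, 1000.0, 172)
            assert 0.0 <= rs <= ra
            assert rs > prev
            prev = rs

    def test_matches_independent_bristow_campbell_evaluation(self):
        # hand re-derivation for latitude 50 N, day 172, 12 degC range:
        # solar geometry first, then tau = 0.7 * (1 - exp(-0.005 * 12**2.4))
        phi = math.radians(50.0)
        dr = 1 + 0.033 * math.cos(2 * math.pi * 172 / 365)
        delta = 0.409 * math.sin(2 * math.pi * 172 / 365 - 1.39)
        ws = math.acos(-math.tan(phi) * math.tan(delta))
        ra = (24 * 60 / math.pi) * 0.0820 * dr * (
            ws * math.sin(phi) * math.sin(delta)
            + math.cos(phi) * math.cos(delta) * math.sin(ws))
        expected = 0.7 * (1 - math.exp(-0.005 * 12**2.4)) * ra
        got = estimate_solar(24.0, 12.0, 50.0, 1000.0, 172)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            estimate_solar(float("nan"), 5.0, 50.0, 1000.0, 100)
        with pytest.raises(ValueError):
            estimate_solar(10.0, 2.0, 95.0, 1000.0, 100)
        with pytest.raises(ValueError):
            estimate_solar(10.0, 2.0, 50.0, 1000.0, 0)


class TestCalendar:
    def test_month_boundaries(self):
        assert month_of_doy(1) == 1
        assert month_of_doy(31) == 1
        assert month_of_doy(32) == 2
        assert month_of_doy(121) == 5      # May 1
        assert month_of_doy(273) == 9      # Sep 30
        assert month_of_doy(365) == 12

    def test_snow_fraction_ramp(self):
        assert snow_fraction_from_temperature(-3.0) == 1.0
        assert snow_fraction_from_temperature(1.0) == 0.5
        assert snow_fraction_from_temperature(5.0) == 0.0

    def test_record_invariants(self):
        with pytest.raises(ValueError):
            DailyClimateRecord(2000, 1, 5.0, 4.0, 1.0, 0.0, 0.0, 10.0, 380.0)
        with pytest.raises(ValueError):
            DailyClimateRecord(2000, 1, 5.0, 8.0, 1.0, -1.0, 0.0, 10.0, 380.0)


class TestCycling:
    def test_cycle_lengths_and_periodicity(self, ref5):
        out = cycle_reference(ref5, 3)
        assert out.n_years == 15
        # each cycle reproduces the input day for day
        base = ref5.data.drop(columns="year")
        for k in range(3):
            block = out.data.iloc[k * 5 * 365 : (k + 1) * 5 * 365]
            pd.testing.assert_frame_equal(
                block.drop(columns="year").reset_index(drop=True), base)
        assert np.array_equal(np.diff(out.data["year"].to_numpy()[::365]),
                              np.ones(14, dtype=int))

    def test_cycle_identity(self, ref5):
        out = cycle_reference(ref5, 1)
        pd.testing.assert_frame_equal(out.data, ref5.data)

    def test_two_year_series_cycled_three_times(self):
        two = generate_synthetic_climate(SyntheticClimateParams(), 2, seed=5)
        out = cycle_reference(two, 3)
        year5 = out.data.iloc[4 * 365 : 5 * 365].drop(columns="year")
        year1 = out.data.iloc[0:365].drop(columns="year")
        pd.testing.assert_frame_equal(year5.reset_index(drop=True),
                                      year1.reset_index(drop=True))

    def test_rejects_zero_cycles(self, ref5):
        with pytest.raises(ValueError):
            cycle_reference(ref5, 0)


def _null_deltas(anchor_year=2000):
    return ScenarioDeltas(anchors={anchor_year: (np.zeros(12), np.ones(12))})


class TestDownscaling:
    def test_null_scenario_is_cycled_reference(self, ref5):
        out = downscale_direct(ref5, _null_deltas(), 10)
        cycled = cycle_reference(ref5, 2)
        for col in ("tmean", "tmax", "tmin", "precip"):
            np.testing.assert_allclose(out.data[col], cycled.data[col])

    def test_monthly_offset_additivity(self, ref5):
        anchors = {2000: (np.zeros(12), np.ones(12))}
        anchors[2000][0][6] = 3.0  # +3 degC in July at the single anchor
        out = downscale_direct(ref5, ScenarioDeltas(anchors=anchors), 5)
        july = month_of_doy(ref5.data["doy"].to_numpy()) == 7
        np.testing.assert_allclose(
            out.data.loc[july, "tmean"], ref5.data.loc[july, "tmean"] + 3.0)
        not_july = ~july
        np.testing.assert_allclose(
            out.data.loc[not_july, "tmean"], ref5.data.loc[not_july, "tmean"])

    def test_increasing_anchors_give_nondecreasing_decadal_warming(self, ref5):
        start = ref5.start_year
        anchors = {start: (np.zeros(12), np.ones(12)),
                   start + 20: (np.full(12, 2.0), np.ones(12)),
                   start + 40: (np.full(12, 4.0), np.ones(12))}
        out = downscale_direct(ref5, ScenarioDeltas(anchors=anchors), 40,
                               start_year=start)
        gs = [growing_season_mean_temperature(
                ClimateSeries(out.data.iloc[i * 365:(i + 1) * 365].reset_index(drop=True)))
              for i in range(40)]
        decades = np.convolve(gs, np.ones(10) / 10, mode="valid")
        assert np.all(np.diff(decades) >= -1e-9)

    def test_scenario_co2_trajectory_applied(self, ref5):
        deltas = ScenarioDeltas(anchors={2000: (np.zeros(12), np.ones(12))},
                                co2={2000: 400.0, 2004: 440.0})
        out = downscale_direct(ref5, deltas, 5, start_year=2000)
        co2 = out.data["co2"].to_numpy()[::365]
        np.testing.assert_allclose(co2, [400, 410, 420, 430, 440])

    def test_rejects_invalid_ratios_and_horizon(self, ref5):
        with pytest.raises(ValueError):
            ScenarioDeltas(anchors={2000: (np.zeros(12), np.zeros(12))})
        with pytest.raises(ValueError):
            downscale_direct(ref5, _null_deltas(), 0)


class TestSyntheticGenerator:
    def test_deterministic_given_seed(self):
        p = SyntheticClimateParams()
        a = generate_synthetic_climate(p, 3, seed=99)
        b = generate_synthetic_climate(p, 3, seed=99)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_growing_season_mean_near_target(self):
        series = generate_synthetic_climate(SyntheticClimateParams(), 30, seed=4)
        assert abs(growing_season_mean_temperature(series) - 12.5) < 0.5

    def test_long_run_convergence_of_seasonal_mean(self):
        # empirical growing-season mean converges on the configured
        # deterministic cycle; 100 y leaves ~3 standard errors ~ 0.2 degC
        series = generate_synthetic_climate(SyntheticClimateParams(), 100, seed=8)
        assert abs(growing_season_mean_temperature(series) - 12.5) < 0.25

    def test_zero_noise_gives_smooth_repeating_cycle(self):
        p = SyntheticClimateParams(t_noise_sd=0.0, wet_prob_winter=0.0,
                                   wet_prob_summer=0.0)
        series = generate_synthetic_climate(p, 2, seed=1)
        y1 = series.data.iloc[:365]["tmean"].to_numpy()
        y2 = series.data.iloc[365:]["tmean"].to_numpy()
        np.testing.assert_array_equal(y1, y2)
        assert np.all(np.abs(np.diff(y1)) < 0.25)  # smooth seasonal cycle
        assert series.data["precip"].sum() == 0.0

    def test_summer_dry_seasonality(self):
        series = generate_synthetic_climate(SyntheticClimateParams(), 30, seed=12)
        month = month_of_doy(series.data["doy"].to_numpy())
        monthly = series.data.groupby(month)["precip"].mean()
        assert monthly[[12, 1]].mean() > monthly[[7, 8]].mean()


class TestCsvRoundTrip:
    def test_round_trip(self, tmp_path, ref5):
        path = tmp_path / "climate.csv"
        ref5.to_csv(path)
        back = ClimateSeries.from_csv(path)
        pd.testing.assert_frame_equal(back.data, ref5.data, check_dtype=False)

    def test_feb29_dropped_and_snow_frac_derived(self, tmp_path):
        dates = pd.date_range("2000-01-01", "2000-12-31", freq="D")  # leap year
        df = pd.DataFrame({
            "date": dates.strftime("%Y-%m-%d"),
            "tmean": 5.0, "tmax": 10.0, "tmin": 0.0,
            "precip": 1.0, "solar": 8.0,
        })
        path = tmp_path / "leap.csv"
        df.to_csv(path, index=False)
        series = ClimateSeries.from_csv(path, co2=380.0)
        assert series.n_years == 1
        assert len(series.data) == 365
        assert np.allclose(series.data["snow_frac"], 0.0)  # tmean 5 degC -> rain
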