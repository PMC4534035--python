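"""Daily water balance: PET, radiation partition, uptake, TDI, step order."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from standclim.defaults import default_soil_profile
from standclim.hydrology import (
    SOIL_ALBEDO, SoilLayerSpec, SpeciesCanopySpec, WaterState,
    actual_transpiration, compute_tdi, partition_radiation, priestley_taylor_pet,
    root_occupancy, step_day, transpiration_demand,
)


def make_veg(lai=2.5, r_can=0.3, albedo=0.0, name="fir", stratum="tree"):
    return SpeciesCanopySpec(name=name, albedo=albedo, r_can=r_can,
                             max_root_depth=100.0, lai=lai, stratum=stratum)


class TestPriestleyTaylor:
    def test_no_energy_no_pet(self):
        assert priestley_taylor_pet(0.0, 15.0) == 0.0

    def test_hand_derived_reference_value(self):
        # alpha * Delta/(Delta+gamma) * Rn/lambda at 20 degC, 10 MJ:
        # Delta ~ 0.145, gamma 0.066, lambda 2.45 -> ~3.53 mm
        assert priestley_taylor_pet(10.0, 20.0, alpha=1.26) == pytest.approx(3.532, abs=0.01)

    def test_monotone_in_temperature_and_radiation(self):
        assert priestley_taylor_pet(10.0, 25.0) > priestley_taylor_pet(10.0, 5.0)
        assert priestley_taylor_pet(12.0, 15.0) > priestley_taylor_pet(8.0, 15.0)

    def test_rejects_extreme_temperature(self):
        with pytest.raises(ValueError):
            priestley_taylor_pet(5.0, -60.0)


class TestRadiationPartition:
    def test_empty_canopy_sends_all_to_soil(self):
        absorbed, soil = partition_radiation(20.0, [make_veg(lai=0.0)])
        assert absorbed["fir"] == 0.0
        assert soil == pytest.approx(20.0 * (1 - SOIL_ALBEDO))

    def test_dense_canopy_transmits_nothing(self):
        absorbed, soil = partition_radiation(20.0, [make_veg(lai=50.0)])
        assert soil < 1e-4
        assert absorbed["fir"] == pytest.approx(20.0, rel=1e-4)

    def test_equal_lai_equal_share(self):
        veg = [make_veg(name="a", lai=2.0), make_veg(name="b", lai=2.0)]
        absorbed, _ = partition_radiation(20.0, veg)
        assert absorbed["a"] == pytest.approx(absorbed["b"])

    def test_energy_conservation_with_black_canopies(self):
        # with zero albedo everywhere except the soil, absorbed + soil
        # net + soil reflection accounts for the whole incoming flux
        veg = [make_veg(name="a", lai=1.5), make_veg(name="u", lai=0.8,
                                                     stratum="understory")]
        incoming = 18.0
        absorbed, soil_net = partition_radiation(incoming, veg)
        transmitted = soil_net / (1 - SOIL_ALBEDO)
        assert sum(absorbed.values()) + transmitted == pytest.approx(incoming, rel=1e-12)

    def test_understory_shaded_by_trees(self):
        shaded = partition_radiation(20.0, [make_veg(name="t", lai=3.0),
                                            make_veg(name="u", lai=1.0,
                                                     stratum="understory")])[0]["u"]
        open_ = partition_radiation(20.0, [make_veg(name="u", lai=1.0,
                                                    stratum="understory")])[0]["u"]
        assert shaded < open_


class TestDemandAndUptake:
    def test_zero_resistance_is_energy_limited(self):
        assert transpiration_demand(10.0, 20.0, 0.0) == priestley_taylor_pet(10.0, 20.0)

    def test_resistance_lowers_demand(self):
        lo = transpiration_demand(10.0, 20.0, 0.3)
        hi = transpiration_demand(10.0, 20.0, 0.6)
        assert hi < lo

    def test_co2_adjusted_resistance_ratio(self):
        base = transpiration_demand(10.0, 20.0, 0.3)
        adj = transpiration_demand(10.0, 20.0, 0.4247)
        assert adj / base == pytest.approx((1 + 0.3) / (1 + 0.4247), rel=1e-12)

    def test_abundant_water_meets_demand(self):
        actual, ext = actual_transpiration(4.0, np.array([50.0, 80.0]),
                                           np.array([1.0, 1.0]))
        assert actual == 4.0
        assert ext.sum() == pytest.approx(4.0)

    def test_wilting_point_stops_uptake(self):
        actual, ext = actual_transpiration(4.0, np.array([0.0, 0.0]),
                                           np.array([1.0, 1.0]))
        assert actual == 0.0 and ext.sum() == 0.0

    def test_supply_capped(self):
        actual, ext = actual_transpiration(4.0, np.array([2.0, 1.0]),
                                           np.array([1.0, 1.0]))
        assert actual == 3.0
        assert np.all(ext <= np.array([2.0, 1.0]) + 1e-12)

    def test_root_occupancy_partial_layers(self):
        profile = default_soil_profile()
        veg = make_veg()  # roots to 100 cm: humus 12.5 + A 40 + B 45 = 97.5
        occ = root_occupancy(veg, profile)
        np.testing.assert_allclose(occ, [1.0, 1.0, 1.0, 2.5 / 50.0])


class TestTdi:
    @pytest.mark.parametrize("demand,actual,expected", [
        (4.0, 3.0, 0.25),
        (4.0, 4.0, 0.0),
        (4.0, 0.0, 1.0),
        (0.0, 0.0, 0.0),   # winter convention
    ])
    def test_examples(self, demand, actual, expected):
        assert compute_tdi(demand, actual) == expected

    @given(st.floats(0.001, 10.0), st.floats(0.0, 1.0))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_bounds(self, demand, frac):
        assert 0.0 <= compute_tdi(demand, demand * frac) <= 1.0


class TestStepDay:
    def setup_method(self):
        self.profile = default_soil_profile()
        self.veg = [SpeciesCanopySpec("douglas_fir", 0.12, 0.3, 100.0, 2.5)]

    def test_null_forcing_leaves_state_unchanged(self):
        state = WaterState(0.0, 0.0, np.array(
            [0.6 * l.capacity_mm for l in self.profile]))
        new, flux = step_day(state, 10.0, 0.0, 0.0, 0.0, self.veg, self.profile)
        np.testing.assert_array_equal(new.layer_water, state.layer_water)
        assert flux.drainage == 0.0 and flux.soil_evaporation == 0.0
        assert flux.demand["douglas_fir"] == 0.0
        assert flux.tdi["douglas_fir"] == 0.0

    def test_saturated_profile_sheds_rain_as_drainage(self):
        state = WaterState.at_field_capacity(self.profile)
        new, flux = step_day(state, 8.0, 50.0, 0.0, 0.0, self.veg, self.profile)
        assert flux.drainage == pytest.approx(50.0 - flux.interception_loss, abs=1e-9)

    def test_snow_accumulates_below_freezing_and_melts_by_degree_days(self):
        state = WaterState.at_field_capacity(self.profile)
        new, _ = step_day(state, -10.0, 20.0, 1.0, 0.0, self.veg, self.profile)
        assert new.snow == 20.0
        new2, flux = step_day(new, 2.0, 0.0, 0.0, 0.0, self.veg, self.profile)
        assert flux.snowmelt == pytest.approx(6.0)  # 3 mm/degC/day * 2 degC
        assert new2.snow == pytest.approx(14.0)

    def test_dry_down_gives_nondecreasing_tdi(self):
        state = WaterState.at_field_capacity(self.profile)
        tdis = []
        for _ in range(60):
            state, flux = step_day(state, 22.0, 0.0, 0.0, 25.0, self.veg, self.profile)
            tdis.append(flux.tdi["douglas_fir"])
        assert all(b >= a - 1e-12 for a, b in zip(tdis, tdis[1:]))
        assert tdis[-1] > tdis[0]

    def test_water_balance_closes_under_random_forcing(self):
        rng = np.random.default_rng(17)
        state = WaterState(5.0, 0.0, np.array(
            [0.7 * l.capacity_mm for l in self.profile]))
        for _ in range(365):
            t = rng.uniform(-15.0, 30.0)
            p = rng.exponential(3.0) * (rng.random() < 0.4)
            sf = 1.0 if t < 0 else 0.0
            sol = rng.uniform(0.0, 30.0)
            state, flux = step_day(state, t, p, sf, sol, self.veg, self.profile)
            assert abs(flux.balance_residual) < 1e-6

    def test_layer_water_stays_within_bounds(self):
        rng = np.random.default_rng(3)
        state = WaterState.at_field_capacity(self.profile)
        caps = np.array([l.capacity_mm for l in self.profile])
        wilts = np.array([l.wilting_mm("douglas_fir") for l in self.profile])
        for _ in range(365):
            t = rng.uniform(-5.0, 30.0)
            p = rng.exponential(2.0) * (rng.random() < 0.3)
            state, _ = step_day(state, t, p, 0.0, rng.uniform(0, 28), self.veg,
                                self.profile)
            assert np.all(state.layer_water <= caps + 1e-9)
            # uptake never draws below the species wilting point (soil
            # evaporation can dry the humus layer further, so skip layer 0)
            assert np.all(state.layer_water[1:] >= wilts[1:] - 1e-9)

    def test_doubling_lai_never_lowers_total_demand(self):
        state = WaterState.at_field_capacity(self.profile)
        _, f1 = step_day(state, 18.0, 0.0, 0.0, 22.0,
                         [SpeciesCanopySpec("d", 0.12, 0.3, 100.0, 1.5)], self.profile)
        _, f2 = step_day(state, 18.0, 0.0, 0.0, 22.0,
                         [SpeciesCanopySpec("d", 0.12, 0.3, 100.0, 3.0)], self.profile)
        assert f2.demand["d"] >= f1.demand["d"]

    def test_rejects_nan_forcing(self):
        state = WaterState.at_field_capacity(self.profile)
        with pytest.raises(ValueError):
            step_day(state, float("nan"), 0.0, 0.0, 0.0, self.veg, self.profile)


class TestSoilLayerSpec:
    def test_capacity_accounts_for_coarse_fragments(self):
        layer = SoilLayerSpec("a", "silt loam", 25.0, 40.0, 0.25,
                              wilting_point={"x": 0.12})
        assert layer.capacity_mm == pytest.approx(0.25 * 40 * 0.75 * 10)
        assert layer.wilting_mm("x") == pytest.approx(0.12 * 40 * 0.75 * 10)

    def test_validation(self):
        with pytest.raises(ValueError):
            SoilLayerSpec("a", "s", 100.0, 40.0, 0.25)
        with pytest.raises(ValueError):
            SoilLayerSpec("a", "s", 10.0, 40.0, 0.25, wilting_point={"x": 0.3})
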