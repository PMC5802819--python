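"""Emission factors against the published table values, sulphur mass balance,
policy application and gridding against a brute-force per-record oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import box

from shipair import (FuelPolicy, SulphurRegion, WorldGrid, applicable_sulphur,
                     co2_ef, generate_fleet, generate_traffic, generate_world,
                     grid_emissions, nox_ef, pm_ef, project_growth,
                     propulsion_load, sfoc_at_load, sox_split, specs_from_frame)
from shipair.emissions import SPECIES, InputError, record_emissions


class TestPropulsionLoad:
    @pytest.mark.parametrize("speed, design, expected", [
        (10.0, 10.0, 1.0),            # cubic law at ratio 1
        (0.0, 10.0, 0.02),            # hotelling floor
        (6.3, 10.0, 0.63**3),         # plain cube, 0.2500 to 4 s.f.
        (20.0, 10.0, 1.0),            # capped above design speed
    ])
    def test_cubic_law_with_clamps(self, speed, design, expected):
        assert propulsion_load(speed, design) == pytest.approx(expected, rel=1e-12)

    def test_negative_speed_rejected(self):
        with pytest.raises(InputError):
            propulsion_load(-1.0, 10.0)


class TestSfoc:
    @pytest.mark.parametrize("base, load, expected_int", [
        (165.0, 0.8, 165),   # normalisation point
        (165.0, 0.25, 186),  # printed HFO low-load value
        (250.0, 0.25, 282),  # printed distillate low-load value
    ])
    def test_quadratic_curve_reproduces_table(self, base, load, expected_int):
        assert round(float(sfoc_at_load(base, load))) == expected_int

    def test_load_outside_unit_interval_rejected(self):
        with pytest.raises(InputError):
            sfoc_at_load(165.0, 0.0)
        with pytest.raises(InputError):
            sfoc_at_load(165.0, 1.2)


class TestNox:
    @pytest.mark.parametrize("tier, cls, rpm, expected", [
        (1, "MSD", 514, 12.9), (2, "MSD", 514, 10.5), (3, "MSD", 514, 2.6),
        (1, "SSD", 100, 17.0), (2, "SSD", 100, 14.4), (3, "SSD", 100, 3.4),
        (1, "HSD", 2500, 9.8), (2, "HSD", 2500, 7.7), (3, "HSD", 2500, 2.0),
        (0, "SSD", 100, 18.7),  # Tier 0 = 110% of Tier I
    ])
    def test_marpol_tier_curves(self, tier, cls, rpm, expected):
        assert nox_ef(tier, cls, rpm) == pytest.approx(expected, abs=0.05)

    def test_unknown_tier_rejected(self):
        with pytest.raises(InputError):
            nox_ef(5, "SSD", 100)


class TestSox:
    @pytest.mark.parametrize("s, sfoc, fuel, so2_expected", [
        (0.005, 250.0, "MDO_MGO", 2.40),
        (0.001, 250.0, "MDO_MGO", 0.48),
        (0.027, 165.0, "HFO", 8.35),
    ])
    def test_printed_so2_factors(self, s, sfoc, fuel, so2_expected):
        ef_so2, _ = sox_split(s, sfoc, fuel)
        assert ef_so2 == pytest.approx(so2_expected, abs=0.005)

    @given(s=st.floats(0.0, 0.035), sfoc=st.floats(100.0, 350.0),
           fuel=st.sampled_from(["HFO", "MDO_MGO"]))
    @settings(max_examples=200, deadline=None)
    def test_sulphur_mass_balance_is_exact(self, s, sfoc, fuel):
        """Fuel sulphur = S(SO2)/2 + S(primary sulphate), exactly."""
        ef_so2, ef_so4s = sox_split(s, sfoc, fuel)
        assert ef_so2 / 2.0 + ef_so4s == pytest.approx(s * sfoc, rel=1e-12, abs=1e-15)

    def test_out_of_range_sulphur_rejected(self):
        with pytest.raises(InputError):
            sox_split(-0.001, 250.0, "HFO")
        with pytest.raises(InputError):
            sox_split(0.05, 250.0, "HFO")


class TestPm:
    @pytest.mark.parametrize("s, load, expected", [
        (0.005, 0.8, 0.50), (0.027, 0.25, 1.35), (0.001, 0.8, 0.38),
        (0.016, 0.8, 0.845),  # midpoint between the 0.5% and 2.7% anchors
    ])
    def test_piecewise_interpolation(self, s, load, expected):
        assert float(pm_ef(s, load)) == pytest.approx(expected, abs=1e-9)

    def test_extrapolation_is_clamped(self):
        assert float(pm_ef(0.03, 0.8)) == pytest.approx(1.19)
        assert float(pm_ef(0.0005, 0.25)) == pytest.approx(0.43)


class TestCo2:
    def test_table_anchor_values(self):
        assert float(co2_ef("HFO", 165.0)) == pytest.approx(515.0)
        # the printed 905 reflects the table's own rounding of the same ratio
        assert float(co2_ef("MDO_MGO", 282.0)) == pytest.approx(905.8, abs=0.1)

    def test_proportional_in_sfoc(self):
        assert float(co2_ef("HFO", 0.0)) == 0.0


class TestPolicy:
    @pytest.fixture
    def seca(self):
        return SulphurRegion("SECA", box(0, 0, 10, 10), 0.001,
                             pd.Timestamp("2015-01-01"))

    def test_open_ocean_gets_global_cap(self, seca):
        pol = FuelPolicy.bau((seca,))
        assert applicable_sulphur(50, 50, "2020-06-01", pol) == 0.027

    def test_seca_overrides_when_stricter(self, seca):
        assert applicable_sulphur(5, 5, "2020-06-01", FuelPolicy.bau((seca,))) == 0.001
        assert applicable_sulphur(5, 5, "2020-06-01",
                                  FuelPolicy.action_2020((seca,))) == 0.001

    def test_region_ignored_before_effective_date(self):
        late = SulphurRegion("DECA", box(0, 0, 10, 10), 0.005,
                             pd.Timestamp("2019-01-01"))
        pol = FuelPolicy.bau((late,))
        assert applicable_sulphur(5, 5, "2018-06-01", pol) == 0.027
        assert applicable_sulphur(5, 5, "2019-06-01", pol) == 0.005


class TestGrowth:
    @pytest.mark.parametrize("ship_type, years, factor", [
        ("dry_bulk", 5, 1.0174**5),     # 1.0901 to 4 d.p.
        ("miscellaneous", 7, 1.0),
        ("unitised", 0, 1.0),
    ])
    def test_compound_growth(self, ship_type, years, factor):
        assert project_growth(1.0, ship_type, years) == pytest.approx(factor)

    def test_unknown_type_rejected(self):
        with pytest.raises(InputError):
            project_growth(1.0, "submarine", 5)


class TestGridding:
    def test_empty_records_give_zero_grid(self, grid20, fleet30):
        empty = pd.DataFrame(columns=["vessel_id", "timestamp", "lon", "lat", "speed"])
        emis = grid_emissions(empty, specs_from_frame(fleet30),
                              FuelPolicy.bau(), grid20)
        assert all(emis.total_g(s) == 0 for s in SPECIES)

    def test_single_record_hand_arithmetic(self, grid20):
        """10 MW at 80% load for 1 h with EF 2.40 g/kWh -> 19.2 kg SO2."""
        fleet = pd.DataFrame([{
            "vessel_id": 0, "ship_type": "unitised", "installed_power": 10_000.0,
            "design_speed": 10.0, "engine_class": "MSD", "crankshaft_rpm": 514.0,
            "nox_tier": 2, "base_sfoc": 250.0, "fuel_family": "MDO_MGO"}])
        rec = pd.DataFrame([{"vessel_id": 0, "timestamp": pd.Timestamp("2020-01-01"),
                             "lon": 1.0, "lat": 41.0, "speed": 10.0 * 0.8**(1/3)}])
        pol = FuelPolicy.action_2020()  # 0.5% S -> EF depends on SFOC at load
        emis = grid_emissions(rec, specs_from_frame(fleet), pol, grid20)
        load = 0.8
        sfoc = float(sfoc_at_load(250.0, load))
        ef_so2 = 2 * 0.005 * sfoc * 0.96
        assert emis.total_g("so2") == pytest.approx(10_000 * load * ef_so2, rel=1e-9)

    def test_grid_totals_match_per_record_loop(self, grid20, world20, fleet30):
        """Gridded per-species totals equal a naive per-record summation."""
        cmap, _ = world20
        rec = generate_traffic(8, grid20, cmap, fleet30, period_hours=12)
        specs = specs_from_frame(fleet30)
        pol = FuelPolicy.bau()
        emis = grid_emissions(rec, specs, pol, grid20, growth_years=5.0)
        oracle = {s: 0.0 for s in SPECIES}
        for r in rec.itertuples(index=False):
            for sp, g in record_emissions(r, specs[int(r.vessel_id)], pol,
                                          growth_years=5.0).items():
                oracle[sp] += g
        for sp in SPECIES:
            assert emis.total_g(sp) == pytest.approx(oracle[sp], rel=1e-12)

    def test_out_of_grid_records_are_excluded_and_counted(self, grid20, fleet30):
        rec = pd.DataFrame([
            {"vessel_id": 0, "timestamp": pd.Timestamp("2020-01-01"),
             "lon": 150.0, "lat": 5.0, "speed": 5.0},
            {"vessel_id": 0, "timestamp": pd.Timestamp("2020-01-01"),
             "lon": 1.0, "lat": 41.0, "speed": 5.0}])
        emis = grid_emissions(rec, specs_from_frame(fleet30), FuelPolicy.bau(), grid20)
        assert emis.n_excluded == 1
        assert emis.total_g("co2") > 0

    def test_action_so2_below_bau_cellwise(self, grid20, world20, fleet30):
        cmap, _ = world20
        rec = generate_traffic(8, grid20, cmap, fleet30, period_hours=12)
        specs = specs_from_frame(fleet30)
        bau = grid_emissions(rec, specs, FuelPolicy.bau(), grid20)
        act = grid_emissions(rec, specs, FuelPolicy.action_2020(), grid20)
        assert np.all(act.species["so2"] <= bau.species["so2"] + 1e-9)


class TestFleetSulphurReduction:
    def test_open_ocean_reduction_is_closed_form(self, grid20, world20, fleet30):
        """A fleet entirely outside control areas switching 2.7% -> 0.5% S cuts
        SO2 by (2.7-0.5)/2.7 = 81.5%; a SECA traffic share pulls the global
        reduction strictly below that."""
        cmap, _ = world20
        fleet = fleet30.assign(fuel_family="HFO")
        rec = generate_traffic(8, grid20, cmap, fleet, period_hours=12)
        specs = specs_from_frame(fleet)
        bau = grid_emissions(rec, specs, FuelPolicy.bau(), grid20)
        act = grid_emissions(rec, specs, FuelPolicy.action_2020(), grid20)
        red = 100 * (1 - act.total_g("so2") / bau.total_g("so2"))
        assert red == pytest.approx(100 * (2.7 - 0.5) / 2.7, abs=0.1)

        seca = (SulphurRegion("SECA", box(*_west_box(grid20)), 0.001),)
        bau_s = grid_emissions(rec, specs, FuelPolicy.bau(seca), grid20)
        act_s = grid_emissions(rec, specs, FuelPolicy.action_2020(seca), grid20)
        if bau_s.total_g("so2") < bau.total_g("so2"):  # some traffic in the SECA
            red_s = 100 * (1 - act_s.total_g("so2") / bau_s.total_g("so2"))
            assert red_s < red


def _west_box(grid):
    return (grid.lon_min, grid.lat_min,
            grid.lon_min + 0.5 * (grid.lon_max - grid.lon_min), grid.lat_max)


def test_vessel_spec_rpm_class_consistency_enforced():
    from shipair import VesselSpec
    with pytest.raises(InputError):
        VesselSpec(0, "dry_bulk", 10_000, 8.0, "SSD", 500.0, 1, 165.0, "HFO")
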