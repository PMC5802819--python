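"""Exposure surrogate: box-model closed forms, linearity, mass-conserving
kernel, burden diagnostics and the bounded nitrate offset."""

import numpy as np
import pytest

from shipair import (ConcentrationField, FuelPolicy, SpeciesLifetimes, WorldGrid,
                     assemble_pm25, burden_diagnostic, nitrate_compensation,
                     steady_state_concentration)
from shipair.emissions import SPECIES, EmissionGrid
from shipair.exposure import InputError, _exponential_kernel


def _emis(grid, species_masses, period_hours=1.0, scenario="X"):
    fields = {s: np.zeros(grid.shape) for s in SPECIES}
    for sp, (r, c, g) in species_masses.items():
        fields[sp][r, c] = g
    return EmissionGrid(grid=grid, species=fields, scenario=scenario,
                        period_hours=period_hours)


@pytest.fixture
def flatgrid():
    # equatorial cells ~0.09 deg so that cell area ~1e8 m2 for hand arithmetic
    return WorldGrid(lon_min=0.0, lat_min=-0.45, cell_size=0.0899322,
                     n_lon=10, n_lat=10)


class TestBoxModel:
    def test_zero_emissions_give_zero_ship_concentration(self, flatgrid, flat_meteo):
        emis = _emis(flatgrid, {})
        conc = steady_state_concentration(emis, SpeciesLifetimes(), flat_meteo(flatgrid.shape))
        assert np.all(conc.ship_pm25 == 0)

    def test_single_cell_emitter_matches_closed_form(self, flatgrid, flat_meteo):
        """No wind (l -> 0): C = Q*tau/(A*h) in the source cell only.
        Q = 1 g/s sulphate, A ~ 1e8 m2, h = 1000 m, tau = 2.8 d -> 2.42 ug/m3
        of sulphur equivalent, x3 as sulphate aerosol mass."""
        met = flat_meteo(flatgrid.shape, wind=0.0, mix=1000.0)
        emis = _emis(flatgrid, {"so4": (5, 5, 3600.0)}, period_hours=1.0)
        conc = steady_state_concentration(emis, SpeciesLifetimes(), met,
                                          so2_to_so4_fraction=0.5)
        area = flatgrid.cell_areas()[5, 5]
        expected_s = 1e6 * 2.8 * 86400 / (area * 1000.0)
        assert expected_s == pytest.approx(2.42, rel=0.01)  # hand arithmetic anchor
        assert conc.c_so4[5, 5] == pytest.approx(3.0 * expected_s, rel=1e-9)
        off_source = conc.c_so4.copy()
        off_source[5, 5] = 0.0
        assert np.all(off_source == 0)

    def test_concentration_linear_in_emissions(self, flatgrid, flat_meteo):
        met = flat_meteo(flatgrid.shape, wind=5.0)
        e1 = _emis(flatgrid, {"so4": (5, 5, 100.0), "so2": (2, 2, 50.0)})
        e2 = _emis(flatgrid, {"so4": (5, 5, 200.0), "so2": (2, 2, 100.0)})
        c1 = steady_state_concentration(e1, SpeciesLifetimes(), met)
        c2 = steady_state_concentration(e2, SpeciesLifetimes(), met)
        np.testing.assert_allclose(c2.ship_pm25, 2.0 * c1.ship_pm25, rtol=1e-12)

    def test_doubling_sulphate_lifetime_doubles_the_field(self, flatgrid, flat_meteo):
        met = flat_meteo(flatgrid.shape, wind=0.0)
        emis = _emis(flatgrid, {"so4": (5, 5, 100.0)})
        c1 = steady_state_concentration(emis, SpeciesLifetimes(tau_so4=2.8), met)
        c2 = steady_state_concentration(emis, SpeciesLifetimes(tau_so4=5.6), met)
        np.testing.assert_allclose(c2.c_so4, 2.0 * c1.c_so4, rtol=1e-12)

    def test_kernel_conserves_column_mass(self, flatgrid):
        k = _exponential_kernel(flatgrid, efold_m=300_000.0)
        np.testing.assert_allclose(k.sum(axis=1), 1.0, rtol=1e-9)
        mass = np.zeros(flatgrid.n_cells)
        mass[17] = 42.0
        assert (mass @ k).sum() == pytest.approx(42.0, rel=1e-6)

    def test_spread_burden_equals_rate_times_lifetime(self, flatgrid, flat_meteo):
        """Steady-state identity on the closed domain: total column burden of
        sulphate equals the sulphate-mass feed rate times its lifetime."""
        met = flat_meteo(flatgrid.shape, wind=4.0, mix=800.0)
        emis = _emis(flatgrid, {"so4": (3, 7, 7200.0)}, period_hours=2.0)
        lt = SpeciesLifetimes()
        conc = steady_state_concentration(emis, lt, met, so2_to_so4_fraction=0.5)
        burden = (conc.c_so4 * flatgrid.cell_areas() * met.mixing_height).sum()
        q_so4_aerosol = 3.0 * 7200.0 / (2 * 3600.0) * 1e6  # ug/s as sulphate
        assert burden == pytest.approx(q_so4_aerosol * lt.tau_so4 * 86400, rel=1e-6)

    def test_zero_mixing_height_rejected(self, flatgrid, flat_meteo):
        from shipair import ConfigurationError
        met = flat_meteo(flatgrid.shape)
        met.mixing_height[:] = 0.0
        with pytest.raises(ConfigurationError):
            steady_state_concentration(_emis(flatgrid, {}), SpeciesLifetimes(), met)


class TestBurdenDiagnostic:
    def test_single_species_mean_lifetime_is_tau(self, flatgrid):
        emis = _emis(flatgrid, {"so4": (0, 0, 3600.0)})
        d = burden_diagnostic(emis, SpeciesLifetimes())
        assert d["mean_lifetime_days"] == pytest.approx(2.8)

    def test_equal_flux_mixture_gives_flux_weighted_mean(self, flatgrid):
        """Equal sulphur sink fluxes at 1.5 and 2.8 days -> mean 2.15 days."""
        # 1 g/s of S as SO4 and 1 g/s of S carried by SO2 (2 g/s SO2 mass)
        emis = _emis(flatgrid, {"so4": (0, 0, 3600.0), "so2": (1, 1, 7200.0)})
        d = burden_diagnostic(emis, SpeciesLifetimes())
        assert d["mean_lifetime_days"] == pytest.approx(2.15)

    def test_zero_emissions_zero_burden(self, flatgrid):
        d = burden_diagnostic(_emis(flatgrid, {}), SpeciesLifetimes())
        assert d["sulphur_burden_g"] == 0.0


class TestNitrateCompensation:
    def test_zero_sulphate_change_zero_offset(self):
        assert np.all(nitrate_compensation(np.zeros((4, 4))) == 0)

    def test_default_offset_is_one_percent_of_reduction(self):
        d = -np.random.default_rng(1).uniform(0.5, 3.0, (6, 6))
        off = nitrate_compensation(d)
        np.testing.assert_allclose(off, 0.01 * (-d), rtol=1e-12)
        assert off.mean() <= 0.01 * (-d).mean() + 1e-12

    def test_offset_never_exceeds_cap_fraction(self):
        d = -np.random.default_rng(2).uniform(0.5, 3.0, (6, 6))
        mask = np.zeros((6, 6), dtype=bool)
        mask[:3] = True
        off = nitrate_compensation(d, kappa=0.01, high_ammonia_mask=mask,
                                   kappa_high=0.5, cap_fraction=0.15)
        assert np.all(off <= 0.15 * (-d) + 1e-12)

    def test_offset_capped_by_ammonia_availability(self):
        d = np.full((3, 3), -10.0)
        off = nitrate_compensation(d, ammonia_availability=0.02,
                                   high_ammonia_mask=np.ones((3, 3), bool))
        assert np.all(off <= 0.02 + 1e-15)

    def test_negative_availability_rejected(self):
        with pytest.raises(InputError):
            nitrate_compensation(np.zeros((2, 2)), ammonia_availability=-1.0)


class TestAssemble:
    def _field(self, grid, scale, scenario):
        z = np.zeros(grid.shape)
        f = ConcentrationField(grid=grid, scenario=scenario,
                               c_so4=np.full(grid.shape, scale),
                               c_no3=z.copy(), c_primary=z.copy(),
                               c_sslt=z.copy(), c_background=z.copy())
        return f

    def test_total_is_exact_component_sum(self, flatgrid):
        bg = np.full(flatgrid.shape, 7.0)
        out = assemble_pm25({"BAU": self._field(flatgrid, 2.0, "BAU")}, bg)
        np.testing.assert_array_equal(out["BAU"]["total"], 9.0)

    def test_all_zero_components_total_equals_background(self, flatgrid):
        bg = np.full(flatgrid.shape, 5.5)
        out = assemble_pm25({"NS": self._field(flatgrid, 0.0, "NS")}, bg)
        np.testing.assert_array_equal(out["NS"]["total"], bg)

    def test_removing_the_source_never_raises_concentration(self, flatgrid):
        bg = np.full(flatgrid.shape, 5.0)
        out = assemble_pm25({"BAU": self._field(flatgrid, 2.0, "BAU"),
                             "NS": self._field(flatgrid, 0.0, "NS")}, bg)
        assert np.all(out["delta:BAU-NS"] >= 0)

    def test_misaligned_grids_rejected(self, flatgrid):
        other = WorldGrid(lon_min=0, lat_min=0, cell_size=1.0, n_lon=3, n_lat=3)
        with pytest.raises(InputError):
            assemble_pm25({"A": self._field(flatgrid, 1.0, "A")},
                          np.zeros(other.shape))


def test_sea_salt_majority_share_over_clean_sea(grid20, world20, meteo20, fleet30):
    """Over sea cells far from traffic, sea salt dominates marine PM2.5."""
    from shipair import generate_background_pm, generate_traffic, grid_emissions
    from shipair import specs_from_frame
    cmap, _ = world20
    rec = generate_traffic(8, grid20, cmap, fleet30, period_hours=12)
    emis = grid_emissions(rec, specs_from_frame(fleet30), FuelPolicy.bau(), grid20)
    bg = generate_background_pm(4, grid20, cmap)
    conc = steady_state_concentration(emis, SpeciesLifetimes(), meteo20, background=bg)
    sea = cmap.sea_mask
    share = conc.c_sslt[sea] / conc.total_pm25[sea]
    assert np.median(share) > 0.4
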