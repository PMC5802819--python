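"""Activity-based ship emission factors and gridded emission inventories.

Per movement record: engine load from the cubic propeller law, load-dependent
specific fuel-oil consumption (SFOC), MARPOL Annex VI NOx tier curves,
fuel-sulphur-driven SOx with explicit sulphur mass balance between gaseous SO2
and primary sulphate, piecewise-linear PM factors, carbon-content CO2 factors,
and fuel-sulphur policy application (global caps plus stricter regional control
areas). Record energies are accumulated into per-species grid-cell masses.

Sulphur bookkeeping: the ``so4`` species of an :class:`EmissionGrid` stores
primary sulphate as *sulphur* mass, so fuel S = S(SO2)/2 + S(SO4) holds exactly
per record; the exposure stage converts sulphur to sulphate aerosol mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry

from .grids import ConfigurationError, WorldGrid

SPECIES = ("so2", "so4", "nox", "pm", "co", "co2")

#: Table-implied fraction of fuel sulphur emitted as primary sulphate
#: (the remainder leaves as gaseous SO2); distillates vs residual fuel.
SULPHATE_S_FRACTION = {"MDO_MGO": 0.04, "HFO": 0.063}

#: Table-implied fuel carbon factors: g CO2 per g fuel.
CO2_PER_G_FUEL = {"HFO": 515.0 / 165.0, "MDO_MGO": 803.0 / 250.0}

#: Compound annual growth rates per ship type (fraction/year), 2015->future.
GROWTH_RATES = {
    "dry_bulk": 0.0174,
    "liquid_bulk": -0.0190,
    "unitised": 0.0279,
    "passenger": -0.0055,
    "miscellaneous": 0.0000,
}

#: CO emission factors, g/kWh, at the two tabulated load points.
CO_EF = {0.8: 0.54, 0.25: 2.18}

#: PM emission factor anchors, g/kWh: fuel sulphur fraction -> value,
#: at normal (80%) and low (25%) load.
PM_ANCHORS_S = np.array([0.001, 0.005, 0.027])
PM_ANCHORS = {0.8: np.array([0.38, 0.50, 1.19]),
              0.25: np.array([0.43, 0.57, 1.35])}

MAX_S_FRAC = 0.035


class InputError(ValueError):
    """Raised for physically invalid operation inputs."""


@dataclass(frozen=True)
class VesselSpec:
    vessel_id: int
    ship_type: str
    installed_power: float        # kW
    design_speed: float           # m/s
    engine_class: str             # SSD | MSD | HSD
    crankshaft_rpm: float
    nox_tier: int
    base_sfoc: float              # g/kWh at 80% load
    fuel_family: str              # HFO | MDO_MGO

    def __post_init__(self) -> None:
        if self.installed_power <= 0 or self.base_sfoc <= 0:
            raise InputError("installed_power and base_sfoc must be positive")
        n = self.crankshaft_rpm
        ok = {"SSD": n < 130, "MSD": 130 <= n < 2000, "HSD": n >= 2000}
        if self.engine_class not in ok:
            raise InputError(f"unknown engine class {self.engine_class!r}")
        if not ok[self.engine_class]:
            raise InputError(
                f"rpm {n} inconsistent with engine class {self.engine_class}")


@dataclass(frozen=True)
class SulphurRegion:
    """A fuel-sulphur control area: cap applies inside the polygon from the
    effective date onward, and only where stricter than the global cap."""

    name: str
    polygon: BaseGeometry
    s_cap: float
    effective_date: pd.Timestamp = pd.Timestamp("2015-01-01")

    def __post_init__(self) -> None:
        if self.polygon.is_empty or not self.polygon.is_valid:
            raise ConfigurationError(f"region {self.name!r} has an invalid polygon")
        if not 0 <= self.s_cap <= MAX_S_FRAC:
            raise ConfigurationError("sulphur cap outside [0, 0.035]")


@dataclass(frozen=True)
class FuelPolicy:
    """Scenario fuel-sulphur policy: a global mass-fraction cap plus regional
    control areas (SECA 0.1%, EU directive / China DECA 0.5%)."""

    scenario: str
    global_s_frac: float
    regions: tuple[SulphurRegion, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not 0 <= self.global_s_frac <= MAX_S_FRAC:
            raise ConfigurationError("global sulphur fraction outside [0, 0.035]")

    @classmethod
    def bau(cls, regions: tuple[SulphurRegion, ...] = ()) -> "FuelPolicy":
        """Business as usual: 2.7% S residual fuel outside control areas."""
        return cls("BAU", 0.027, regions)

    @classmethod
    def action_2020(cls, regions: tuple[SulphurRegion, ...] = ()) -> "FuelPolicy":
        """Global 0.5% S cap in force."""
        return cls("ACTION_2020", 0.005, regions)


@dataclass
class EmissionGrid:
    """Per-cell, per-species emission masses for one scenario period.

    Masses are accumulated in grams internally; :meth:`totals_tonnes` reports
    tonnes. ``n_excluded`` counts records outside the grid bounds.
    """

    grid: WorldGrid
    species: dict[str, np.ndarray]
    scenario: str
    period_hours: float
    n_excluded: int = 0

    def total_g(self, species: str) -> float:
        return float(self.species[species].sum())

    def totals_tonnes(self) -> pd.Series:
        return pd.Series({s: self.total_g(s) / 1e6 for s in SPECIES}, name=self.scenario)

    def rate_ug_s(self, species: str) -> np.ndarray:
        """Mean emission rate over the period, ug/s per cell."""
        return self.species[species] * 1e6 / (self.period_hours * 3600.0)


# --------------------------------------------------------------------------
# per-record emission factors
# --------------------------------------------------------------------------

def propulsion_load(speed, design_speed, floor: float = 0.02):
    """Engine load fraction via the cubic propeller law, clamped to
    [floor, 1]. The floor stands in for auxiliary/hotelling power of slow or
    stationary vessels."""
    speed = np.asarray(speed, dtype=float)
    if np.any(speed < 0):
        raise InputError("speed must be non-negative")
    if np.any(np.asarray(design_speed) <= 0):
        raise InputError("design_speed must be positive")
    return np.clip((speed / design_speed) ** 3, floor, 1.0)


def _sfoc_curve(load):
    return 0.455 * load**2 - 0.71 * load + 1.28


def sfoc_at_load(base_sfoc, load):
    """Load-dependent SFOC (g/kWh): base SFOC (valid at 80% load) scaled by the
    relative consumption curve q(L) = 0.455 L^2 - 0.71 L + 1.28 normalised to
    unity at L = 0.8. Reproduces 165->186 and 250->282 g/kWh at 25% load."""
    load = np.asarray(load, dtype=float)
    if np.any(load <= 0) or np.any(load > 1):
        raise InputError("load must be in (0, 1]")
    return np.asarray(base_sfoc, dtype=float) * _sfoc_curve(load) / _sfoc_curve(0.8)


_NOX_FLAT = {  # g/kWh, rpm-independent classes
    ("SSD", 1): 17.0, ("SSD", 2): 14.4, ("SSD", 3): 3.4,
    ("HSD", 1): 9.8, ("HSD", 2): 7.7, ("HSD", 3): 2.0,
}
_NOX_MSD = {1: (45.0, -0.2), 2: (44.0, -0.23), 3: (9.0, -0.2)}


def nox_ef(tier: int, engine_class: str, rpm: float) -> float:
    """MARPOL Annex VI NOx emission factor (g/kWh). Tier 0 engines are assigned
    110% of the Tier I value."""
    if tier not in (0, 1, 2, 3):
        raise InputError(f"unknown NOx tier {tier}")
    if engine_class not in ("SSD", "MSD", "HSD"):
        raise InputError(f"unknown engine class {engine_class!r}")
    eff_tier, scale = (1, 1.1) if tier == 0 else (tier, 1.0)
    if engine_class == "MSD":
        a, p = _NOX_MSD[eff_tier]
        if rpm <= 0:
            raise InputError("MSD NOx curve needs a positive rpm")
        return scale * a * rpm**p
    return scale * _NOX_FLAT[(engine_class, eff_tier)]


def sox_split(s_frac: float, sfoc: float, fuel_family: str) -> tuple[float, float]:
    """(SO2 g/kWh, primary-sulphate *sulphur* g/kWh) from fuel sulphur content.

    Fuel sulphur mass per kWh is s_frac * sfoc; a fuel-family fraction f of it
    is emitted as primary sulphate (f = 0.04 distillate, 0.063 residual,
    implied by the emission-factor table) and the remainder as SO2 at twice
    the sulphur mass (molar mass ratio SO2:S = 64:32).
    """
    if not 0 <= s_frac <= MAX_S_FRAC:
        raise InputError("fuel sulphur fraction outside [0, 0.035]")
    if fuel_family not in SULPHATE_S_FRACTION:
        raise InputError(f"unknown fuel family {fuel_family!r}")
    f = SULPHATE_S_FRACTION[fuel_family]
    s_mass = s_frac * np.asarray(sfoc, dtype=float)
    return 2.0 * s_mass * (1.0 - f), s_mass * f


def pm_ef(s_frac: float, load) -> np.ndarray:
    """PM emission factor (g/kWh): piecewise linear in fuel sulphur between the
    tabulated anchors at 80% and 25% load, linear in load between those two
    points, constant beyond (clamped extrapolation)."""
    load = np.asarray(load, dtype=float)
    if np.any(load <= 0) or np.any(load > 1):
        raise InputError("load must be in (0, 1]")
    s = float(np.clip(s_frac, PM_ANCHORS_S[0], PM_ANCHORS_S[-1]))
    at_high = np.interp(s, PM_ANCHORS_S, PM_ANCHORS[0.8])
    at_low = np.interp(s, PM_ANCHORS_S, PM_ANCHORS[0.25])
    frac = np.clip((0.8 - load) / (0.8 - 0.25), 0.0, 1.0)
    return at_high + frac * (at_low - at_high)


def co_ef(load) -> np.ndarray:
    """CO emission factor (g/kWh), linear in load between the tabulated points."""
    load = np.asarray(load, dtype=float)
    frac = np.clip((0.8 - load) / (0.8 - 0.25), 0.0, 1.0)
    return CO_EF[0.8] + frac * (CO_EF[0.25] - CO_EF[0.8])


def co2_ef(fuel_family: str, sfoc) -> np.ndarray:
    """CO2 emission factor (g/kWh) = fuel carbon factor x SFOC."""
    if fuel_family not in CO2_PER_G_FUEL:
        raise InputError(f"unknown fuel family {fuel_family!r}")
    sfoc = np.asarray(sfoc, dtype=float)
    if np.any(sfoc < 0):
        raise InputError("sfoc must be non-negative")
    return CO2_PER_G_FUEL[fuel_family] * sfoc


def applicable_sulphur(lon: float, lat: float, when, policy: FuelPolicy) -> float:
    """Effective fuel sulphur fraction at a position/date: the minimum of the
    global cap and every regional cap whose polygon contains the position and
    whose effective date has passed."""
    when = pd.Timestamp(when)
    s = policy.global_s_frac
    pt = Point(float(lon), float(lat))
    for region in policy.regions:
        if region.effective_date <= when and region.polygon.covers(pt):
            s = min(s, region.s_cap)
    return s


def project_growth(value, ship_type: str, n_years: float,
                   growth_rates: dict[str, float] | None = None):
    """Compound growth scaling: value x (1+g)^n_years for the ship type."""
    rates = GROWTH_RATES if growth_rates is None else growth_rates
    if ship_type not in rates:
        raise InputError(f"unknown ship type {ship_type!r}")
    if n_years < 0:
        raise InputError("n_years must be >= 0")
    return value * (1.0 + rates[ship_type]) ** n_years


# --------------------------------------------------------------------------
# gridding
# --------------------------------------------------------------------------

def record_emissions(record, spec: VesselSpec, policy: FuelPolicy,
                     dt_hours: float = 1.0, growth_years: float = 0.0,
                     growth_rates: dict[str, float] | None = None) -> dict[str, float]:
    """Per-species emitted mass (grams) for one activity record.

    Energy = installed power x load x dt; mass = energy x emission factor,
    scaled by the ship-type compound growth factor.
    """
    load = float(propulsion_load(record.speed, spec.design_speed))
    sfoc = float(sfoc_at_load(spec.base_sfoc, load))
    s_frac = applicable_sulphur(record.lon, record.lat, record.timestamp, policy)
    ef_so2, ef_so4s = sox_split(s_frac, sfoc, spec.fuel_family)
    energy_kwh = spec.installed_power * load * dt_hours
    grams = {
        "so2": energy_kwh * ef_so2,
        "so4": energy_kwh * ef_so4s,
        "nox": energy_kwh * nox_ef(int(spec.nox_tier), spec.engine_class,
                                   spec.crankshaft_rpm),
        "pm": energy_kwh * float(pm_ef(s_frac, load)),
        "co": energy_kwh * float(co_ef(load)),
        "co2": energy_kwh * float(co2_ef(spec.fuel_family, sfoc)),
    }
    factor = project_growth(1.0, spec.ship_type, growth_years, growth_rates)
    return {k: v * factor for k, v in grams.items()}


def specs_from_frame(fleet: pd.DataFrame) -> dict[int, VesselSpec]:
    """Vessel registry DataFrame -> {vessel_id: VesselSpec}."""
    return {
        int(row.vessel_id): VesselSpec(
            vessel_id=int(row.vessel_id), ship_type=str(row.ship_type),
            installed_power=float(row.installed_power),
            design_speed=float(row.design_speed),
            engine_class=str(row.engine_class),
            crankshaft_rpm=float(row.crankshaft_rpm), nox_tier=int(row.nox_tier),
            base_sfoc=float(row.base_sfoc), fuel_family=str(row.fuel_family))
        for row in fleet.itertuples(index=False)
    }


def grid_emissions(records: pd.DataFrame, specs: dict[int, VesselSpec],
                   policy: FuelPolicy, grid: WorldGrid,
                   dt_hours: float = 1.0, growth_years: float = 0.0,
                   growth_rates: dict[str, float] | None = None,
                   period_hours: float | None = None) -> EmissionGrid:
    """Accumulate per-record emissions into a per-species grid inventory.

    Records outside the grid bounds are excluded and counted in
    ``n_excluded``. ``period_hours`` defaults to the record time span plus one
    record interval (used downstream to convert masses to mean rates).
    """
    fields = {s: np.zeros(grid.shape) for s in SPECIES}
    n_excluded = 0
    if len(records):
        missing = set(records.vessel_id.unique()) - set(specs)
        if missing:
            raise InputError(f"records reference vessels without specs: {sorted(missing)}")
    for rec in records.itertuples(index=False):
        if not bool(np.all(grid.contains(rec.lon, rec.lat))):
            n_excluded += 1
            continue
        row, col = grid.cell_index(rec.lon, rec.lat)
        grams = record_emissions(rec, specs[int(rec.vessel_id)], policy,
                                 dt_hours, growth_years, growth_rates)
        for sp, g in grams.items():
            fields[sp][int(row), int(col)] += g
    if period_hours is None:
        if len(records):
            span = records.timestamp.max() - records.timestamp.min()
            period_hours = span / pd.Timedelta(hours=1) + dt_hours
        else:
            period_hours = dt_hours
    return EmissionGrid(grid=grid, species=fields, scenario=policy.scenario,
                        period_hours=float(period_hours), n_excluded=n_excluded)
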