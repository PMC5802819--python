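"""Steady-state lifetime/kernel surrogate for the chemical-transport step.

Gridded emission masses become PM2.5 component concentration fields through a
box model: the column burden of a species with atmospheric lifetime tau fed at
rate Q is Q*tau at steady state; that burden is spread over neighbouring cells
with a mass-conserving isotropic exponential kernel whose e-folding length is
the advection distance over one lifetime (domain-mean wind x tau), and diluted
through the local mixing height into a near-surface concentration. A fixed
fraction of emitted SO2 sulphur is oxidised to sulphate; the rest of the
chemistry (ammonium nitrate equilibrium) is represented only by the bounded
nitrate-compensation offset.

Concentrations scale linearly with emissions for fixed meteorology, are
non-negative for non-negative inputs, and the kernel redistributes but never
creates or destroys column mass on the closed domain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import ConfigurationError, WorldGrid
from .world import MeteoFields

SECONDS_PER_DAY = 86_400.0
SO4_PER_S = 96.0 / 32.0     # sulphate aerosol mass per unit sulphur mass
S_PER_SO2 = 32.0 / 64.0
NO3_PER_NOX = 62.0 / 46.0   # nitrate mass per NOx mass (as NO2)


class InputError(ValueError):
    pass


@dataclass(frozen=True)
class SpeciesLifetimes:
    """Atmospheric e-folding lifetimes, days."""

    tau_so2: float = 1.5
    tau_so4: float = 2.8
    tau_no3: float = 2.8
    tau_primary: float = 2.8

    def __post_init__(self) -> None:
        if min(self.tau_so2, self.tau_so4, self.tau_no3, self.tau_primary) <= 0:
            raise ConfigurationError("species lifetimes must be positive")


@dataclass
class ConcentrationField:
    """Gridded PM2.5 component concentrations (ug/m3) for one scenario.

    ``c_so4``..``c_primary`` are ship-attributable; ``c_sslt`` and
    ``c_background`` come from the synthetic world. Total PM2.5 is the
    component sum.
    """

    grid: WorldGrid
    scenario: str
    c_so4: np.ndarray
    c_no3: np.ndarray
    c_primary: np.ndarray
    c_sslt: np.ndarray
    c_background: np.ndarray

    SHIP_COMPONENTS = ("c_so4", "c_no3", "c_primary")

    def components(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in
                ("c_so4", "c_no3", "c_primary", "c_sslt", "c_background")}

    @property
    def total_pm25(self) -> np.ndarray:
        return sum(self.components().values())

    @property
    def ship_pm25(self) -> np.ndarray:
        return sum(getattr(self, n) for n in self.SHIP_COMPONENTS)

    def validate(self) -> None:
        for name, arr in self.components().items():
            if np.any(arr < 0):
                raise InputError(f"negative concentrations in {name}")


def _exponential_kernel(grid: WorldGrid, efold_m: float) -> np.ndarray:
    """Row-normalised (n_cells, n_cells) redistribution kernel.

    Each row distributes a source cell's column mass over the domain with
    weight exp(-d/l); normalising rows to 1 conserves mass exactly on the
    closed domain. l -> 0 degenerates to the identity (no spreading).
    """
    if efold_m <= 0:
        return np.eye(grid.n_cells)
    d = grid.pairwise_distances_m()
    k = np.exp(-d / efold_m)
    return k / k.sum(axis=1, keepdims=True)


def _spread_concentration(mass_g: np.ndarray, tau_days: float, grid: WorldGrid,
                          meteo: MeteoFields, period_hours: float) -> np.ndarray:
    """Emission mass (g per period, per cell) -> concentration field (ug/m3)."""
    rate_ug_s = mass_g.ravel() * 1e6 / (period_hours * 3600.0)
    tau_s = tau_days * SECONDS_PER_DAY
    efold = float(np.mean(meteo.wind_speed)) * tau_s
    kernel = _exponential_kernel(grid, efold)
    column_ug = (rate_ug_s * tau_s) @ kernel          # column burden per cell
    volume = (grid.cell_areas() * meteo.mixing_height).ravel()
    return (column_ug / volume).reshape(grid.shape)


def steady_state_concentration(
    emis, lifetimes: SpeciesLifetimes, meteo: MeteoFields,
    so2_to_so4_fraction: float = 0.5,
    nox_to_no3_fraction: float = 0.1,
    background: np.ndarray | None = None,
) -> ConcentrationField:
    """Ship-attributable PM2.5 component fields from an emission inventory.

    Sulphate aerosol mass combines primary sulphate (emitted as sulphur) and
    the configured oxidised fraction of SO2 sulphur, both scaled to SO4 mass
    by 96/32. A small fraction of NOx forms particulate nitrate. Primary PM
    excludes the sulphate already counted separately (the inventory PM factor
    is total dry PM, so primary sulphate mass is subtracted, floored at zero).
    """
    grid = emis.grid
    if np.any(meteo.mixing_height <= 0):
        raise ConfigurationError("mixing height must be positive")
    if not 0 <= so2_to_so4_fraction <= 1:
        raise InputError("so2_to_so4_fraction must be in [0, 1]")

    so4_mass = SO4_PER_S * (
        emis.species["so4"]
        + so2_to_so4_fraction * S_PER_SO2 * emis.species["so2"]
    )
    no3_mass = nox_to_no3_fraction * NO3_PER_NOX * emis.species["nox"]
    primary_mass = np.clip(
        emis.species["pm"] - SO4_PER_S * emis.species["so4"], 0.0, None)

    ph = emis.period_hours
    zeros = np.zeros(grid.shape)
    return ConcentrationField(
        grid=grid, scenario=emis.scenario,
        c_so4=_spread_concentration(so4_mass, lifetimes.tau_so4, grid, meteo, ph),
        c_no3=_spread_concentration(no3_mass, lifetimes.tau_no3, grid, meteo, ph),
        c_primary=_spread_concentration(primary_mass, lifetimes.tau_primary,
                                        grid, meteo, ph),
        c_sslt=np.array(meteo.sea_salt_conc, dtype=float, copy=True),
        c_background=zeros if background is None else np.asarray(background, float),
    )


def nitrate_compensation(
    delta_so4: np.ndarray,
    ammonia_availability: np.ndarray | float = np.inf,
    kappa: float = 0.01,
    cap_fraction: float = 0.15,
    high_ammonia_mask: np.ndarray | None = None,
    kappa_high: float = 0.15,
) -> np.ndarray:
    """Ammonium-nitrate offset to a sulphate *reduction* field (ug/m3, >= 0).

    Where sulphate falls (delta_so4 < 0), freed ammonia forms nitrate worth a
    fraction kappa of the local sulphate reduction (kappa_high in designated
    high-ammonia cells), never more than cap_fraction of the reduction and
    never more than the ammonia-equivalent availability.
    """
    delta_so4 = np.asarray(delta_so4, dtype=float)
    avail = np.broadcast_to(np.asarray(ammonia_availability, dtype=float),
                            delta_so4.shape)
    if np.any(avail < 0):
        raise InputError("ammonia availability must be non-negative")
    reduction = np.clip(-delta_so4, 0.0, None)
    k = np.full(delta_so4.shape, kappa)
    if high_ammonia_mask is not None:
        k = np.where(high_ammonia_mask, min(kappa_high, cap_fraction), k)
    return np.minimum(np.minimum(k, cap_fraction) * reduction, avail)


def assemble_pm25(fields: dict[str, ConcentrationField],
                  background: np.ndarray) -> dict[str, dict]:
    """Attach a shared background, total the components and diff scenario pairs.

    Returns ``{scenario: {"field", "total", "sulphate_share"}}`` plus
    ``{"delta:<a>-<b>": array}`` entries for every ordered scenario pair.
    """
    out: dict[str, dict] = {}
    names = list(fields)
    ref_grid = fields[names[0]].grid
    for name, cf in fields.items():
        if cf.grid != ref_grid or cf.c_so4.shape != np.asarray(background).shape:
            raise InputError("misaligned grids in assemble_pm25")
        cf.c_background = np.asarray(background, dtype=float)
        cf.validate()
        total = cf.total_pm25
        out[name] = {
            "field": cf,
            "total": total,
            "sulphate_share": float(cf.c_so4.sum() / max(total.sum(), 1e-300)),
        }
    for a in names:
        for b in names:
            if a != b:
                out[f"delta:{a}-{b}"] = out[a]["total"] - out[b]["total"]
    return out


def burden_diagnostic(emis, lifetimes: SpeciesLifetimes) -> dict[str, float]:
    """Global steady-state sulphur burden and flux-weighted mean lifetime.

    Burden = sum over sulphur species of (sulphur emission rate x lifetime);
    at steady state the sink flux equals the source flux, so the mean lifetime
    is the burden over the total sulphur throughput.
    """
    q_so2_s = emis.total_g("so2") / (emis.period_hours * 3600.0) * S_PER_SO2
    q_so4_s = emis.total_g("so4") / (emis.period_hours * 3600.0)
    burden_g = (q_so2_s * lifetimes.tau_so2 + q_so4_s * lifetimes.tau_so4) \
        * SECONDS_PER_DAY
    total_flux = q_so2_s + q_so4_s
    mean_lifetime = (burden_g / SECONDS_PER_DAY / total_flux
                     if total_flux > 0 else 0.0)
    return {"sulphur_burden_g": burden_g, "mean_lifetime_days": mean_lifetime}
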