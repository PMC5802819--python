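"""Direct and first-indirect (Twomey) aerosol radiative forcing from scenario
concentration differences, via single-band box expressions.

Direct effect: a Haywood-Shine-type clear-sky top-of-atmosphere expression in
the aerosol optical depth perturbation, single-scattering albedo (SSA, omega),
hemispheric backscatter fraction and the underlying surface albedo. The
bracket term changes sign at a tipping SSA that grows with surface brightness:
scattering aerosol over a dark ocean cools, while even mildly absorbing
aerosol over a bright scene warms.

First-indirect effect: cloud droplet number from the empirical multi-component
relation D_n = a + b*C_NSS + c*C_SSLT (non-sea-salt sulphate and sea salt,
ug/m3), cloud albedo susceptibility dA = A0(1-A0)/3 * ln(Dn1/Dn0), and
forcing F = -S_local * f_cloud * dA * T_atm^2. The "detached" vertical-mixing
mode scales the in-cloud ship sulphate by a detachment factor before the
droplet relation, bounding the envelope between perfectly mixed and
bottom-trapped sulphate profiles.

Sign convention: negative = cooling. Global numbers are area-weighted means in
mW/m2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import WorldGrid
from .world import MeteoFields


class InputError(ValueError):
    pass


@dataclass(frozen=True)
class AerosolOptics:
    """Single-band aerosol optical properties."""

    ssa: float = 0.999                     # single-scattering albedo, (0, 1]
    mass_extinction_efficiency: float = 8.5  # m2/g, dry sulphate-like
    backscatter_fraction: float = 0.29

    def __post_init__(self) -> None:
        if not 0 < self.ssa <= 1:
            raise InputError("SSA must be in (0, 1]")
        if not 0 < self.backscatter_fraction <= 1:
            raise InputError("backscatter fraction must be in (0, 1]")
        if self.mass_extinction_efficiency <= 0:
            raise InputError("mass extinction efficiency must be positive")


@dataclass(frozen=True)
class DropletParams:
    """Empirical droplet-number fit: D_n = a + b*C_NSS + c*C_SSLT.

    The constants are applied to ug/m3 concentrations and read as droplet
    numbers per cm3 (``units``); only the ratio Dn1/Dn0 enters the Twomey
    susceptibility, so the unit choice does not affect forcing.
    """

    a: float = 31.0
    b: float = 93.5
    c: float = 16.5
    units: str = "per_cm3"

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise InputError("droplet fit constants must be positive")


@dataclass
class ForcingResult:
    """Global-mean direct and first-indirect forcing for one scenario pair."""

    scenario: str
    f_direct_mw_m2: float
    f_indirect_mw_m2: float
    mixing_mode: str = "well_mixed"
    f_direct_field: np.ndarray | None = None
    f_indirect_field: np.ndarray | None = None

    @property
    def f_net_mw_m2(self) -> float:
        return self.f_direct_mw_m2 + self.f_indirect_mw_m2


SOLAR_CONSTANT = 1361.0          # W/m2
ATM_TRANSMITTANCE = 0.76


def droplet_number(c_nss, c_sslt, params: DropletParams = DropletParams()):
    """Cloud droplet number from non-sea-salt sulphate and sea salt (ug/m3)."""
    c_nss = np.asarray(c_nss, dtype=float)
    c_sslt = np.asarray(c_sslt, dtype=float)
    if np.any(c_nss < 0) or np.any(c_sslt < 0):
        raise InputError("concentrations must be non-negative")
    return params.a + params.b * c_nss + params.c * c_sslt


def twomey_albedo_change(a0, dn0, dn1):
    """Cloud-albedo perturbation dA = A0(1-A0)/3 * ln(Dn1/Dn0), with the
    perturbed albedo clamped to [0, 1]."""
    a0 = np.asarray(a0, dtype=float)
    dn0 = np.asarray(dn0, dtype=float)
    dn1 = np.asarray(dn1, dtype=float)
    if np.any(dn0 <= 0) or np.any(dn1 <= 0):
        raise InputError("droplet numbers must be positive")
    if np.any(a0 < 0) or np.any(a0 > 1):
        raise InputError("cloud albedo must be in [0, 1]")
    da = a0 * (1.0 - a0) / 3.0 * np.log(dn1 / dn0)
    return np.clip(a0 + da, 0.0, 1.0) - a0


def column_aod(conc_ug_m3, mixing_height_m, optics: AerosolOptics):
    """AOD of a well-mixed layer: mass extinction efficiency x column mass."""
    conc = np.asarray(conc_ug_m3, dtype=float)
    return optics.mass_extinction_efficiency * conc * 1e-6 \
        * np.asarray(mixing_height_m, dtype=float)


def direct_forcing_field(delta_aod, optics: AerosolOptics, meteo: MeteoFields,
                         t_atm: float = ATM_TRANSMITTANCE,
                         solar: np.ndarray | float | None = None) -> np.ndarray:
    """Per-cell clear-sky direct forcing (W/m2) of an AOD perturbation.

    F = -(S/4) T^2 (1-f_c) omega beta (dAOD) [(1-R_s)^2 - (2 R_s/beta)(1/omega - 1)]
    with R_s the underlying albedo and beta the backscatter fraction. The
    bracket is positive (cooling) for bright aerosol over dark surfaces and
    flips sign once absorption outweighs backscatter over bright scenes.
    """
    if optics.ssa <= 0:
        raise InputError("SSA must be positive")
    delta_aod = np.asarray(delta_aod, dtype=float)
    s = (SOLAR_CONSTANT if solar is None else solar)
    rs = meteo.underlying_albedo
    beta = optics.backscatter_fraction
    omega = optics.ssa
    bracket = (1.0 - rs) ** 2 - (2.0 * rs / beta) * (1.0 / omega - 1.0)
    return (-(np.asarray(s) / 4.0) * t_atm**2 * (1.0 - meteo.cloud_fraction)
            * omega * beta * delta_aod * bracket)


def direct_forcing(delta_aod, optics: AerosolOptics, meteo: MeteoFields,
                   grid: WorldGrid, **kw) -> tuple[float, np.ndarray]:
    """Global area-weighted mean direct forcing in mW/m2, plus the field."""
    f = direct_forcing_field(delta_aod, optics, meteo, **kw)
    return float((f * grid.area_weights()).sum() * 1000.0), f * 1000.0


def tipping_ssa(surface_albedo, backscatter_fraction: float):
    """Analytic root of the direct-forcing bracket in omega:
    omega* = 1 / (1 + beta (1-R_s)^2 / (2 R_s)). Increases with R_s; no root
    for R_s = 0 (pure-scattering cooling regardless of SSA)."""
    rs = np.asarray(surface_albedo, dtype=float)
    with np.errstate(divide="ignore"):
        return np.where(
            rs > 0,
            1.0 / (1.0 + backscatter_fraction * (1.0 - rs) ** 2 / (2.0 * rs)),
            np.nan)


def ssa_sensitivity(delta_aod, ssa_values, meteo: MeteoFields, grid: WorldGrid,
                    optics: AerosolOptics = AerosolOptics()) -> pd.DataFrame:
    """Global direct forcing for each SSA in ``ssa_values`` (other optics held
    fixed). Over bright scenes F increases toward warming as SSA decreases."""
    rows = []
    for omega in ssa_values:
        opt = AerosolOptics(ssa=float(omega),
                            mass_extinction_efficiency=optics.mass_extinction_efficiency,
                            backscatter_fraction=optics.backscatter_fraction)
        f, _ = direct_forcing(delta_aod, opt, meteo, grid)
        rows.append({"ssa": float(omega), "f_direct_mw_m2": f})
    return pd.DataFrame(rows)


def indirect_forcing(
    c_nss0, c_nss1, meteo: MeteoFields, grid: WorldGrid,
    mixing_mode: str = "well_mixed",
    detachment: float = 0.25,
    cloud_albedo: np.ndarray | float = 0.5,
    params: DropletParams = DropletParams(),
    t_atm: float = ATM_TRANSMITTANCE,
) -> tuple[float, np.ndarray]:
    """Global first-indirect forcing (mW/m2) of an in-cloud sulphate change.

    ``c_nss0``/``c_nss1`` are counterfactual and scenario non-sea-salt sulphate
    fields (ug/m3). In ``detached`` mode, in-cloud convection is assumed not to
    loft the ship sulphate, so only a fraction ``detachment`` of it reaches the
    radiatively dominant upper cloud; the effective concentrations are scaled
    accordingly before the droplet relation.
    """
    if mixing_mode not in ("well_mixed", "detached"):
        raise InputError(f"unknown mixing mode {mixing_mode!r}")
    scale = detachment if mixing_mode == "detached" else 1.0
    if not 0 <= scale <= 1:
        raise InputError("detachment factor must be in [0, 1]")
    dn0 = droplet_number(np.asarray(c_nss0) * scale, meteo.sea_salt_conc, params)
    dn1 = droplet_number(np.asarray(c_nss1) * scale, meteo.sea_salt_conc, params)
    da = twomey_albedo_change(cloud_albedo, dn0, dn1)
    f = -meteo.insolation * meteo.cloud_fraction * da * t_atm**2
    return float((f * grid.area_weights()).sum() * 1000.0), f * 1000.0


def forcing_report(f_bau: ForcingResult, f_action: ForcingResult) -> pd.DataFrame:
    """Scenario forcing table: BAU, Action, and the net change per component
    (positive net change = reduced cooling), with percent change vs BAU."""
    if f_bau.mixing_mode != f_action.mixing_mode:
        raise InputError("scenario forcing results use different mixing modes")
    rows = []
    for name, b, a in (
        ("direct", f_bau.f_direct_mw_m2, f_action.f_direct_mw_m2),
        ("indirect", f_bau.f_indirect_mw_m2, f_action.f_indirect_mw_m2),
        ("net", f_bau.f_net_mw_m2, f_action.f_net_mw_m2),
    ):
        rows.append({
            "component": name, "bau_mw_m2": b, "action_mw_m2": a,
            "net_change_mw_m2": a - b,
            "pct_change_vs_bau": (100.0 * (a - b) / abs(b)) if b != 0 else np.nan,
        })
    return pd.DataFrame(rows)
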