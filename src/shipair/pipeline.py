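"""Scenario orchestration: no-shipping / BAU / 2020 Action runs on one shared
synthetic world, and cross-scenario emission, health and forcing reports.

All randomness lives in the world generators; given the world, every
downstream stage is a pure transform, so reruns with the same config produce
identical checksums for every deterministic stage.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .emissions import (EmissionGrid, FuelPolicy, SulphurRegion, grid_emissions,
                        specs_from_frame)
from .exposure import (ConcentrationField, SpeciesLifetimes, nitrate_compensation,
                       steady_state_concentration)
from .forcing import (AerosolOptics, ForcingResult, column_aod, direct_forcing,
                      indirect_forcing)
from .grids import ConfigurationError, WorldGrid
from .health import (DEFAULT_MODELS, BurdenResult, compute_burden,
                     percent_reduction, round_for_report)
from .world import (generate_background_pm, generate_fleet, generate_incidence,
                    generate_meteo, generate_traffic, generate_world)

NO_SHIPPING = "NO_SHIPPING"


@dataclass
class ScenarioConfig:
    """Everything one pipeline run needs; ``seed`` is mandatory."""

    seed: int
    n_lon: int = 30
    n_lat: int = 30
    cell_size: float = 0.5
    lon_min: float = -10.0
    lat_min: float = 30.0
    n_countries: int = 4
    coastal_bias: float = 3.0
    total_population: int = 20_000_000
    n_vessels: int = 100
    n_lanes: int = 3
    period_hours: int = 72
    growth_years: float = 5.0
    scenarios: tuple[str, ...] = ("BAU", "ACTION_2020")
    seca_fraction: float = 0.15       # share of the domain width under a SECA box
    lifetimes: SpeciesLifetimes = dc_field(default_factory=SpeciesLifetimes)
    ssa: float = 0.999
    mixing_mode: str = "well_mixed"
    detachment: float = 0.25
    models: dict = dc_field(default_factory=lambda: dict(DEFAULT_MODELS))

    REQUIRED = ("seed",)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "ScenarioConfig":
        for key in cls.REQUIRED:
            if key not in raw:
                raise ConfigurationError(f"config missing required field {key!r}")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
        if "scenarios" in raw:
            raw = {**raw, "scenarios": tuple(raw["scenarios"])}
        return cls(**raw)

    @property
    def grid(self) -> WorldGrid:
        return WorldGrid(lon_min=self.lon_min, lat_min=self.lat_min,
                         cell_size=self.cell_size, n_lon=self.n_lon,
                         n_lat=self.n_lat)


@dataclass
class RunManifest:
    config_hash: str
    software_version: str
    stage_checksums: dict[str, str]
    timestamps: dict[str, float]

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=1, sort_keys=True)


@dataclass
class RunResult:
    config: ScenarioConfig
    manifest: RunManifest
    world: dict
    emissions: dict[str, EmissionGrid]
    concentrations: dict[str, ConcentrationField]
    burdens: dict[str, BurdenResult]
    forcing: dict[str, ForcingResult]


def _checksum(*arrays) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()[:16]


def _default_seca(cfg: ScenarioConfig, sea_mask: np.ndarray) -> tuple[SulphurRegion, ...]:
    """A SECA box over the western ``seca_fraction`` of the domain."""
    if cfg.seca_fraction <= 0:
        return ()
    from shapely.geometry import box
    g = cfg.grid
    width = (g.lon_max - g.lon_min) * cfg.seca_fraction
    return (SulphurRegion("SECA", box(g.lon_min, g.lat_min,
                                      g.lon_min + width, g.lat_max), 0.001),)


def make_policy(scenario: str, regions: tuple[SulphurRegion, ...]) -> FuelPolicy:
    if scenario == "BAU":
        return FuelPolicy.bau(regions)
    if scenario == "ACTION_2020":
        return FuelPolicy.action_2020(regions)
    raise ConfigurationError(f"unknown scenario {scenario!r}")


def run_pipeline(cfg: ScenarioConfig, outdir: str | Path | None = None) -> RunResult:
    """Execute world -> emissions -> exposure -> health + forcing for every
    configured scenario plus the no-shipping counterfactual.

    Burdens are computed against the no-shipping counterfactual per scenario.
    If ``outdir`` is given, grids go to NetCDF, tables to CSV, and the run
    manifest to JSON.
    """
    t0 = time.time()
    checksums: dict[str, str] = {}
    stamps: dict[str, float] = {}
    cfg_hash = hashlib.sha256(
        json.dumps({k: str(v) for k, v in sorted(cfg.__dict__.items())})
        .encode()).hexdigest()[:16]

    grid = cfg.grid
    grid_, cmap, pop = generate_world(
        cfg.seed, grid, n_countries=cfg.n_countries, coastal_bias=cfg.coastal_bias,
        total_population=cfg.total_population)
    fleet = generate_fleet(cfg.seed + 1, cfg.n_vessels)
    records = generate_traffic(cfg.seed + 2, grid, cmap, fleet,
                               n_lanes=cfg.n_lanes, period_hours=cfg.period_hours)
    meteo = generate_meteo(cfg.seed + 3, grid, cmap)
    background = generate_background_pm(cfg.seed + 4, grid, cmap)
    incidence = generate_incidence(cfg.seed + 5, cmap.countries)
    checksums["world"] = _checksum(cmap.country_id, pop.persons,
                                   background, meteo.cloud_fraction)
    stamps["world"] = time.time() - t0

    specs = specs_from_frame(fleet)
    regions = _default_seca(cfg, cmap.sea_mask)
    emissions: dict[str, EmissionGrid] = {}
    concentrations: dict[str, ConcentrationField] = {}

    # no-shipping counterfactual: empty inventory on the same grid/meteo
    empty = records.iloc[0:0]
    for scenario in (NO_SHIPPING, *cfg.scenarios):
        if scenario == NO_SHIPPING:
            emis = grid_emissions(empty, specs, FuelPolicy(NO_SHIPPING, 0.027, regions),
                                  grid, period_hours=float(cfg.period_hours))
        else:
            emis = grid_emissions(records, specs, make_policy(scenario, regions),
                                  grid, growth_years=cfg.growth_years,
                                  period_hours=float(cfg.period_hours))
        emissions[scenario] = emis
        conc = steady_state_concentration(emis, cfg.lifetimes, meteo,
                                          background=background)
        concentrations[scenario] = conc
        checksums[f"emissions:{scenario}"] = _checksum(
            *(emis.species[s] for s in sorted(emis.species)))
        checksums[f"exposure:{scenario}"] = _checksum(conc.ship_pm25)
    stamps["emissions+exposure"] = time.time() - t0

    burdens: dict[str, BurdenResult] = {}
    forcing: dict[str, ForcingResult] = {}
    c0_field = concentrations[NO_SHIPPING].total_pm25
    optics = AerosolOptics(ssa=cfg.ssa)
    for scenario in cfg.scenarios:
        c1_field = concentrations[scenario].total_pm25
        burdens[scenario] = compute_burden(
            c0_field, np.maximum(c1_field, c0_field), pop, cmap, incidence,
            models=cfg.models, scenario_pair=f"{scenario} vs {NO_SHIPPING}")
        checksums[f"health:{scenario}"] = _checksum(
            burdens[scenario].by_country.E_central.to_numpy())

        d_aod = column_aod(
            concentrations[scenario].c_so4 + concentrations[scenario].c_no3
            - concentrations[NO_SHIPPING].c_so4 - concentrations[NO_SHIPPING].c_no3,
            meteo.mixing_height, optics)
        f_dir, _ = direct_forcing(d_aod, optics, meteo, grid)
        f_ind, _ = indirect_forcing(
            concentrations[NO_SHIPPING].c_so4, concentrations[scenario].c_so4,
            meteo, grid, mixing_mode=cfg.mixing_mode, detachment=cfg.detachment)
        forcing[scenario] = ForcingResult(scenario, f_dir, f_ind, cfg.mixing_mode)
    stamps["health+forcing"] = time.time() - t0

    manifest = RunManifest(config_hash=cfg_hash, software_version=_version(),
                           stage_checksums=checksums, timestamps=stamps)
    result = RunResult(cfg, manifest, {"grid": grid, "country_map": cmap,
                                       "population": pop, "meteo": meteo,
                                       "background": background,
                                       "incidence": incidence,
                                       "fleet": fleet, "records": records},
                       emissions, concentrations, burdens, forcing)
    if outdir is not None:
        _write_outputs(result, Path(outdir))
    return result


def _version() -> str:
    from . import __version__
    return __version__


def _write_outputs(result: RunResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    grid = result.world["grid"]
    sio.write_netcdf(sio.population_to_dataset(result.world["population"], grid),
                     outdir / "population.nc")
    sio.write_netcdf(sio.meteo_to_dataset(result.world["meteo"], grid),
                     outdir / "meteo.nc")
    sio.write_records_csv(result.world["records"], outdir / "activity.csv")
    result.world["fleet"].to_csv(outdir / "fleet.csv", index=False)
    result.world["incidence"].table.to_csv(outdir / "incidence.csv")
    for scen, emis in result.emissions.items():
        sio.write_netcdf(sio.emission_grid_to_dataset(emis),
                         outdir / f"emissions_{scen}.nc")
    for scen, conc in result.concentrations.items():
        sio.write_netcdf(sio.concentration_to_dataset(conc),
                         outdir / f"concentration_{scen}.nc")
    for scen, burden in result.burdens.items():
        burden.by_country.to_csv(outdir / f"burden_{scen}.csv", index=False)
    (outdir / "manifest.json").write_text(result.manifest.to_json())


# --------------------------------------------------------------------------
# scenario comparison
# --------------------------------------------------------------------------

def compare_scenarios(result: RunResult, base: str = "BAU",
                      alt: str = "ACTION_2020") -> dict:
    """Report bundle for a scenario pair run on the same world.

    Emission totals per pollutant, health burden with confidence bounds and
    avoided burden, forcing components with net change, and percent
    reductions.
    """
    for scen in (base, alt):
        if scen not in result.emissions:
            raise ConfigurationError(f"scenario {scen!r} not present in run")
    if result.emissions[base].grid != result.emissions[alt].grid:
        raise ConfigurationError("scenario grids do not match; comparison refused")

    emis_tab = pd.concat([result.emissions[base].totals_tonnes(),
                          result.emissions[alt].totals_tonnes()], axis=1)
    emis_tab["pct_reduction"] = [
        percent_reduction(a, b) if a > 0 else np.nan
        for a, b in zip(emis_tab[base], emis_tab[alt])]

    rows = []
    for endpoint in result.burdens[base].cells:
        eb = {c: result.burdens[base].total(endpoint, c)
              for c in ("E_low", "E_central", "E_high")}
        ea = {c: result.burdens[alt].total(endpoint, c)
              for c in ("E_low", "E_central", "E_high")}
        rows.append({
            "endpoint": endpoint,
            **{f"{k}_{base}": v for k, v in eb.items()},
            **{f"{k}_{alt}": v for k, v in ea.items()},
            "avoided_central": eb["E_central"] - ea["E_central"],
            "avoided_rounded": round_for_report(
                eb["E_central"] - ea["E_central"], endpoint),
            "pct_reduction": (percent_reduction(eb["E_central"], ea["E_central"])
                              if eb["E_central"] > 0 else np.nan),
        })
    health_tab = pd.DataFrame(rows)

    from .forcing import forcing_report
    forcing_tab = forcing_report(result.forcing[base], result.forcing[alt])

    return {"emissions": emis_tab, "health": health_tab, "forcing": forcing_tab,
            "base": base, "alt": alt}
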