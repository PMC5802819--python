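"""File interchange: CF-style NetCDF for gridded fields, CSV for tables and
activity records, GeoJSON for policy-region polygons.

NetCDF files are written in classic (NetCDF3) format through xarray's scipy
backend, which keeps the on-disk artefacts dependency-light.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
from shapely.geometry import mapping, shape

from .emissions import SPECIES, EmissionGrid, FuelPolicy, SulphurRegion
from .exposure import ConcentrationField
from .grids import WorldGrid
from .world import MeteoFields, PopulationGrid


def _coords(grid: WorldGrid) -> dict:
    return {"lat": ("lat", grid.lat_centers, {"units": "degrees_north"}),
            "lon": ("lon", grid.lon_centers, {"units": "degrees_east"})}


def grid_attrs(grid: WorldGrid) -> dict:
    return {"lon_min": grid.lon_min, "lat_min": grid.lat_min,
            "cell_size": grid.cell_size, "n_lon": grid.n_lon, "n_lat": grid.n_lat}


def grid_from_attrs(attrs: dict) -> WorldGrid:
    return WorldGrid(lon_min=float(attrs["lon_min"]), lat_min=float(attrs["lat_min"]),
                     cell_size=float(attrs["cell_size"]),
                     n_lon=int(attrs["n_lon"]), n_lat=int(attrs["n_lat"]))


def dataset_on_grid(grid: WorldGrid, fields: dict[str, np.ndarray],
                    units: str, attrs: dict | None = None) -> xr.Dataset:
    data = {k: (("lat", "lon"), np.asarray(v), {"units": units})
            for k, v in fields.items()}
    return xr.Dataset(data, coords=_coords(grid),
                      attrs={**grid_attrs(grid), **(attrs or {})})


def write_netcdf(ds: xr.Dataset, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ds.to_netcdf(path, engine="scipy")
    return path


def read_netcdf(path: str | Path) -> xr.Dataset:
    return xr.open_dataset(path, engine="scipy").load()


# ---- typed writers/readers -------------------------------------------------

def emission_grid_to_dataset(emis: EmissionGrid) -> xr.Dataset:
    ds = dataset_on_grid(emis.grid, emis.species, units="g",
                         attrs={"scenario": emis.scenario,
                                "period_hours": emis.period_hours,
                                "n_excluded": emis.n_excluded})
    return ds


def emission_grid_from_dataset(ds: xr.Dataset) -> EmissionGrid:
    grid = grid_from_attrs(ds.attrs)
    return EmissionGrid(grid=grid,
                        species={s: ds[s].values.copy() for s in SPECIES},
                        scenario=str(ds.attrs["scenario"]),
                        period_hours=float(ds.attrs["period_hours"]),
                        n_excluded=int(ds.attrs["n_excluded"]))


def concentration_to_dataset(cf: ConcentrationField) -> xr.Dataset:
    return dataset_on_grid(cf.grid, cf.components(), units="ug m-3",
                           attrs={"scenario": cf.scenario})


def concentration_from_dataset(ds: xr.Dataset) -> ConcentrationField:
    grid = grid_from_attrs(ds.attrs)
    comp = {k: ds[k].values.copy() for k in
            ("c_so4", "c_no3", "c_primary", "c_sslt", "c_background")}
    return ConcentrationField(grid=grid, scenario=str(ds.attrs["scenario"]), **comp)


def meteo_to_dataset(met: MeteoFields, grid: WorldGrid) -> xr.Dataset:
    fields = {"cloud_fraction": met.cloud_fraction, "insolation": met.insolation,
              "wind_speed": met.wind_speed, "mixing_height": met.mixing_height,
              "sea_salt_conc": met.sea_salt_conc,
              "underlying_albedo": met.underlying_albedo}
    return dataset_on_grid(grid, fields, units="mixed")


def meteo_from_dataset(ds: xr.Dataset) -> MeteoFields:
    return MeteoFields(**{k: ds[k].values.copy() for k in
                          ("cloud_fraction", "insolation", "wind_speed",
                           "mixing_height", "sea_salt_conc", "underlying_albedo")})


def population_to_dataset(pop: PopulationGrid, grid: WorldGrid) -> xr.Dataset:
    return dataset_on_grid(grid, {"persons": pop.persons.astype(float),
                                  "country_id": pop.country_map.country_id.astype(float)},
                           units="count")


def write_records_csv(records: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = records.copy()
    if "timestamp" in out:
        out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime(
            "%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)
    return path


def read_records_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "timestamp" in df:
        df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def policy_regions_to_geojson(policy: FuelPolicy, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    features = [{
        "type": "Feature",
        "properties": {"name": r.name, "s_cap": r.s_cap,
                       "effective_date": str(r.effective_date.date())},
        "geometry": mapping(r.polygon),
    } for r in policy.regions]
    path.write_text(json.dumps({"type": "FeatureCollection",
                                "features": features}, indent=1))
    return path


def policy_regions_from_geojson(path: str | Path) -> tuple[SulphurRegion, ...]:
    fc = json.loads(Path(path).read_text())
    return tuple(
        SulphurRegion(name=f["properties"]["name"],
                      polygon=shape(f["geometry"]),
                      s_cap=float(f["properties"]["s_cap"]),
                      effective_date=pd.Timestamp(f["properties"]["effective_date"]))
        for f in fc["features"])
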