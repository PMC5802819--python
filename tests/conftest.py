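import numpy as np
import pytest

from shipair import (ScenarioConfig, WorldGrid, generate_fleet, generate_meteo,
                     generate_world)


@pytest.fixture(scope="session")
def grid20():
    return WorldGrid(lon_min=0.0, lat_min=40.0, cell_size=0.5, n_lon=20, n_lat=20)


@pytest.fixture(scope="session")
def world20(grid20):
    _, cmap, pop = generate_world(seed=7, grid=grid20, n_countries=3,
                                  coastal_bias=3.0, total_population=5_000_000)
    return cmap, pop


@pytest.fixture(scope="session")
def meteo20(grid20, world20):
    cmap, _ = world20
    return generate_meteo(seed=11, grid=grid20, country_map=cmap)


@pytest.fixture(scope="session")
def fleet30():
    return generate_fleet(seed=3, n_vessels=30)


@pytest.fixture(scope="session")
def small_run():
    """One shared small pipeline run for pipeline-level tests."""
    from shipair import run_pipeline
    cfg = ScenarioConfig(seed=5, n_lon=15, n_lat=15, n_vessels=25,
                         period_hours=24, n_countries=3)
    return run_pipeline(cfg)


@pytest.fixture
def flat_meteo():
    """Spatially constant meteorology on a given shape, built on demand."""
    from shipair import MeteoFields

    def make(shape, wind=0.0, mix=1000.0, cloud=0.5, sslt=0.0, albedo=0.1,
             insolation=300.0):
        full = lambda v: np.full(shape, float(v))
        return MeteoFields(cloud_fraction=full(cloud), insolation=full(insolation),
                           wind_speed=full(wind), mixing_height=full(mix),
                           sea_salt_conc=full(sslt), underlying_albedo=full(albedo))

    return make
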