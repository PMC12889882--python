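import numpy as np
import pytest
from hypothesis import settings

from airsurf import WorldConfig, generate_world

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_world():
    """A compact world with smoke, AOD gaps, and 1-in-3 reporting."""
    return generate_world(WorldConfig(
        grid_nx=12, grid_ny=12, cell_km=15.0, n_stations=15, n_days=45,
        ar1_rho=0.7, station_reporting_period=3, aod_missing_rate=0.3,
        seed=7))


@pytest.fixture(scope="session")
def daily_world():
    """Daily-reporting world without AOD gaps (fast, deterministic paths)."""
    return generate_world(WorldConfig(
        grid_nx=10, grid_ny=10, cell_km=15.0, n_stations=12, n_days=40,
        ar1_rho=0.6, station_reporting_period=1, aod_missing_rate=0.0,
        seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
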