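import numpy as np
import pandas as pd
import pytest

from medcarry import SyntheticCityConfig, generate_city, generate_od_matrix


@pytest.fixture(scope="session")
def small_city():
    """A compact synthetic city shared across tests (10x10 grid, 15 hospitals)."""
    cfg = SyntheticCityConfig(
        grid_nx=10, grid_ny=10, n_hospitals=15, supply_demand_corr=0.7, seed=7
    )
    demand, hospitals, road = generate_city(cfg)
    od = generate_od_matrix(demand, hospitals, road)
    return cfg, demand, hospitals, road, od


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def yearbook_panel():
    """Tiny hand-made year x indicator panel with two layers."""
    years = pd.Index(range(2000, 2010), name="year")
    t = np.arange(10)
    return pd.DataFrame(
        {
            "beds": 100 * 1.08**t,
            "doctors": 50 * 1.06**t,
            "patients": 200 * 1.07**t,
            "population": 1000 * 1.05**t,
        },
        index=years,
    )


@pytest.fixture()
def layer_map():
    return {
        "beds": "supply",
        "doctors": "supply",
        "patients": "demand",
        "population": "demand",
    }
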