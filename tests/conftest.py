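import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from geofoot.simulate import SimulationConfig, assign_deprivation, generate_geography
from geofoot.zones import ZoneSet


def grid_zones(nx: int, ny: int, quintiles=None, populations=None) -> ZoneSet:
    """nx x ny grid of unit squares, row-major from the bottom-left."""
    ids, polys = [], []
    for j in range(ny):
        for i in range(nx):
            ids.append(f"G{i}_{j}")
            polys.append(box(i, j, i + 1, j + 1))
    return ZoneSet(ids, polys, populations=populations, quintiles=quintiles)


@pytest.fixture(scope="session")
def grid3():
    return grid_zones(3, 3)


@pytest.fixture(scope="session")
def small_geography():
    """200-zone synthetic geography with deprivation, shared across tests."""
    cfg = SimulationConfig(n_zones=200, seed=11)
    zones = generate_geography(cfg)
    return assign_deprivation(zones, cfg.deprivation_smoothness, cfg.seed)


@pytest.fixture()
def tiny_cohort():
    """Three persons in one zone; one DFU case."""
    return pd.DataFrame(
        {
            "person_id": ["a", "b", "c"],
            "zone_id": ["G0_0", "G0_0", "G0_0"],
            "entry_date": pd.to_datetime(["2002-03-01", "2003-01-01", "2010-06-15"]),
            "dfu_date": pd.to_datetime(["2013-05-01", pd.NaT, pd.NaT]),
            "lea_date": pd.to_datetime([pd.NaT, pd.NaT, pd.NaT]),
            "lea_level": [None, None, None],
            "death_date": pd.to_datetime([pd.NaT, pd.NaT, pd.NaT]),
        }
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20251001)
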