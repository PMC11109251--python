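import numpy as np
import pytest
from shapely.geometry import box

from ocean3d import BathymetryGrid, EcoregionMap, GridSpec
from ocean3d.synthetic_data import SeascapeParams, simulate_seascape


@pytest.fixture(scope="session")
def seascape():
    """One default synthetic seascape shared across tests."""
    return simulate_seascape(seed=7)


@pytest.fixture(scope="session")
def small_params():
    return SeascapeParams(n_rows=40, n_cols=60, n_events_per_year=400, seed=11)


@pytest.fixture(scope="session")
def small_seascape(small_params):
    return simulate_seascape(small_params)


def flat_grid(depths, resolution_deg=0.01, lat0=0.0, lon0=0.0):
    """1-row bathymetry grid with prescribed seabed depths (m, positive).

    All cells sit at the same latitude, so they have identical areas —
    convenient for worked examples with exact fractions.  Non-positive
    entries become land.
    """
    depths = np.asarray(depths, dtype=float)
    spec = GridSpec(resolution_deg, lat0, lon0, 1, depths.size)
    elevation = np.where(depths > 0, -depths, 30.0).reshape(1, -1)
    return BathymetryGrid(spec, elevation)


def one_ecoregion(spec, label="eco", cls="offshore"):
    geom = box(spec.lon0, spec.lat0, spec.lon_max, spec.lat_max)
    return EcoregionMap([label], [cls], [geom])
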