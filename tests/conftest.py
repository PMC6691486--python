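import numpy as np
import pandas as pd
import pytest

from thermalscape.fixtures import ForcingSpec, TerrainSpec, synthetic_dem
from thermalscape.terrain import ElevationGrid


@pytest.fixture
def flat_dem() -> ElevationGrid:
    return synthetic_dem(TerrainSpec(kind="plane", shape=(9, 9), cell_size=0.02,
                                     base_elevation=1.0, target_rq=None))


@pytest.fixture
def random_dem() -> ElevationGrid:
    rng = np.random.default_rng(42)
    return ElevationGrid(rng.normal(1.0, 0.05, size=(12, 12)), cell_size=0.02)


@pytest.fixture
def summer_forcing() -> ForcingSpec:
    """One clear-sky mid-latitude summer day, always-emersed tide."""
    return ForcingSpec(start="2017-06-22", n_days=1, tide_amplitude=0.0,
                       tide_datum_offset=0.0)


@pytest.fixture
def noon_utc() -> pd.Timestamp:
    # local solar noon at 70.843 degW is ~16:43 UTC
    return pd.Timestamp("2017-06-22 17:00", tz="UTC")
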