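import numpy as np
import pytest

from sdmrisk.grids import ARC_MIN_2_5, GridSpec
from sdmrisk.synthetic import generate_env_stack


@pytest.fixture(scope="session")
def small_grid() -> GridSpec:
    return GridSpec(n_rows=20, n_cols=20, cell_size=ARC_MIN_2_5, origin_lon=10.0, origin_lat=30.0)


@pytest.fixture(scope="session")
def env_small(small_grid):
    """Three mildly autocorrelated independent layers on the small grid."""
    return generate_env_stack(small_grid, n_layers=3, autocorr_range=4.0, seed=42)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
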