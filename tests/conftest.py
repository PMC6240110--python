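import numpy as np
import pytest

from rhograd.grid import SpatialGrid
from rhograd.synth import GeneratorConfig, calibrate_cdc42_shape, calibrate_rac1_shape


@pytest.fixture(scope="session")
def default_grid():
    return SpatialGrid()


@pytest.fixture(scope="session")
def fine_grid():
    """0.005 µm grid used as brute-force oracle resolution."""
    return SpatialGrid(length=35.0, spacing=0.005)


@pytest.fixture(scope="session")
def gen_config():
    return GeneratorConfig()


@pytest.fixture(scope="session")
def window_positions(gen_config):
    return gen_config.positions


@pytest.fixture(scope="session")
def cdc42_shape():
    return calibrate_cdc42_shape()


@pytest.fixture(scope="session")
def rac1_shape():
    return calibrate_rac1_shape()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
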