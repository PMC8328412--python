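import logging

import numpy as np
import pytest

from pikasim.config import SimulationConfig
from pikasim.territory import generate_landscape

logging.getLogger("pikasim.territory").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A fast config: 200 m square, 100 systems (~400 m^2 cells, as at
    full scale), 2 days."""
    return SimulationConfig(L=200.0, n_systems=100, D_tol=2, t_tol=10.0, seed=7)


@pytest.fixture(scope="session")
def small_landscape(small_config):
    return generate_landscape(small_config, seed=3)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
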