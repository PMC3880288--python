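import numpy as np
import pytest

from tumorsim import SimulationConfig, init_state


@pytest.fixture
def tiny_config():
    """Small, fast configuration for unit tests."""
    return SimulationConfig(grid_points_per_axis=16, domain_edge=0.0008,
                            total_days=1.0, rng_seed=7, c_init=0.0)


@pytest.fixture
def tiny_state(tiny_config):
    return init_state(tiny_config)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
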