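import numpy as np
import pytest

from prnet.network import NetworkConfig, initialize_network


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A 20-neuron, 3-winner network for fast unit tests."""
    return NetworkConfig(N=20, k=3, connectivity=0.3)


@pytest.fixture
def small_net(small_config, rng):
    params, state = initialize_network(small_config, rng)
    return small_config, params, state
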