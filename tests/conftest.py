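import numpy as np
import pytest

from econrnn import taskenv
from econrnn.network import NetworkConfig, init_params


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tasks():
    return taskenv.make_tasks()


@pytest.fixture
def tiny_params(rng):
    """Small network for fast dynamics/gradient tests."""
    cfg = NetworkConfig(n_neurons=16, frac_exc=0.75)
    return init_params(cfg, rng)
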