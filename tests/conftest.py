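import numpy as np
import pytest

from oncostream import ModelParams, SimulationConfig, init_random


@pytest.fixture
def params2d():
    """Reference elongated-cell parameters in a small 2D box."""
    return ModelParams(a=5.5, b=3.0, c=10.0, alpha=40.0, beta=1.0, L=60.0, d=2)


@pytest.fixture
def params3d():
    return ModelParams(a=5.5, b=3.0, c=10.0, alpha=40.0, beta=1.0, L=40.0, d=3)


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)


def random_config(params, n, seed):
    return init_random(n, params, seed)
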