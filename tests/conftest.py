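import numpy as np
import pytest

from tcnet.corex import CorexConfig, fit_layer
from tcnet.synthetic import gen_dependent_mixture, gen_modular_blocks


@pytest.fixture(scope="session")
def modular_data():
    """3 blocks x 4 variables, within-block rho 0.6, n=2000."""
    return gen_modular_blocks((4, 4, 4), 0.6, 2000, seed=0)


@pytest.fixture(scope="session")
def modular_layer(modular_data):
    ts, _ = modular_data
    return fit_layer(ts, CorexConfig(seed=0), m=3)


@pytest.fixture(scope="session")
def mixture_data():
    """Six-variable dependent/independent mixture (defaults)."""
    return gen_dependent_mixture(500, 0.5, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
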