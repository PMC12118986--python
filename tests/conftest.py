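import numpy as np
import pytest

from oie import IDENTIFIED_GAMMA, IDENTIFIED_NOISE, predict_surface


@pytest.fixture(scope="session")
def identified_noise():
    return IDENTIFIED_NOISE


@pytest.fixture(scope="session")
def gamma_star():
    return IDENTIFIED_GAMMA


@pytest.fixture(scope="session")
def stationary_table(identified_noise, gamma_star):
    """Noise-free 3x3 coactivation table at the OIE stationary points."""
    return predict_surface(identified_noise, gamma_star).values


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
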