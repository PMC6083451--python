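import numpy as np
import pytest

from ecwm.neural import PopulationConfig
from ecwm.priors import Prior


@pytest.fixture(scope="session")
def uniform_prior():
    return Prior("uniform")


@pytest.fixture(scope="session")
def cardinal_prior():
    return Prior("natural_cardinal")


@pytest.fixture(scope="session")
def oblique_prior():
    return Prior("adapt_oblique")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_config(cardinal_prior):
    return PopulationConfig(M=100, kappa=2.0, gamma=50.0, prior=cardinal_prior)


@pytest.fixture(scope="session")
def uniform_config(uniform_prior):
    return PopulationConfig(M=100, kappa=2.0, gamma=50.0, prior=uniform_prior)
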