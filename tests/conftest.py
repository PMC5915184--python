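import numpy as np
import pytest

from ornmix.ensemble import EnsembleConfig
from ornmix.fixtures import generate_fixtures


@pytest.fixture(scope="session")
def fixtures():
    return generate_fixtures()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240817)


@pytest.fixture()
def config_p05():
    return EnsembleConfig(rho=0.0, p=0.5)
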