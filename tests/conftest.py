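import numpy as np
import pytest

from oxlink.digest import DigestSpec
from oxlink.simulate import default_spec, mini_fibronectin, table2_crosslink_plants


@pytest.fixture(scope="session")
def fixture_protein():
    return mini_fibronectin()


@pytest.fixture(scope="session")
def plants():
    return table2_crosslink_plants()


@pytest.fixture(scope="session")
def sim_spec():
    return default_spec(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


@pytest.fixture(scope="session")
def digest_spec():
    return DigestSpec()
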