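import numpy as np
import pytest

from idtnet import DynamicsParams
from idtnet.fixtures import (
    path_network,
    random_simple_network,
    star_network,
    triangle_network,
    two_spin_chain,
)


@pytest.fixture(scope="session")
def star6():
    """Six units: hub 0 plus five leaves."""
    return star_network(5)


@pytest.fixture(scope="session")
def path5():
    return path_network(5)


@pytest.fixture(scope="session")
def triangle():
    return triangle_network()


@pytest.fixture(scope="session")
def two_spin():
    return two_spin_chain()


@pytest.fixture(scope="session")
def random8():
    return random_simple_network(8, 12, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(params=["glauber", "metropolis"])
def rule(request):
    return request.param


def make_params(temperature=2.0, rule="glauber", seed=0):
    return DynamicsParams(temperature=temperature, rule=rule, seed=seed)
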