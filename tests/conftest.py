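import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from latticefold import make_lattice


@pytest.fixture(scope="session")
def square2():
    return make_lattice("square", 2)


@pytest.fixture(scope="session")
def square3():
    return make_lattice("square", 3)


@pytest.fixture(scope="session")
def tri2():
    return make_lattice("triangular", 2)


@pytest.fixture(scope="session")
def tri3():
    return make_lattice("triangular", 3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
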