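import numpy as np
import pytest

from burstnet import make_distribution


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def power2():
    """Power-law alpha=2 on a support long enough that truncation is
    invisible at test tolerances."""
    return make_distribution("power_law", 2.0, 10 ** 6)


@pytest.fixture(scope="session")
def power19():
    return make_distribution("power_law", 1.9, 10 ** 6)


@pytest.fixture(scope="session")
def exp1():
    return make_distribution("discrete_exponential", 1.0, 500)
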