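import numpy as np
import pytest

from snowflakesim import GrowthConstraints, build_unconstrained_tree


@pytest.fixture(scope="session")
def uncapped_t3():
    return build_unconstrained_tree(3)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def unconstrained():
    return GrowthConstraints(degree_cap=None, volume_limited=False)
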