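import numpy as np
import pytest

from dimernet import ConcentrationProfile, DimerizationNetwork, TitrationGrid


@pytest.fixture
def grid1():
    return TitrationGrid.default(1)


@pytest.fixture
def grid2():
    return TitrationGrid.default(2)


@pytest.fixture
def pair_network():
    """Single heterodimer M1-M2."""
    return DimerizationNetwork(2, ((0, 1),), (1.0,))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_small_network(m, seed, affinity_range=(-5.0, 7.0)):
    from dimernet import random_network

    return random_network(m, seed=seed, affinity_range=affinity_range)
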