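import numpy as np
import pytest

from aridiv import simulate_yule
from aridiv.treeio import parse_newick


@pytest.fixture
def three_tip():
    return parse_newick("((a:5,b:5):5,c:10);")


@pytest.fixture
def four_tip():
    return parse_newick("((a:4,b:4):6,(c:8,d:8):2);")


@pytest.fixture
def yule_factory():
    """Factory for seeded Yule trees."""

    def make(n=10, lam=0.3, seed=0):
        return simulate_yule(n, lam, seed)

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
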