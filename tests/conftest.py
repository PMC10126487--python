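import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from crossfeednet import CommunityModel, SpeciesModel

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def chain_model():
    """medium {m0}; a eats m0 -> secretes m1; b eats m1."""
    return CommunityModel(
        ["m0", "m1"],
        frozenset({"m0"}),
        [
            SpeciesModel.make("a", {"m0"}, {"m1"}),
            SpeciesModel.make("b", {"m1"}, set()),
        ],
    )


@pytest.fixture
def deadlock_model():
    """Mutual dependency with no entry point: neither can ever grow."""
    return CommunityModel(
        ["x", "y"],
        frozenset(),
        [
            SpeciesModel.make("a", {"x"}, {"y"}),
            SpeciesModel.make("b", {"y"}, {"x"}),
        ],
    )


@pytest.fixture
def redundant_donor_model():
    """Recipient needs e (medium) and x; two interchangeable donors of x."""
    return CommunityModel(
        ["e", "x"],
        frozenset({"e"}),
        [
            SpeciesModel.make("r", {"e", "x"}, set()),
            SpeciesModel.make("d1", {"e"}, {"x"}),
            SpeciesModel.make("d2", {"e"}, {"x"}),
            SpeciesModel.make("b1", {"e"}, set()),
        ],
    )


def random_digraph(rng: np.random.Generator, n: int, p: float, self_loops: bool = False):
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    for u, v in itertools.product(range(n), repeat=2):
        if u == v and not self_loops:
            continue
        if rng.random() < p:
            g.add_edge(u, v)
    return g
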