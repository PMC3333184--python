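import networkx as nx
import pytest

from netprio.network_io import GeneNetwork
from netprio.synthetic import benchmark_fixture


def make_network(edges, weighted=False, extra_nodes=()):
    """Build a GeneNetwork from (a, b) pairs or (a, b, w) triples."""
    triples = [(e[0], e[1], e[2] if len(e) > 2 else 1.0) for e in edges]
    return GeneNetwork.from_edges(triples, weighted=weighted, extra_nodes=extra_nodes)


@pytest.fixture
def triangle():
    """Unweighted triangle a-b-c."""
    return make_network([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def weighted_star():
    """a-b (0.5), a-c (0.7)."""
    return make_network([("a", "b", 0.5), ("a", "c", 0.7)], weighted=True)


@pytest.fixture
def hub_path():
    """Path a-u-b with extra spokes u-c, u-d (connector u between a and b)."""
    return make_network([("a", "u"), ("u", "b"), ("u", "c"), ("u", "d")])


@pytest.fixture(scope="session")
def tiny_fixture():
    return benchmark_fixture("tiny")
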