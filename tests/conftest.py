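import networkx as nx
import pytest

from orcflow.dmk import DMKConfig


def make_weighted(edges):
    G = nx.Graph()
    for e in edges:
        if len(e) == 3:
            u, v, w = e
        else:
            (u, v), w = e, 1.0
        G.add_edge(u, v, weight=float(w))
    return G


@pytest.fixture
def triangle():
    """K3 with unit weights."""
    return make_weighted([(1, 2), (2, 3), (1, 3)])


@pytest.fixture
def path3():
    """Path 1-2-3 with unit weights."""
    return make_weighted([(1, 2), (2, 3)])


@pytest.fixture
def single_edge():
    G = nx.Graph()
    G.add_edge("a", "b", weight=0.4)
    return G


@pytest.fixture
def barbell_triangles():
    """Two unit-weight triangles joined by a unit bridge (3-4)."""
    return make_weighted(
        [(1, 2), (2, 3), (1, 3), (4, 5), (5, 6), (4, 6), (3, 4)]
    )


@pytest.fixture
def two_k4_bridge():
    """Two K4 cliques joined by one unit bridge edge (3-4); 13 edges."""
    G = nx.Graph()
    for base in (0, 4):
        for a in range(4):
            for b in range(a + 1, 4):
                G.add_edge(base + a, base + b, weight=1.0)
    G.add_edge(3, 4, weight=1.0)
    return G


@pytest.fixture
def star4():
    """Star with center 0 and 4 leaves."""
    return make_weighted([(0, i) for i in range(1, 5)])


@pytest.fixture
def dmk_config():
    return DMKConfig()
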