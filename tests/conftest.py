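import networkx as nx
import pytest

from gamecover import Graph, karate_fixture


@pytest.fixture(scope="session")
def karate():
    return karate_fixture()


@pytest.fixture(scope="session")
def triangle():
    return Graph([(1, 2), (2, 3), (1, 3)])


def random_graph(seed: int, n: int = 30, p: float = 0.12) -> Graph:
    """Seeded Erdos-Renyi helper; regenerates until at least one edge."""
    for s in range(seed, seed + 50):
        gg = nx.gnp_random_graph(n, p, seed=s)
        if gg.number_of_edges() > 0:
            return Graph(gg.edges(), nodes=gg.nodes())
    raise RuntimeError("could not draw a non-empty graph")
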