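import itertools

import networkx as nx
import numpy as np
import pytest

from netpharm import GODag, Network


@pytest.fixture
def path4() -> Network:
    """Path a-b-c-d: diameter 3, the worked proximity fixture."""
    return Network([("a", "b"), ("b", "c"), ("c", "d")])


@pytest.fixture
def two_cliques() -> Network:
    """Two 5-cliques joined by a single bridge edge."""
    edges = (
        list(itertools.combinations(["A1", "A2", "A3", "A4", "A5"], 2))
        + list(itertools.combinations(["B1", "B2", "B3", "B4", "B5"], 2))
        + [("A1", "B1")]
    )
    return Network(edges)


@pytest.fixture
def chain_dag() -> GODag:
    """Three-term is_a chain: root <- A <- B."""
    return GODag(
        namespace={"GO:0000001": "BP", "GO:0000002": "BP", "GO:0000003": "BP"},
        parents={
            "GO:0000001": (),
            "GO:0000002": (("GO:0000001", "is_a"),),
            "GO:0000003": (("GO:0000002", "is_a"),),
        },
    )


def random_connected_graph(n: int, p: float, seed: int) -> Network:
    """Seeded G(n, p) restricted to its largest component."""
    g = nx.gnp_random_graph(n, p, seed=seed)
    comp = max(nx.connected_components(g), key=len)
    g = g.subgraph(comp)
    return Network(((f"N{a:03d}", f"N{b:03d}") for a, b in g.edges))


def rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
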