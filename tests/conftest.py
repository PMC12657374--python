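import networkx as nx
import pytest

from herbprox.core import InteractomeGraph, load_catalog
from herbprox.synthdata import SyntheticScenario, generate_scenario


@pytest.fixture(scope="session")
def path_graph():
    """The 5-node path v1-v2-v3-v4-v5 used by the worked distance examples."""
    g = nx.path_graph([f"v{i}" for i in range(1, 6)])
    return InteractomeGraph(graph=g, lcc_flag=True)


@pytest.fixture(scope="session")
def path_catalog():
    """Small catalog on the path graph: three ingredients, one disease.

    I1 targets the disease genes exactly, I2 sits one hop away, I3 at the
    far end of the path.
    """
    return load_catalog(
        formula_herb=[("F1", "H1"), ("F1", "H2")],
        herb_ingredient=[("H1", "I1"), ("H1", "I2"), ("H2", "I3")],
        ingredient_target=[("I1", "v4"), ("I1", "v5"), ("I2", "v3"), ("I3", "v1")],
        disease_target=[("D1", "v4"), ("D1", "v5")],
    )


@pytest.fixture(scope="session")
def default_scenario():
    """The default synthetic study scenario (seeded), shared across tests."""
    catalog, graph, truth = generate_scenario(SyntheticScenario(seed=0))
    return catalog, graph, truth


def random_connected_graph(rng, n_max=40):
    """Random connected graph for oracle-equivalence checks."""
    n = int(rng.integers(4, n_max + 1))
    p = float(rng.uniform(0.08, 0.4))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    if not nx.is_connected(g):
        comps = list(nx.connected_components(g))
        for a, b in zip(comps, comps[1:]):
            g.add_edge(min(a), min(b))
    return nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})


def random_target_sets(rng, graph, k=2):
    nodes = sorted(graph.nodes)
    sets = []
    for _ in range(k):
        size = int(rng.integers(1, min(6, len(nodes)) + 1))
        sets.append(frozenset(rng.choice(nodes, size=size, replace=False).tolist()))
    return sets
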