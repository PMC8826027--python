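"""Shared fixtures: small named graphs and tiny synthetic datasets."""

import itertools

import networkx as nx
import numpy as np
import pytest

from netfactor import SyntheticSpec, generate_dataset


def clique(prefix: str, n: int) -> nx.Graph:
    g = nx.complete_graph(n)
    return nx.relabel_nodes(g, {i: f"{prefix}{i}" for i in g})


@pytest.fixture
def k5_with_isolates() -> nx.Graph:
    g = clique("A", 5)
    g.add_nodes_from(["I1", "I2", "I3"])
    return g


@pytest.fixture
def bridged_k4s() -> nx.Graph:
    g = nx.compose(clique("a", 4), clique("b", 4))
    g.add_edge("a0", "b0")
    return g


@pytest.fixture
def bridged_k5s() -> nx.Graph:
    g = nx.Graph()
    for i, j in itertools.combinations(range(5), 2):
        g.add_edge(f"g{i}", f"g{j}")
        g.add_edge(f"g{i + 5}", f"g{j + 5}")
    g.add_edge("g4", "g5")
    return g


@pytest.fixture
def shared_vertex_k4s() -> nx.Graph:
    g = nx.Graph()
    for trio in ("abc", "def"):
        for u, v in itertools.combinations(trio, 2):
            g.add_edge(u, v)
        for u in trio:
            g.add_edge("s", u)
    return g


@pytest.fixture
def star6() -> nx.Graph:
    g = nx.star_graph(6)
    return nx.relabel_nodes(g, {i: f"n{i}" for i in g})


@pytest.fixture
def path8() -> nx.Graph:
    g = nx.path_graph(8)
    return nx.relabel_nodes(g, {i: f"v{i}" for i in g})


@pytest.fixture
def k4_with_pendants() -> nx.Graph:
    g = clique("c", 4)
    for pendant in ("p1", "p2"):
        for target in ("c0", "c1", "c2"):
            g.add_edge(pendant, target)
    return g


@pytest.fixture
def tiny_dataset():
    """Small planted-complex dataset for fast training tests."""
    spec = SyntheticSpec(
        n_genes=24, n_complexes=3, complex_size_range=(4, 6),
        overlap_fraction=0.0, p_in=1.0, p_out=0.0,
        n_samples=60, n_classes=2, seed=7,
    )
    return generate_dataset(spec)


def connected_subsets(graph: nx.Graph, min_size: int = 1):
    """All connected induced vertex subsets of a graph with <= ~12 nodes."""
    nodes = sorted(graph.nodes)
    for r in range(min_size, len(nodes) + 1):
        for subset in itertools.combinations(nodes, r):
            sub = graph.subgraph(subset)
            if r == 1 or nx.is_connected(sub):
                yield frozenset(subset)


def subgraph_density(graph: nx.Graph, nodes) -> float:
    sub = graph.subgraph(nodes)
    n = sub.number_of_nodes()
    if n <= 1:
        return 1.0
    return 2.0 * sub.number_of_edges() / (n * (n - 1))


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
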