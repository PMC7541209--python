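import sys
from pathlib import Path

import networkx as nx
import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from netpharm.network import INTERACTOR, TARGET, ProteinNetwork


def make_net(edges, targets=(), extra_nodes=()):
    """Build a ProteinNetwork from edge pairs and a target-id collection."""
    g = nx.Graph()
    g.add_edges_from(edges)
    g.add_nodes_from(extra_nodes)
    targets = set(targets)
    for n in g.nodes:
        g.nodes[n]["role"] = TARGET if n in targets else INTERACTOR
    return ProteinNetwork(graph=g)


@pytest.fixture
def path_net():
    """Path A-B-C."""
    return make_net([("A", "B"), ("B", "C")])


@pytest.fixture
def triangle_net():
    return make_net([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def star_net():
    """Star with center C and four leaves."""
    return make_net([("C", f"L{i}") for i in range(1, 5)])


@pytest.fixture
def barbell_net():
    """Two K4s joined by a single bridge edge."""
    g = nx.Graph()
    left = [f"a{i}" for i in range(4)]
    right = [f"b{i}" for i in range(4)]
    for block in (left, right):
        for i in range(4):
            for j in range(i + 1, 4):
                g.add_edge(block[i], block[j])
    g.add_edge(left[0], right[0])
    for n in g.nodes:
        g.nodes[n]["role"] = INTERACTOR
    return ProteinNetwork(graph=g)


def random_connected_net(n, p, seed):
    """Seeded G(n, p) conditioned on connectedness."""
    for attempt in range(200):
        g = nx.gnp_random_graph(n, p, seed=seed * 1000 + attempt)
        if g.number_of_nodes() and nx.is_connected(g):
            g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})
            for node in g.nodes:
                g.nodes[node]["role"] = INTERACTOR
            return ProteinNetwork(graph=g)
    raise RuntimeError("no connected graph found")


def connected_atlas_nets(max_nodes=6):
    """Every connected graph with 2..max_nodes nodes from the graph atlas."""
    nets = []
    for g in nx.graph_atlas_g()[1:]:
        if 2 <= g.number_of_nodes() <= max_nodes and nx.is_connected(g):
            h = nx.relabel_nodes(g, {i: f"N{i}" for i in g.nodes})
            for node in h.nodes:
                h.nodes[node]["role"] = INTERACTOR
            nets.append(ProteinNetwork(graph=h))
    return nets


@pytest.fixture(scope="session")
def atlas_nets():
    return connected_atlas_nets(6)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
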