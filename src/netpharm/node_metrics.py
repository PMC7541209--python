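"""Node topological attributes: degree and five centrality-type measures.

Six per-node attributes are tabulated for the true and false networks:
degree, closeness centrality (component-scaled Wasserman-Faust form),
eigenvector centrality (power iteration on the adjacency matrix),
shortest-path betweenness (Brandes, normalized), local clustering
coefficient, and eccentricity (per connected component).
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

from .network import ProteinNetwork

logger = logging.getLogger(__name__)

TRUE_NET = "TRUE_NET"
FALSE_NET = "FALSE_NET"

NODE_ATTRIBUTES = (
    "degree",
    "closeness",
    "eigenvector",
    "betweenness",
    "clustering_coefficient",
    "eccentricity",
)


def degree_all(net: ProteinNetwork) -> dict[str, int]:
    return dict(net.graph.degree())


def closeness_all(net: ProteinNetwork) -> dict[str, float]:
    """Component-scaled normalized closeness.

    For node u in a component of n_c nodes within a graph of N nodes:
    ((n_c - 1)/(N - 1)) * ((n_c - 1) / sum of distances from u within its
    component); isolated nodes get 0. This keeps values in [0, 1] and
    comparable on the typically disconnected pruned/false networks.
    """
    return nx.closeness_centrality(net.graph, wf_improved=True)


class PowerIterationError(RuntimeError):
    """Eigenvector power iteration failed to converge."""


def _power_iteration(adj: np.ndarray, tol: float, max_iter: int) -> np.ndarray:
    # iterate on A + I: same eigenvectors, but the principal eigenvalue is
    # strictly dominant even on bipartite components (spectrum ±lambda)
    n = adj.shape[0]
    shifted = adj + np.eye(n)
    x = np.full(n, 1.0 / np.sqrt(n))
    for _ in range(max_iter):
        y = shifted @ x
        norm = np.linalg.norm(y)
        if norm == 0:  # nilpotent adjacency cannot occur for a graph with an edge
            raise PowerIterationError("zero iterate in power iteration")
        y /= norm
        if np.max(np.abs(y - x)) < tol:
            return np.abs(y)
        x = y
    raise PowerIterationError(
        f"power iteration did not converge within max_iter={max_iter}"
    )


def eigenvector_all(
    net: ProteinNetwork, tol: float = 1e-8, max_iter: int = 1000
) -> dict[str, float]:
    """Principal adjacency eigenvector, entries >= 0, Euclidean norm 1.

    On disconnected graphs each component with an edge is iterated
    separately; the component with the largest principal eigenvalue carries
    the eigenvector and all other nodes get 0. A (numerically) degenerate
    principal eigenvalue across components is resolved in favour of the
    largest component, with a logged warning.
    """
    g = net.graph
    if g.number_of_edges() < 1:
        raise ValueError("eigenvector centrality requires at least one edge")
    components = [sorted(c) for c in nx.connected_components(g)]
    results = []  # (eigenvalue, size, nodes, vector)
    for comp in components:
        if len(comp) < 2:
            continue
        adj = nx.to_numpy_array(g, nodelist=comp)
        vec = _power_iteration(adj, tol, max_iter)
        eigval = float(vec @ adj @ vec)
        results.append((eigval, len(comp), comp, vec))
    top = max(r[0] for r in results)
    winners = [r for r in results if r[0] >= top - 10 * tol]
    if len(winners) > 1:
        logger.warning(
            "principal eigenvalue degenerate across %d components; "
            "assigning the eigenvector to the largest component",
            len(winners),
        )
    winners.sort(key=lambda r: (-r[1], r[2][0]))
    _, _, comp, vec = winners[0]
    out = {n: 0.0 for n in g.nodes}
    vec = vec / np.linalg.norm(vec)
    for node, value in zip(comp, vec):
        out[node] = float(value)
    return out


def betweenness_all(net: ProteinNetwork) -> dict[str, float]:
    """Brandes shortest-path betweenness, endpoints excluded, normalized by (N-1)(N-2)/2."""
    return nx.betweenness_centrality(net.graph, normalized=True)


def clustering_coefficient_all(net: ProteinNetwork) -> dict[str, float]:
    """Local clustering coefficient; nodes of degree < 2 get 0."""
    return nx.clustering(net.graph)


def eccentricity_all(net: ProteinNetwork) -> dict[str, int]:
    """Max shortest-path distance within the node's own component; isolated -> 0."""
    g = net.graph
    out: dict[str, int] = {}
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        out.update(nx.eccentricity(sub))
    return out


def node_attribute_table(net: ProteinNetwork, origin: str) -> pd.DataFrame:
    """One row per node with all six attributes, labeled with *origin*."""
    if origin not in (TRUE_NET, FALSE_NET):
        raise ValueError(f"unknown origin {origin!r}")
    g = net.graph
    if g.number_of_nodes() == 0:
        return pd.DataFrame(columns=["node", "origin", *NODE_ATTRIBUTES])
    deg = degree_all(net)
    clo = closeness_all(net)
    if g.number_of_edges() >= 1:
        eig = eigenvector_all(net)
    else:
        eig = {n: 0.0 for n in g.nodes}
    bet = betweenness_all(net)
    clu = clustering_coefficient_all(net)
    ecc = eccentricity_all(net)
    rows = [
        {
            "node": n,
            "origin": origin,
            "degree": deg[n],
            "closeness": clo[n],
            "eigenvector": eig[n],
            "betweenness": bet[n],
            "clustering_coefficient": clu[n],
            "eccentricity": ecc[n],
        }
        for n in sorted(g.nodes)
    ]
    return pd.DataFrame(rows, columns=["node", "origin", *NODE_ATTRIBUTES])


def write_node_scores(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g", lineterminator="\n")
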