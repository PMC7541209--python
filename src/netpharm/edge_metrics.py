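"""Link-prediction scores on protein pairs.

Four topological pair statistics — Jaccard coefficient, preferential
attachment, common-neighbour count and resource-allocation index — computed
for true edges and for false (non-)edges alike on the *true* network's
topology, the standard link-prediction convention (a false pair contributes
no edge of its own).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .network import ProteinNetwork, edge_key

TRUE_EDGE = "TRUE_EDGE"
FALSE_EDGE = "FALSE_EDGE"

EDGE_ATTRIBUTES = (
    "jaccard",
    "preferential_attachment",
    "common_neighbors",
    "resource_allocation",
)


def _neighbors(net: ProteinNetwork, pair: tuple[str, str]) -> tuple[set, set]:
    g = net.graph
    u, v = pair
    for x in (u, v):
        if x not in g:
            raise KeyError(f"node {x!r} not in network")
    # simple graph: neighbourhoods never contain the node itself
    return set(g.adj[u]) - {v}, set(g.adj[v]) - {u}


def jaccard_score(net: ProteinNetwork, pair: tuple[str, str]) -> float:
    """|N(u) ∩ N(v)| / |N(u) ∪ N(v)|, endpoints excluded; 0 on empty union."""
    nu, nv = _neighbors(net, pair)
    union = nu | nv
    if not union:
        return 0.0
    return len(nu & nv) / len(union)


def preferential_attachment(net: ProteinNetwork, pair: tuple[str, str]) -> int:
    """deg(u) * deg(v)."""
    u, v = pair
    g = net.graph
    for x in (u, v):
        if x not in g:
            raise KeyError(f"node {x!r} not in network")
    return g.degree[u] * g.degree[v]


def common_neighbors(net: ProteinNetwork, pair: tuple[str, str]) -> int:
    """|N(u) ∩ N(v)|."""
    nu, nv = _neighbors(net, pair)
    return len(nu & nv)


def resource_allocation(net: ProteinNetwork, pair: tuple[str, str]) -> float:
    """Sum over common neighbours z of 1/deg(z); 0 with no common neighbour.

    A common neighbour is adjacent to both endpoints, so deg(z) >= 2 > 0 and
    the division is always defined (asserted, not guarded).
    """
    nu, nv = _neighbors(net, pair)
    g = net.graph
    total = 0.0
    for z in nu & nv:
        assert g.degree[z] > 0
        total += 1.0 / g.degree[z]
    return total


def score_edge_set(
    net: ProteinNetwork,
    pairs: Iterable[tuple[str, str]],
    origin: str,
) -> pd.DataFrame:
    """Score a set of node pairs on *net*; one row per pair.

    Returns a DataFrame with columns protein_a, protein_b, origin,
    string_score (the STRING combined score for TRUE_EDGE pairs carrying one,
    else NA) and the four link-prediction attributes.
    """
    if origin not in (TRUE_EDGE, FALSE_EDGE):
        raise ValueError(f"unknown origin {origin!r}")
    rows = []
    g = net.graph
    for u, v in pairs:
        a, b = edge_key(u, v)
        string_score = None
        if origin == TRUE_EDGE and g.has_edge(a, b):
            string_score = g.edges[a, b].get("string_score")
        rows.append(
            {
                "protein_a": a,
                "protein_b": b,
                "origin": origin,
                "string_score": string_score,
                "jaccard": jaccard_score(net, (a, b)),
                "preferential_attachment": preferential_attachment(net, (a, b)),
                "common_neighbors": common_neighbors(net, (a, b)),
                "resource_allocation": resource_allocation(net, (a, b)),
            }
        )
    columns = ["protein_a", "protein_b", "origin", "string_score", *EDGE_ATTRIBUTES]
    return pd.DataFrame(rows, columns=columns)


def score_networks(
    true_net: ProteinNetwork, false_net: ProteinNetwork
) -> pd.DataFrame:
    """Score true edges and false edges (both on the true topology) into one table."""
    true_rows = score_edge_set(true_net, true_net.edges, TRUE_EDGE)
    false_rows = score_edge_set(true_net, false_net.edges, FALSE_EDGE)
    return pd.concat([true_rows, false_rows], ignore_index=True)


def write_edge_scores(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g", lineterminator="\n")
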