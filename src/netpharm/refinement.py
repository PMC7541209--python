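"""Percentile-based network sparsification.

The true PPIN is pruned with the discriminating attributes: edges whose
Jaccard score lies strictly above the 75th percentile of the true-network
edge distribution are removed, then nodes whose closeness centrality lies
strictly below the 25th percentile, then nodes left isolated. Both cutoffs
are computed once on the un-pruned network.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import ProteinNetwork, edge_key


def percentile(values, q: float) -> float:
    """Linear-interpolation percentile (rank (q/100)*(n-1) on sorted values)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot take a percentile of an empty sequence")
    if not 0 < q < 100:
        raise ValueError("q must lie strictly between 0 and 100")
    return float(np.percentile(arr, q, method="linear"))


@dataclass
class PruningThresholds:
    """Attribute names, percentiles, and the cutoff values computed from them."""

    edge_attribute: str = "jaccard"
    edge_percentile: float = 75.0
    node_attribute: str = "closeness"
    node_percentile: float = 25.0
    edge_cutoff_value: float = field(default=float("nan"))
    node_cutoff_value: float = field(default=float("nan"))
    #: remove edges ABOVE the edge percentile (as published); False inverts
    #: the edge rule for sensitivity analysis.
    remove_high_edges: bool = True

    def compute_cutoffs(
        self, edge_scores: pd.DataFrame, node_rows: pd.DataFrame
    ) -> "PruningThresholds":
        """Return a copy with cutoff values set from the given distributions."""
        out = copy.copy(self)
        out.edge_cutoff_value = percentile(
            edge_scores[self.edge_attribute], self.edge_percentile
        )
        out.node_cutoff_value = percentile(
            node_rows[self.node_attribute], self.node_percentile
        )
        return out


@dataclass(frozen=True)
class RemovalReport:
    edges_removed_by_score: int
    nodes_removed_by_closeness: int
    nodes_removed_isolated: int


def prune_network(
    net: ProteinNetwork,
    edge_scores: pd.DataFrame,
    node_rows: pd.DataFrame,
    thresholds: PruningThresholds,
) -> tuple[ProteinNetwork, RemovalReport]:
    """Sparsify *net* by the edge rule, then the node rule, then isolation cleanup.

    Edge rule: drop edges with ``edge_attribute`` strictly greater than
    ``edge_cutoff_value`` (strictly smaller when ``remove_high_edges`` is
    False). Node rule: drop nodes with ``node_attribute`` strictly less than
    ``node_cutoff_value``, with their incident edges. Finally drop nodes of
    degree 0. Cutoffs must already be computed (see
    :meth:`PruningThresholds.compute_cutoffs`); *edge_scores* must cover
    every edge of *net* and *node_rows* every node.
    """
    th = thresholds
    if np.isnan(th.edge_cutoff_value) or np.isnan(th.node_cutoff_value):
        th = th.compute_cutoffs(edge_scores, node_rows)

    edge_attr = {
        edge_key(a, b): float(v)
        for a, b, v in zip(
            edge_scores["protein_a"], edge_scores["protein_b"],
            edge_scores[th.edge_attribute],
        )
    }
    node_attr = dict(
        zip(node_rows["node"], node_rows[th.node_attribute].astype(float))
    )
    missing_edges = [e for e in net.edges if e not in edge_attr]
    missing_nodes = [n for n in net.nodes if n not in node_attr]
    if missing_edges or missing_nodes:
        raise ValueError(
            f"attribute coverage gaps: {len(missing_edges)} edge(s) "
            f"{missing_edges[:5]}, {len(missing_nodes)} node(s) {missing_nodes[:5]}"
        )

    g = net.graph.copy()
    if th.remove_high_edges:
        bad_edges = [e for e in net.edges if edge_attr[e] > th.edge_cutoff_value]
    else:
        bad_edges = [e for e in net.edges if edge_attr[e] < th.edge_cutoff_value]
    g.remove_edges_from(bad_edges)

    bad_nodes = [n for n in g.nodes if node_attr[n] < th.node_cutoff_value]
    g.remove_nodes_from(bad_nodes)

    isolated = [n for n, d in g.degree() if d == 0]
    g.remove_nodes_from(isolated)

    report = RemovalReport(
        edges_removed_by_score=len(bad_edges),
        nodes_removed_by_closeness=len(bad_nodes),
        nodes_removed_isolated=len(isolated),
    )
    return ProteinNetwork(graph=g), report
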