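"""Protein-interaction network model and STRING-dialect I/O.

A true PPIN is built from scored interaction records (STRING ``protein.links``
dialect) with a small set of *target* proteins embedded among their
interactors; a false PPIN over the same nodes collects target-incident
protein pairs with no recorded interaction, serving as the negative contrast
class for downstream attribute selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, NamedTuple, Sequence, Union

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

TARGET = "TARGET"
INTERACTOR = "INTERACTOR"

#: sentinel for "every available false edge"
ALL = "all"


class InteractionRecord(NamedTuple):
    """One scored undirected protein pair, as read from a STRING-style file."""

    protein_a: str
    protein_b: str
    combined_score: int


def edge_key(u: str, v: str) -> tuple[str, str]:
    """Canonical (sorted) form of an unordered protein pair."""
    return (u, v) if u <= v else (v, u)


@dataclass
class ProteinNetwork:
    """Undirected simple graph whose nodes carry a TARGET/INTERACTOR role.

    Thin wrapper over :class:`networkx.Graph`; the ``role`` node attribute
    partitions the node set. ``unmapped_targets`` records target identifiers
    that appeared in the target list but in no interaction record.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)
    unmapped_targets: frozenset[str] = frozenset()

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return [edge_key(u, v) for u, v in self.graph.edges]

    def role(self, node: str) -> str:
        return self.graph.nodes[node]["role"]

    def target_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["role"] == TARGET]

    def number_of_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()

    def has_edge(self, u: str, v: str) -> bool:
        return self.graph.has_edge(u, v)

    def _check_invariants(self) -> None:
        g = self.graph
        assert not any(u == v for u, v in g.edges), "self-loop present"
        assert all(d.get("role") in (TARGET, INTERACTOR) for _, d in g.nodes(data=True))


class StringLinksParseError(ValueError):
    """Malformed line in a STRING-dialect links file."""


def _validate_record(a: str, b: str, score: int, lineno: int | None = None) -> None:
    where = f" (line {lineno})" if lineno is not None else ""
    if a == b:
        raise StringLinksParseError(f"self-interaction {a!r}-{b!r} rejected{where}")
    if not (0 < score <= 1000):
        raise StringLinksParseError(
            f"combined_score {score} outside (0, 1000]{where}"
        )
    if not a or not b or any(ch.isspace() for ch in a + b):
        raise StringLinksParseError(f"invalid protein identifier{where}")


def read_string_links(path: Union[str, Path]) -> list[InteractionRecord]:
    """Read a STRING ``protein.links``-dialect file.

    Three whitespace-separated columns: protein1, protein2, combined_score
    (integer in (0, 1000]). An optional single header line (non-numeric third
    token) is skipped. Duplicate pairs in either orientation collapse to a
    single record keeping the maximum score, preserving first-seen order.
    """
    path = Path(path)
    best: dict[tuple[str, str], InteractionRecord] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 3:
                raise StringLinksParseError(
                    f"{path}: line {lineno}: expected >=3 fields, got {len(fields)}"
                )
            a, b, raw = fields[0], fields[1], fields[2]
            try:
                score = int(raw)
            except ValueError:
                if lineno == 1:  # header line
                    continue
                raise StringLinksParseError(
                    f"{path}: line {lineno}: non-integer score {raw!r}"
                ) from None
            _validate_record(a, b, score, lineno)
            key = edge_key(a, b)
            prev = best.get(key)
            if prev is None:
                best[key] = InteractionRecord(*key, score)
            elif score > prev.combined_score:
                best[key] = InteractionRecord(*key, score)
    return list(best.values())


def filter_by_score(
    records: Sequence[InteractionRecord], min_score: int = 300
) -> list[InteractionRecord]:
    """Keep records with ``combined_score >= min_score`` (order preserved).

    The default threshold 300 keeps a pair scoring exactly 300 ("below 300"
    is removed).
    """
    if min_score < 0:
        raise ValueError("min_score must be >= 0")
    return [r for r in records if r.combined_score >= min_score]


def build_true_ppin(
    records: Sequence[InteractionRecord], targets: Iterable[str]
) -> ProteinNetwork:
    """Build the true PPIN: one node per protein in *records*, one edge per pair.

    Nodes named in *targets* get role TARGET, all others INTERACTOR. Target
    identifiers appearing in no record are excluded from the graph and
    reported on ``unmapped_targets`` (and logged).
    """
    records = list(records)
    if not records:
        raise ValueError("cannot build a network from an empty record sequence")
    targets = set(targets)
    g = nx.Graph()
    for rec in records:
        g.add_edge(rec.protein_a, rec.protein_b, string_score=rec.combined_score)
    for n in g.nodes:
        g.nodes[n]["role"] = TARGET if n in targets else INTERACTOR
    unmapped = frozenset(targets - set(g.nodes))
    if unmapped:
        logger.warning(
            "%d target identifier(s) not present in any interaction record: %s",
            len(unmapped),
            ", ".join(sorted(unmapped)[:10]),
        )
    net = ProteinNetwork(graph=g, unmapped_targets=unmapped)
    net._check_invariants()
    return net


def iter_target_nonedges(true_net: ProteinNetwork):
    """Yield (in canonical order, sorted) every non-edge with >=1 TARGET endpoint."""
    g = true_net.graph
    targets = sorted(true_net.target_nodes())
    target_set = set(targets)
    seen: set[tuple[str, str]] = set()
    for u in targets:
        adj = set(g.adj[u])
        for v in sorted(g.nodes):
            if v == u or v in adj:
                continue
            key = edge_key(u, v)
            if v in target_set:
                if key in seen:
                    continue  # target-target pair, count once
                seen.add(key)
            yield key


def build_false_ppin(
    true_net: ProteinNetwork,
    n_false_edges: Union[int, Literal["all"]] = ALL,
    seed: int = 0,
) -> ProteinNetwork:
    """Build the false PPIN: same node set, edges drawn from target-incident non-edges.

    With ``n_false_edges=ALL`` every pair (u, v) with u a TARGET node and
    (u, v) not an edge of *true_net* is included; otherwise that many pairs
    are sampled uniformly without replacement with the given seed.
    """
    if true_net.number_of_nodes() < 2:
        raise ValueError("true network must have at least 2 nodes")
    nonedges = list(iter_target_nonedges(true_net))
    if n_false_edges == ALL:
        chosen = nonedges
    else:
        n = int(n_false_edges)
        if n > len(nonedges):
            raise ValueError(
                f"requested {n} false edges but only {len(nonedges)} "
                f"target-incident non-edges exist"
            )
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(nonedges), size=n, replace=False)
        chosen = [nonedges[i] for i in sorted(idx)]
    g = nx.Graph()
    for node in true_net.graph.nodes:
        g.add_node(node, role=true_net.role(node))
    g.add_edges_from(chosen)
    net = ProteinNetwork(graph=g)
    net._check_invariants()
    return net


def read_target_list(path: Union[str, Path]) -> set[str]:
    """Read a one-identifier-per-line target-protein list (blank lines ignored)."""
    with Path(path).open() as fh:
        return {line.strip() for line in fh if line.strip()}


def write_edge_list(net: ProteinNetwork, path: Union[str, Path]) -> None:
    """Write a TSV edge list: protein_a, protein_b, role_a, role_b (canonical order)."""
    path = Path(path)
    with path.open("w", newline="\n") as fh:
        fh.write("protein_a\tprotein_b\trole_a\trole_b\n")
        for u, v in sorted(net.edges):
            fh.write(f"{u}\t{v}\t{net.role(u)}\t{net.role(v)}\n")


def read_edge_list(path: Union[str, Path]) -> ProteinNetwork:
    """Read back an edge list written by :func:`write_edge_list`."""
    path = Path(path)
    g = nx.Graph()
    with path.open() as fh:
        header = fh.readline()
        if not header.startswith("protein_a"):
            raise StringLinksParseError(f"{path}: missing edge-list header")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise StringLinksParseError(
                    f"{path}: line {lineno}: expected 4 columns, got {len(parts)}"
                )
            u, v, ru, rv = parts
            g.add_node(u, role=ru)
            g.add_node(v, role=rv)
            g.add_edge(u, v)
    if g.number_of_nodes() == 0:
        logger.warning("%s: edge list contains no edges; returning empty network", path)
    return ProteinNetwork(graph=g)
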