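"""Synthetic inputs for the pipeline, with full seed control.

A planted-partition (stochastic block) network stands in for the
STRING-derived interactome: communities give true edges the elevated
shared-neighbour statistics (Jaccard, resource allocation) that real
interaction networks show, target proteins are spread evenly across
communities, and integer interaction scores span the STRING range with a
configurable upward shift for within-community edges. Pathway gene sets are
sampled either uniformly (background) or concentrated in a home community
(planted), optionally with one pathway planted across three communities so
cross-cluster overlap reporting can be exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .enrichment import GeneSetCollection, write_gmt
from .network import InteractionRecord, edge_key
from .node_metrics import FALSE_NET, NODE_ATTRIBUTES, TRUE_NET


@dataclass(frozen=True)
class SyntheticNetworkSpec:
    """Planted-partition network with integer STRING-style edge scores.

    Defaults give 6 communities of 20 nodes with 30 targets — small enough
    for desk-scale runs, structured enough for MCL to recover the blocks.
    ``score_bias`` shifts within-community scores upward (clipped to
    ``score_range``), producing the weak positive score-topology correlation
    regime observed in real interactomes.
    """

    n_targets: int = 30
    n_interactors: int = 90
    n_communities: int = 6
    p_in: float = 0.6
    p_out: float = 0.02
    score_range: tuple[int, int] = (150, 999)
    score_bias: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p_out < self.p_in <= 1:
            raise ValueError("need 0 <= p_out < p_in <= 1")
        if self.score_range[0] >= self.score_range[1]:
            raise ValueError("score_range low must be < high")
        if self.n_communities < 1:
            raise ValueError("n_communities must be >= 1")


@dataclass(frozen=True)
class SyntheticPathwaySpec:
    """Pathway gene sets with planted, community-concentrated pathways."""

    n_pathways: int = 40
    pathway_size_range: tuple[int, int] = (8, 15)
    n_planted: int = 4
    planted_fraction: float = 1.0
    shared_planted: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.planted_fraction <= 1:
            raise ValueError("planted_fraction must lie in (0, 1]")
        if self.n_planted > self.n_pathways:
            raise ValueError("n_planted cannot exceed n_pathways")


def generate_network(
    spec: SyntheticNetworkSpec,
) -> tuple[list[InteractionRecord], set[str], dict[str, int]]:
    """Generate scored interaction records, a target set, and community labels.

    Nodes are split into ``n_communities`` near-equal blocks; each
    within-community pair receives an edge with probability ``p_in``,
    between-community pairs with ``p_out``. Targets are drawn evenly across
    communities. Scores are uniform integers on ``score_range``; within-
    community edges get ``score_bias`` added, clipped to the range.
    """
    rng = np.random.default_rng(spec.seed)
    n_nodes = spec.n_targets + spec.n_interactors
    nodes = [f"P{i:04d}" for i in range(n_nodes)]
    labels = {nodes[i]: i % spec.n_communities for i in range(n_nodes)}

    # targets drawn evenly: round-robin over communities
    by_comm: dict[int, list[str]] = {c: [] for c in range(spec.n_communities)}
    for node, c in labels.items():
        by_comm[c].append(node)
    targets: set[str] = set()
    comm_cycle = list(range(spec.n_communities))
    pools = {c: list(rng.permutation(members)) for c, members in by_comm.items()}
    ci = 0
    while len(targets) < spec.n_targets:
        c = comm_cycle[ci % spec.n_communities]
        if pools[c]:
            targets.add(pools[c].pop())
        ci += 1

    lo, hi = spec.score_range
    records: list[InteractionRecord] = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            u, v = nodes[i], nodes[j]
            within = labels[u] == labels[v]
            p = spec.p_in if within else spec.p_out
            if rng.random() >= p:
                continue
            score = int(rng.integers(lo, hi + 1))
            if within:
                score = min(hi, score + spec.score_bias)
            a, b = edge_key(u, v)
            records.append(InteractionRecord(a, b, score))
    if not records:
        raise ValueError("spec yields an edgeless network; raise p_in/p_out or sizes")
    return records, targets, labels


def generate_pathways(
    community_labels: dict[str, int],
    spec: SyntheticPathwaySpec,
    records: Optional[list[InteractionRecord]] = None,
) -> tuple[GeneSetCollection, dict]:
    """Generate GMT-style gene sets plus a ground-truth manifest.

    Background pathways sample members uniformly from all nodes; planted
    pathways draw ``planted_fraction`` of their members from a home
    community. With ``shared_planted`` the first planted pathway instead
    spans three distinct communities, covering ``planted_fraction`` of each.
    When *records* are supplied, the spanning pathway's home communities are
    the three with the most between-community interactions — shared pathways
    belong to the modules that communicate, which also makes them the
    modules best retained downstream; otherwise homes are drawn at random.
    """
    rng = np.random.default_rng(spec.seed)
    nodes = sorted(community_labels)
    communities = sorted(set(community_labels.values()))
    if not nodes:
        raise ValueError("community labels are empty")
    by_comm: dict[int, list[str]] = {c: [] for c in communities}
    for node, c in community_labels.items():
        by_comm[c].append(node)

    lo, hi = spec.pathway_size_range
    if hi > len(nodes):
        raise ValueError("pathway size exceeds the universe")
    pathways: dict[str, tuple[str, frozenset[str]]] = {}
    manifest: dict = {"planted": {}, "shared": None, "background": []}

    for i in range(spec.n_pathways):
        pid = f"PW{i:03d}"
        size = int(rng.integers(lo, hi + 1))
        if i < spec.n_planted:
            if i == 0 and spec.shared_planted and len(communities) >= 3:
                # module-spanning pathway: covers planted_fraction of EACH of
                # three home communities, so it stays overrepresented in all
                # three corresponding clusters downstream
                if records is not None:
                    cross = {c: 0 for c in communities}
                    for r in records:
                        ca = community_labels.get(r.protein_a)
                        cb = community_labels.get(r.protein_b)
                        if ca is not None and cb is not None and ca != cb:
                            cross[ca] += 1
                            cross[cb] += 1
                    homes = sorted(communities, key=lambda c: (-cross[c], c))[:3]
                else:
                    homes = [communities[int(c)] for c in
                             rng.choice(len(communities), size=3, replace=False)]
                picked = set()
                for h in homes:
                    n_home = max(1, round(spec.planted_fraction * len(by_comm[h])))
                    picked |= set(rng.choice(by_comm[h], size=n_home, replace=False))
                manifest["shared"] = {"pathway_id": pid, "communities": sorted(homes)}
            else:
                home = communities[i % len(communities)]
                pool = by_comm[home]
                n_home = min(len(pool), max(1, round(spec.planted_fraction * size)))
                picked = set(rng.choice(pool, size=n_home, replace=False))
                rest = [n for n in nodes if n not in picked]
                if size > n_home:
                    picked |= set(rng.choice(rest, size=size - n_home, replace=False))
                manifest["planted"][pid] = {"community": home}
            name = f"planted pathway {i}"
        else:
            picked = set(rng.choice(nodes, size=size, replace=False))
            name = f"background pathway {i}"
            manifest["background"].append(pid)
        pathways[pid] = (name, frozenset(picked))

    collection = GeneSetCollection(pathways=pathways, universe=frozenset(nodes))
    return collection, manifest


def generate_false_attribute_fixture(
    n: int, separation: float, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired node-attribute tables where only closeness separates the origins.

    The closeness column of the TRUE_NET table is shifted upward by
    ``separation`` standard deviations; every other column is exchangeable
    between origins. Intended as a controlled fixture for attribute-ranking
    checks.
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    rng = np.random.default_rng(seed)

    def table(origin: str, shift: float) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "node": [f"{origin[0]}{i:04d}" for i in range(n)],
                "origin": origin,
                "degree": rng.integers(1, 30, size=n),
                "closeness": rng.normal(0.4 + shift, 0.1, size=n),
                "eigenvector": rng.uniform(0, 1, size=n),
                "betweenness": rng.uniform(0, 0.3, size=n),
                "clustering_coefficient": rng.uniform(0, 1, size=n),
                "eccentricity": rng.integers(1, 8, size=n),
            }
        )
        return df[["node", "origin", *NODE_ATTRIBUTES]]

    true_rows = table(TRUE_NET, separation * 0.1)
    false_rows = table(FALSE_NET, 0.0)
    return true_rows, false_rows


def write_links_file(records: list[InteractionRecord], path: Union[str, Path]) -> None:
    """Write records in the STRING ``protein.links`` dialect (with header)."""
    with Path(path).open("w", newline="\n") as fh:
        fh.write("protein1 protein2 combined_score\n")
        for r in records:
            fh.write(f"{r.protein_a} {r.protein_b} {r.combined_score}\n")


def write_target_list(targets: set[str], path: Union[str, Path]) -> None:
    with Path(path).open("w", newline="\n") as fh:
        for t in sorted(targets):
            fh.write(t + "\n")


def write_inputs(
    outdir: Union[str, Path],
    net_spec: SyntheticNetworkSpec = SyntheticNetworkSpec(),
    pw_spec: SyntheticPathwaySpec = SyntheticPathwaySpec(),
) -> dict:
    """Write links file, target list, GMT and manifest under *outdir*.

    Returns the manifest (also written as JSON) with community labels.
    """
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, targets, labels = generate_network(net_spec)
    gene_sets, manifest = generate_pathways(labels, pw_spec, records=records)
    write_links_file(records, outdir / "links.txt")
    write_target_list(targets, outdir / "targets.txt")
    write_gmt(gene_sets, outdir / "pathways.gmt")
    manifest = dict(manifest)
    manifest["community_labels"] = labels
    manifest["targets"] = sorted(targets)
    with (outdir / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
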