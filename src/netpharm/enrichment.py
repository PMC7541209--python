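"""Pathway overrepresentation analysis for protein clusters.

Each cluster is tested against every pathway it overlaps with a one-sided
upper-tail hypergeometric test (the classic overrepresentation test), with
Benjamini-Hochberg FDR control across the whole family of (cluster, pathway)
tests. Pathways significant in two or more clusters are summarized
separately — shared pathways across clusters are the signature of a
synergistic, multi-module mechanism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .mcl import Partition

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Pathway gene sets plus the background universe.

    ``pathways`` maps pathway id -> (display name, member gene set). The
    universe defaults to the union of all members; a user-supplied universe
    overrides it (members outside it are dropped).
    """

    pathways: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.universe:
            u: set[str] = set()
            for _, members in self.pathways.values():
                u |= members
            self.universe = frozenset(u)
        for pid, (name, members) in list(self.pathways.items()):
            if not members:
                raise ValueError(f"pathway {pid!r} has no members")
            clipped = frozenset(members) & self.universe
            if clipped != members:
                logger.warning(
                    "pathway %s: %d member(s) outside the universe dropped",
                    pid, len(members - clipped),
                )
                if not clipped:
                    raise ValueError(f"pathway {pid!r} has no members in the universe")
                self.pathways[pid] = (name, clipped)


def read_gmt(
    path: Union[str, Path], universe: Optional[Sequence[str]] = None
) -> GeneSetCollection:
    """Read GMT gene sets (tab-separated: id, description, members...)."""
    path = Path(path)
    pathways: dict[str, tuple[str, frozenset[str]]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT lines need >=3 tab-separated fields"
                )
            pid, name, members = parts[0], parts[1], frozenset(parts[2:]) - {""}
            pathways[pid] = (name, members)
    if not pathways:
        raise ValueError(f"{path}: no pathways found")
    return GeneSetCollection(
        pathways=pathways,
        universe=frozenset(universe) if universe is not None else frozenset(),
    )


def write_gmt(collection: GeneSetCollection, path: Union[str, Path]) -> None:
    with Path(path).open("w", newline="\n") as fh:
        for pid in sorted(collection.pathways):
            name, members = collection.pathways[pid]
            fh.write("\t".join([pid, name, *sorted(members)]) + "\n")


def hypergeom_overrep_p(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric P(X >= k), X ~ Hypergeom(N, K, n).

    N: universe size, K: pathway size, n: cluster genes in the universe,
    k: overlap count.
    """
    if not (0 <= k <= min(n, K) and 0 <= n <= N and 0 <= K <= N):
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values (order-preserving)."""
    p = list(p_values)
    if not p:
        return []
    if any(not 0 <= v <= 1 for v in p):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


@dataclass
class OverlapSummary:
    """Which clusters each pathway is significant in, plus shared-pathway lists."""

    pathway_clusters: dict[str, set[int]]
    shared_2plus: list[str]
    shared_3plus: list[str]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "pathway_id": pid,
                "cluster_ids": ",".join(str(c) for c in sorted(cids)),
                "n_clusters": len(cids),
            }
            for pid, cids in sorted(self.pathway_clusters.items())
        ]
        return pd.DataFrame(
            rows, columns=["pathway_id", "cluster_ids", "n_clusters"]
        ).sort_values(
            ["n_clusters", "pathway_id"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)


def enrich_clusters(
    partition: Partition,
    gene_sets: GeneSetCollection,
    alpha: float = 0.05,
    id_map: Optional[Mapping[str, str]] = None,
    min_cluster_size: int = 1,
) -> tuple[pd.DataFrame, OverlapSummary]:
    """Overrepresentation test of every cluster against every overlapping pathway.

    Protein ids are mapped through *id_map* when given; cluster members
    absent from the universe are dropped (logged). Only (cluster, pathway)
    pairs with overlap k >= 1 are tested; BH-FDR is applied across the whole
    family and a pathway is significant in a cluster iff q <= alpha.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    N = len(gene_sets.universe)
    records = []
    n_dropped = 0
    any_in_universe = False
    for cid, block in enumerate(partition.clusters, start=1):
        if len(block) < min_cluster_size:
            continue
        genes = {id_map.get(p, p) for p in block} if id_map else set(block)
        in_universe = genes & gene_sets.universe
        n_dropped += len(genes) - len(in_universe)
        if not in_universe:
            continue
        any_in_universe = True
        n = len(in_universe)
        for pid in sorted(gene_sets.pathways):
            name, members = gene_sets.pathways[pid]
            k = len(in_universe & members)
            if k < 1:
                continue
            records.append(
                {
                    "cluster_id": cid,
                    "pathway_id": pid,
                    "pathway_name": name,
                    "k": k,
                    "n": n,
                    "K": len(members),
                    "N": N,
                    "p_value": hypergeom_overrep_p(k, n, len(members), N),
                }
            )
    if not any_in_universe:
        raise ValueError("no cluster member maps into the gene-set universe")
    if n_dropped:
        logger.info("%d cluster member(s) absent from the universe dropped", n_dropped)
    table = pd.DataFrame(
        records,
        columns=[
            "cluster_id", "pathway_id", "pathway_name",
            "k", "n", "K", "N", "p_value",
        ],
    )
    table["q_value"] = bh_fdr(table["p_value"].tolist()) if len(table) else []
    table["significant"] = table["q_value"] <= alpha

    pathway_clusters: dict[str, set[int]] = {}
    for _, row in table[table["significant"]].iterrows():
        pathway_clusters.setdefault(row["pathway_id"], set()).add(int(row["cluster_id"]))
    shared2 = sorted(p for p, c in pathway_clusters.items() if len(c) >= 2)
    shared3 = sorted(p for p, c in pathway_clusters.items() if len(c) >= 3)
    summary = OverlapSummary(pathway_clusters, shared2, shared3)
    table = table.sort_values(
        ["cluster_id", "q_value", "pathway_id"], kind="mergesort"
    ).reset_index(drop=True)
    return table, summary
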