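"""Pipeline orchestration: one config, staged execution, machine-readable report.

Stages run in the published order — build the true/false networks, score
edges and nodes, select discriminating attributes, prune, cluster with MCL,
and test pathway overrepresentation — writing every intermediate artifact to
the output directory and returning a :class:`RunReport` whose counts are
recomputable from the stage files. One global seed feeds per-stage derived
seeds (CRC32 of ``stage:seed``) so each stage is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from . import __version__
from .edge_metrics import TRUE_EDGE, FALSE_EDGE, score_edge_set, write_edge_scores
from .enrichment import enrich_clusters, read_gmt
from .mcl import MclParams, cluster_network
from .network import (
    ALL,
    ProteinNetwork,
    build_false_ppin,
    build_true_ppin,
    filter_by_score,
    read_string_links,
    read_target_list,
    write_edge_list,
)
from .node_metrics import TRUE_NET, FALSE_NET, node_attribute_table, write_node_scores
from .refinement import PruningThresholds, prune_network
from .selection import rank_edge_attributes, rank_node_attributes

logger = logging.getLogger(__name__)


def derived_seed(stage: str, global_seed: int) -> int:
    """Stable per-stage seed below 2**31."""
    return zlib.crc32(f"{stage}:{global_seed}".encode()) % (2**31)


@dataclass
class PipelineConfig:
    """Inputs, thresholds and seeds for a full run; defaults follow the study."""

    links_file: str = ""
    targets_file: str = ""
    gmt_file: str = ""
    id_map_file: Optional[str] = None
    universe_file: Optional[str] = None
    output_dir: str = "run_output"
    min_score: int = 300
    false_edges: Union[int, str, None] = None  # None -> balanced (= |true edges|)
    edge_percentile: float = 75.0
    node_percentile: float = 25.0
    mcl: MclParams = field(default_factory=MclParams)
    alpha: float = 0.05
    n_folds: int = 5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        mcl_raw = raw.pop("mcl", {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if mcl_raw:
            cfg.mcl = MclParams(**mcl_raw)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class RunReport:
    """Per-stage counts plus the chosen thresholds and attribute winners."""

    config: dict
    version: str
    n_records_raw: int = 0
    n_records_filtered: int = 0
    n_nodes: int = 0
    n_edges: int = 0
    n_targets_in_network: int = 0
    n_unmapped_targets: int = 0
    n_false_edges: int = 0
    best_edge_attribute: Optional[str] = None
    best_node_attribute: Optional[str] = None
    node_roc_auc: float = 0.0
    edge_cutoff_value: float = 0.0
    node_cutoff_value: float = 0.0
    edges_removed_by_score: int = 0
    nodes_removed_by_closeness: int = 0
    nodes_removed_isolated: int = 0
    n_pruned_nodes: int = 0
    n_pruned_edges: int = 0
    n_clusters: int = 0
    mcl_converged: bool = True
    n_enrichment_tests: int = 0
    n_significant: int = 0
    n_pathways_shared_2plus: int = 0
    n_pathways_shared_3plus: int = 0
    shared_3plus: list = field(default_factory=list)
    timestamp: str = ""

    def to_json(self, path: Union[str, Path]) -> None:
        with Path(path).open("w", newline="\n") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute build -> attributes -> selection -> prune -> cluster -> enrich."""
    import datetime

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=config.to_dict(), version=__version__)

    def stage(name):
        logger.info("stage %s", name)
        return name

    # ---- build ----
    name = stage("build")
    try:
        records = read_string_links(config.links_file)
        report.n_records_raw = len(records)
        records = filter_by_score(records, config.min_score)
        report.n_records_filtered = len(records)
        targets = read_target_list(config.targets_file)
        true_net = build_true_ppin(records, targets)
        n_false = config.false_edges
        if n_false is None:
            n_false = true_net.number_of_edges()
        elif isinstance(n_false, str) and n_false.lower() == ALL:
            n_false = ALL
        false_net = build_false_ppin(
            true_net, n_false, seed=derived_seed("false_ppin", config.seed)
        )
        write_edge_list(true_net, outdir / "edges.tsv")
        write_edge_list(false_net, outdir / "false_edges.tsv")
        report.n_nodes = true_net.number_of_nodes()
        report.n_edges = true_net.number_of_edges()
        report.n_targets_in_network = len(true_net.target_nodes())
        report.n_unmapped_targets = len(true_net.unmapped_targets)
        report.n_false_edges = false_net.number_of_edges()
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError(name, exc) from exc

    # ---- attributes ----
    name = stage("attributes")
    try:
        true_scores = score_edge_set(true_net, true_net.edges, TRUE_EDGE)
        false_scores = score_edge_set(true_net, false_net.edges, FALSE_EDGE)
        import pandas as pd

        edge_scores = pd.concat([true_scores, false_scores], ignore_index=True)
        write_edge_scores(edge_scores, outdir / "edge_scores.tsv")
        true_nodes = node_attribute_table(true_net, TRUE_NET)
        false_nodes = node_attribute_table(false_net, FALSE_NET)
        node_scores = pd.concat([true_nodes, false_nodes], ignore_index=True)
        write_node_scores(node_scores, outdir / "node_scores.tsv")
    except Exception as exc:  # noqa: BLE001
        raise StageError(name, exc) from exc

    # ---- selection ----
    name = stage("selection")
    try:
        edge_ranking = rank_edge_attributes(true_scores, false_scores)
        node_report = rank_node_attributes(
            true_nodes, false_nodes, n_folds=config.n_folds,
            seed=derived_seed("selection", config.seed),
        )
        edge_ranking.to_frame().to_csv(
            outdir / "selection.tsv", sep="\t", index=False, lineterminator="\n"
        )
        node_report.table.to_csv(
            outdir / "node_importances.tsv", sep="\t", index=False, lineterminator="\n"
        )
        report.best_edge_attribute = edge_ranking.best_attribute
        report.best_node_attribute = node_report.best_attribute
        report.node_roc_auc = node_report.roc_auc
    except Exception as exc:  # noqa: BLE001
        raise StageError(name, exc) from exc

    # ---- prune ----
    name = stage("prune")
    try:
        thresholds = PruningThresholds(
            edge_percentile=config.edge_percentile,
            node_percentile=config.node_percentile,
        ).compute_cutoffs(true_scores, true_nodes)
        pruned, removal = prune_network(true_net, true_scores, true_nodes, thresholds)
        write_edge_list(pruned, outdir / "pruned.tsv")
        report.edge_cutoff_value = thresholds.edge_cutoff_value
        report.node_cutoff_value = thresholds.node_cutoff_value
        report.edges_removed_by_score = removal.edges_removed_by_score
        report.nodes_removed_by_closeness = removal.nodes_removed_by_closeness
        report.nodes_removed_isolated = removal.nodes_removed_isolated
        report.n_pruned_nodes = pruned.number_of_nodes()
        report.n_pruned_edges = pruned.number_of_edges()
    except Exception as exc:  # noqa: BLE001
        raise StageError(name, exc) from exc

    # ---- cluster ----
    name = stage("cluster")
    try:
        partition = cluster_network(pruned, config.mcl)
        report.n_clusters = partition.n_clusters()
        report.mcl_converged = partition.converged
        with (outdir / "clusters.tsv").open("w", newline="\n") as fh:
            fh.write("node\tcluster_id\trole\n")
            for node in sorted(partition.assignment):
                fh.write(
                    f"{node}\t{partition.assignment[node]}\t{pruned.role(node)}\n"
                )
        with (outdir / "cluster_summary.tsv").open("w", newline="\n") as fh:
            fh.write("cluster_id\tsize\tn_target_proteins\n")
            for cid, block in enumerate(partition.clusters, start=1):
                n_tp = sum(1 for n in block if pruned.role(n) == "TARGET")
                fh.write(f"{cid}\t{len(block)}\t{n_tp}\n")
    except Exception as exc:  # noqa: BLE001
        raise StageError(name, exc) from exc

    # ---- enrich ----
    name = stage("enrich")
    try:
        universe = None
        if config.universe_file:
            universe = sorted(read_target_list(config.universe_file))
        gene_sets = read_gmt(config.gmt_file, universe=universe)
        id_map = None
        if config.id_map_file:
            id_map = {}
            with Path(config.id_map_file).open() as fh:
                for line in fh:
                    if line.strip():
                        a, b = line.split()[:2]
                        id_map[a] = b
        table, summary = enrich_clusters(
            partition, gene_sets, alpha=config.alpha, id_map=id_map
        )
        table.to_csv(
            outdir / "enrichment.tsv", sep="\t", index=False,
            float_format="%.6g", lineterminator="\n",
        )
        summary.to_frame().to_csv(
            outdir / "overlap.tsv", sep="\t", index=False, lineterminator="\n"
        )
        report.n_enrichment_tests = len(table)
        report.n_significant = int(table["significant"].sum())
        report.n_pathways_shared_2plus = len(summary.shared_2plus)
        report.n_pathways_shared_3plus = len(summary.shared_3plus)
        report.shared_3plus = list(summary.shared_3plus)
    except Exception as exc:  # noqa: BLE001
        raise StageError(name, exc) from exc

    report.timestamp = datetime.datetime.now().isoformat()
    report.to_json(outdir / "report.json")
    return report
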