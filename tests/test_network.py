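"""Network construction and STRING-dialect I/O."""

import itertools

import numpy as np
import pytest

from netpharm.network import (
    ALL,
    InteractionRecord,
    StringLinksParseError,
    build_false_ppin,
    build_true_ppin,
    filter_by_score,
    iter_target_nonedges,
    read_edge_list,
    read_string_links,
    read_target_list,
    write_edge_list,
)
from netpharm.synthetic import write_links_file

from conftest import make_net


def write_lines(tmp_path, lines, name="links.txt"):
    p = tmp_path / name
    p.write_text("\n".join(lines) + "\n")
    return p


class TestReadStringLinks:
    def test_duplicate_orientations_collapse_to_max_score(self, tmp_path):
        p = write_lines(tmp_path, ["P1 P2 400", "P2 P1 350"])
        records = read_string_links(p)
        assert records == [InteractionRecord("P1", "P2", 400)]

    def test_self_interaction_rejected(self, tmp_path):
        p = write_lines(tmp_path, ["P1 P1 500"])
        with pytest.raises(StringLinksParseError, match="self-interaction"):
            read_string_links(p)

    def test_header_line_skipped(self, tmp_path):
        p = write_lines(tmp_path, ["protein1 protein2 combined_score", "P1 P2 700"])
        assert read_string_links(p) == [InteractionRecord("P1", "P2", 700)]

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = write_lines(tmp_path, ["P1 P2 700", "P3 P4"])
        with pytest.raises(StringLinksParseError, match="line 2"):
            read_string_links(p)

    @pytest.mark.parametrize("score", [0, -5, 1001])
    def test_score_outside_range_rejected(self, tmp_path, score):
        p = write_lines(tmp_path, [f"P1 P2 {score}"])
        with pytest.raises(StringLinksParseError):
            read_string_links(p)

    def test_round_trip_through_links_file(self, tmp_path):
        records = [
            InteractionRecord("P1", "P2", 400),
            InteractionRecord("P1", "P3", 999),
            InteractionRecord("P2", "P3", 150),
            InteractionRecord("P3", "P4", 301),
            InteractionRecord("P4", "P5", 875),
        ]
        path = tmp_path / "rt.txt"
        write_links_file(records, path)
        assert set(read_string_links(path)) == set(records)


class TestFilterByScore:
    def test_threshold_is_inclusive(self):
        records = [InteractionRecord("A", "B", s) for s in (250, 300, 350)]
        kept = filter_by_score(records, 300)
        assert [r.combined_score for r in kept] == [300, 350]

    def test_zero_threshold_keeps_everything(self):
        records = [InteractionRecord("A", "B", s) for s in (150, 999)]
        assert filter_by_score(records, 0) == records

    def test_matches_brute_force_recount(self, rng):
        scores = rng.integers(150, 1000, size=1000)
        records = [
            InteractionRecord(f"A{i}", f"B{i}", int(s)) for i, s in enumerate(scores)
        ]
        kept = filter_by_score(records, 300)
        assert len(kept) == sum(1 for s in scores if s >= 300)

    def test_idempotent(self, rng):
        records = [
            InteractionRecord(f"A{i}", f"B{i}", int(s))
            for i, s in enumerate(rng.integers(150, 1000, size=200))
        ]
        once = filter_by_score(records, 300)
        assert filter_by_score(once, 300) == once


class TestBuildTruePpin:
    def test_direct_construction(self):
        records = [
            InteractionRecord("T1", "I1", 400),
            InteractionRecord("T1", "I2", 400),
            InteractionRecord("I1", "I2", 400),
        ]
        net = build_true_ppin(records, {"T1"})
        assert net.number_of_nodes() == 3
        assert net.number_of_edges() == 3
        assert net.target_nodes() == ["T1"]

    def test_unmapped_target_reported_not_fatal(self):
        records = [InteractionRecord("I1", "I2", 400)]
        net = build_true_ppin(records, {"T9"})
        assert net.target_nodes() == []
        assert net.unmapped_targets == {"T9"}
        assert "T9" not in net.nodes

    def test_empty_records_error(self):
        with pytest.raises(ValueError):
            build_true_ppin([], {"T1"})

    def test_counts_match_set_based_recount(self, rng):
        names = [f"P{i}" for i in range(60)]
        pairs = set()
        while len(pairs) < 500:
            i, j = rng.integers(0, 60, size=2)
            if i != j:
                pairs.add(tuple(sorted((names[i], names[j]))))
        records = [InteractionRecord(a, b, 500) for a, b in sorted(pairs)]
        net = build_true_ppin(records, set(names[:5]))
        distinct = {p for r in records for p in (r.protein_a, r.protein_b)}
        assert net.number_of_nodes() == len(distinct)
        assert net.number_of_edges() == len(pairs)


class TestBuildFalsePpin:
    def test_triangle_has_no_false_edges(self):
        net = make_net([("T1", "I1"), ("T1", "I2"), ("I1", "I2")], targets={"T1"})
        false_net = build_false_ppin(net, ALL)
        assert false_net.number_of_edges() == 0
        assert set(false_net.nodes) == set(net.nodes)

    def test_path_yields_single_false_edge(self):
        net = make_net([("T1", "I1"), ("I1", "I2")], targets={"T1"})
        false_net = build_false_ppin(net, ALL)
        assert false_net.edges == [("I2", "T1")]

    def test_seeded_sampling_reproducible_and_disjoint_from_true(self):
        net = make_net(
            [(f"N{i}", f"N{(i + k) % 50}") for i in range(50) for k in (1, 2)],
            targets={f"N{i}" for i in range(10)},
        )
        a = build_false_ppin(net, 100, seed=7)
        b = build_false_ppin(net, 100, seed=7)
        assert a.edges == b.edges
        assert len(a.edges) == 100
        for u, v in a.edges:
            assert not net.has_edge(u, v)

    def test_oversampling_error_states_maximum(self):
        net = make_net([("T1", "I1"), ("I1", "I2")], targets={"T1"})
        with pytest.raises(ValueError, match="1"):
            build_false_ppin(net, 5)

    @pytest.mark.parametrize("n_nodes,n_targets,seed", [(5, 1, 0), (6, 2, 1), (8, 3, 2)])
    def test_complement_arithmetic_on_small_graphs(self, n_nodes, n_targets, seed):
        """|false ALL| + |target-incident true edges| = all target-incident pairs."""
        rng = np.random.default_rng(seed)
        nodes = [f"N{i}" for i in range(n_nodes)]
        edges = [
            (a, b)
            for a, b in itertools.combinations(nodes, 2)
            if rng.random() < 0.4
        ]
        targets = set(nodes[:n_targets])
        net = make_net(edges, targets=targets, extra_nodes=nodes)
        false_net = build_false_ppin(net, ALL)
        target_incident_true = sum(
            1 for u, v in net.edges if u in targets or v in targets
        )
        total_target_pairs = sum(
            1
            for a, b in itertools.combinations(nodes, 2)
            if a in targets or b in targets
        )
        assert false_net.number_of_edges() + target_incident_true == total_target_pairs
        assert not set(false_net.edges) & set(net.edges)

    def test_nonedges_all_touch_a_target(self):
        net = make_net([("T1", "I1"), ("I1", "I2"), ("I2", "I3")], targets={"T1"})
        targets = set(net.target_nodes())
        for u, v in iter_target_nonedges(net):
            assert u in targets or v in targets


class TestEdgeListIO:
    def test_triangle_writes_three_lines(self, triangle_net, tmp_path):
        p = tmp_path / "e.tsv"
        write_edge_list(triangle_net, p)
        lines = p.read_text().splitlines()
        assert len(lines) == 4  # header + 3 edges

    def test_empty_graph_round_trip_warns(self, tmp_path, caplog):
        p = tmp_path / "e.tsv"
        write_edge_list(make_net([]), p)
        assert p.read_text().startswith("protein_a")
        with caplog.at_level("WARNING"):
            back = read_edge_list(p)
        assert back.number_of_nodes() == 0

    def test_random_graph_round_trip(self, rng, tmp_path):
        pairs = set()
        while len(pairs) < 200:
            i, j = rng.integers(0, 40, size=2)
            if i != j:
                pairs.add(tuple(sorted((f"P{i}", f"P{j}"))))
        net = make_net(sorted(pairs), targets={"P0", "P1"})
        p = tmp_path / "e.tsv"
        write_edge_list(net, p)
        back = read_edge_list(p)
        assert set(back.nodes) == set(net.nodes)
        assert set(back.edges) == set(net.edges)
        assert back.role("P0") == "TARGET"


def test_read_target_list_skips_blanks(tmp_path):
    p = tmp_path / "t.txt"
    p.write_text("T1\n\nT2\n  \nT3\n")
    assert read_target_list(p) == {"T1", "T2", "T3"}
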