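"""Markov clustering: transition matrices, convergence, partitions, oracle agreement."""

import itertools

import networkx as nx
import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

import netpharm.mcl as mcl_mod
from netpharm.mcl import (
    MarkovClustering,
    MclParams,
    build_transition_matrix,
    cluster_network,
    extract_clusters,
    mcl_iterate,
)

from conftest import make_net, random_connected_net
from oracles import mcl_oracle


def partitions_agree(partition, oracle_blocks):
    nodes = sorted(partition.assignment)
    mine = [partition.assignment[n] for n in nodes]
    lookup = {n: i for i, block in enumerate(oracle_blocks) for n in block}
    theirs = [lookup[n] for n in nodes]
    return adjusted_rand_score(mine, theirs)


class TestTransitionMatrix:
    def test_single_edge_columns_half_half(self):
        net = make_net([("A", "B")])
        m, nodes = build_transition_matrix(net, 1.0)
        assert nodes == ["A", "B"]
        assert np.allclose(m, 0.5)

    def test_isolated_node_unit_column(self):
        net = make_net([("A", "B")], extra_nodes=["X"])
        m, nodes = build_transition_matrix(net, 1.0)
        j = nodes.index("X")
        col = m[:, j]
        assert col[j] == pytest.approx(1.0)
        assert col.sum() == pytest.approx(1.0)

    def test_random_graph_columns_stochastic(self):
        net = random_connected_net(20, 0.2, seed=2)
        m, _ = build_transition_matrix(net, 1.0)
        assert np.allclose(m.sum(axis=0), 1.0, atol=1e-12)

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            build_transition_matrix(make_net([]), 1.0)


class TestIterate:
    def test_identity_is_fixed_point(self):
        m = np.eye(3)
        out, converged = mcl_iterate(m, MclParams())
        assert converged
        assert np.allclose(out, np.eye(3))

    def test_single_edge_converges_to_uniform(self):
        net = make_net([("A", "B")])
        m, _ = build_transition_matrix(net, 1.0)
        # hand iteration: [[.5,.5],[.5,.5]] is already idempotent under
        # expansion and inflation, so it is returned unchanged
        out, converged = mcl_iterate(m, MclParams())
        assert converged
        assert np.allclose(out, 0.5)

    def test_columns_stay_stochastic_each_round(self):
        net = random_connected_net(15, 0.3, seed=4)
        m, _ = build_transition_matrix(net, 1.0)
        params = MclParams(max_iterations=1, convergence_tol=0.0)
        for _ in range(6):
            m, _ = mcl_iterate(m, params)
            assert np.allclose(m.sum(axis=0), 1.0, atol=1e-9)

    def test_nonconvergence_flagged(self, caplog):
        net = random_connected_net(15, 0.3, seed=4)
        m, _ = build_transition_matrix(net, 1.0)
        with caplog.at_level("WARNING"):
            _, converged = mcl_iterate(m, MclParams(max_iterations=1))
        assert not converged
        assert "did not converge" in caplog.text


class TestExtractClusters:
    def test_identity_gives_singletons(self):
        nodes = ["A", "B", "C", "D"]
        partition = extract_clusters(np.eye(4), nodes)
        assert partition.n_clusters() == 4
        assert all(len(b) == 1 for b in partition.clusters)

    def test_k5_single_cluster(self):
        k5 = make_net(list(itertools.combinations("ABCDE", 2)))
        partition = cluster_network(k5)
        assert partition.n_clusters() == 1
        assert partition.clusters[0] == frozenset("ABCDE")

    def test_two_triangles_joined_by_edge(self):
        net = make_net(
            [("A", "B"), ("B", "C"), ("A", "C"),
             ("X", "Y"), ("Y", "Z"), ("X", "Z"), ("C", "X")]
        )
        partition = cluster_network(net)
        assert partition.n_clusters() == 2
        assert frozenset("ABC") in partition.clusters
        assert frozenset("XYZ") in partition.clusters

    def test_barbell_two_clusters_of_four(self, barbell_net):
        partition = cluster_network(barbell_net)
        assert partition.n_clusters() == 2
        assert sorted(len(b) for b in partition.clusters) == [4, 4]

    def test_edgeless_graph_all_singletons(self):
        net = make_net([], extra_nodes=[f"N{i}" for i in range(4)])
        partition = cluster_network(net)
        assert partition.n_clusters() == 4

    def test_cluster_ids_ordered_by_size_then_member(self):
        net = make_net(
            [("A", "B"), ("B", "C"), ("A", "C"), ("X", "Y")],
        )
        partition = cluster_network(net)
        assert partition.clusters[0] == frozenset("ABC")
        assert partition.assignment["A"] == 1


class TestOracleAgreement:
    def test_two_disjoint_triangles(self):
        net = make_net(
            [("A", "B"), ("B", "C"), ("A", "C"), ("X", "Y"), ("Y", "Z"), ("X", "Z")]
        )
        partition = cluster_network(net)
        blocks = mcl_oracle(net.edges, net.nodes)
        assert partitions_agree(partition, blocks) == 1.0

    def test_fifty_seeded_random_graphs_identical(self):
        """Dual-route check: partitions match the naive implementation exactly."""
        rng = np.random.default_rng(99)
        for trial in range(50):
            n = int(rng.integers(8, 30))
            p = float(rng.uniform(0.15, 0.5))
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31)))
            g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})
            for node in g.nodes:
                g.nodes[node]["role"] = "INTERACTOR"
            from netpharm.network import ProteinNetwork

            net = ProteinNetwork(graph=g)
            partition = cluster_network(net)
            blocks = mcl_oracle(net.edges, net.nodes)
            assert partitions_agree(partition, blocks) == 1.0, f"trial {trial}"


class TestPlantedPartition:
    def test_six_blocks_recovered(self):
        from netpharm.network import build_true_ppin
        from netpharm.synthetic import SyntheticNetworkSpec, generate_network

        spec = SyntheticNetworkSpec(seed=0)
        records, targets, labels = generate_network(spec)
        net = build_true_ppin(records, targets)
        partition = cluster_network(net)
        assert partition.n_clusters() == 6
        nodes = sorted(net.nodes)
        ari = adjusted_rand_score(
            [labels[n] for n in nodes], [partition.assignment[n] for n in nodes]
        )
        assert ari >= 0.9

    def test_cluster_count_monotone_in_inflation(self):
        from netpharm.network import build_true_ppin
        from netpharm.synthetic import SyntheticNetworkSpec, generate_network

        records, targets, _ = generate_network(SyntheticNetworkSpec(seed=3))
        net = build_true_ppin(records, targets)
        counts = [
            cluster_network(net, MclParams(inflation=i)).n_clusters()
            for i in (1.4, 2.0, 4.0)
        ]
        assert counts[0] <= counts[1] <= counts[2]


class TestDenseSparseContract:
    def test_identical_partitions_both_representations(self, monkeypatch):
        net = random_connected_net(25, 0.2, seed=8)
        dense = cluster_network(net)
        monkeypatch.setattr(mcl_mod, "_DENSE_LIMIT", 0)  # force sparse path
        sparse = cluster_network(net)
        assert dense.assignment == sparse.assignment


class TestPartitionInvariants:
    def test_blocks_disjoint_and_cover(self):
        for seed in range(5):
            net = random_connected_net(20, 0.25, seed=seed)
            partition = cluster_network(net)
            union = set()
            for block in partition.clusters:
                assert not union & set(block)
                union |= set(block)
            assert union == set(net.nodes)


class TestEstimatorSurface:
    def test_fit_predict_labels(self, barbell_net):
        est = MarkovClustering()
        labels = est.fit_predict(barbell_net)
        assert est.n_clusters_ == 2
        assert len(labels) == 8
        assert est.nodes_ == sorted(barbell_net.nodes)

    def test_get_set_params_round_trip(self):
        est = MarkovClustering()
        params = est.get_params()
        assert params["inflation"] == 2.0
        est.set_params(inflation=3.0)
        assert est.get_params()["inflation"] == 3.0
        with pytest.raises(ValueError):
            est.set_params(bogus=1)

    def test_accepts_plain_networkx_graph(self):
        g = nx.complete_graph(4)
        est = MarkovClustering().fit(g)
        assert est.n_clusters_ == 1
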