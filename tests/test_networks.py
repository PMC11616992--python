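"""Residue networks: DC/BC against brute-force oracles, statistics, export."""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pytest

from lspnet.errors import ComparisonError, ConfigError, DegenerateInputError
from lspnet.lsp import AdjacencyMatrix
from lspnet.networks import (
    CentralityProfile,
    ResidueNetwork,
    adjacency_to_network,
    betweenness_centrality,
    centrality_stats,
    degree_centrality,
    delta_centrality,
    export_network,
)
from lspnet.synthetic import generate_toy_graph

from oracles import brute_force_betweenness, brute_force_degree


def _adj(matrix, window_id=0):
    m = np.asarray(matrix, float)
    return AdjacencyMatrix(
        window_id=window_id,
        labels=tuple(f"n{i}" for i in range(len(m))),
        matrix=m,
        match_counts=(m * 100).astype(int),
        n_comparisons=100,
    )


def _random_weighted_network(rng, n, p=0.6):
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                m[i, j] = m[j, i] = rng.uniform(0.05, 1.0)
    return adjacency_to_network(_adj(m))


class TestToyGraphCentralities:
    def test_hub_star_degree_eight(self):
        net = generate_toy_graph("hub_star", n_leaves=8)
        dc = degree_centrality(net)
        assert dc[0] == 8.0
        assert set(dc[1:]) == {1.0}

    def test_bridged_cliques_bridge_betweenness_six(self):
        net = generate_toy_graph("bridged_cliques", k1=3, k2=3)
        bc = betweenness_centrality(net, "unit")
        assert bc[0] == pytest.approx(6.0)
        assert bc[3] == pytest.approx(6.0)
        assert np.allclose(np.delete(bc, [0, 3]), 0.0)
        # exhaustive path enumeration agrees
        assert np.allclose(bc, brute_force_betweenness(net.graph, lambda w: 1.0))

    def test_three_node_path(self):
        net = generate_toy_graph("path", n=3)
        bc = betweenness_centrality(net, "unit")
        assert list(bc) == [0.0, 1.0, 0.0]

    def test_complete_graph_has_zero_betweenness(self):
        net = generate_toy_graph("complete", n=6)
        assert np.allclose(betweenness_centrality(net, "unit"), 0.0)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ConfigError):
            generate_toy_graph("moebius")


class TestAdjacencyToNetwork:
    def test_threshold_zero_keeps_all_positive_entries(self):
        m = np.ones((4, 4)) - np.eye(4)
        net = adjacency_to_network(_adj(m), 0.0)
        assert net.n_edges == 6

    def test_threshold_one_rejected(self):
        with pytest.raises(ConfigError):
            adjacency_to_network(_adj(np.zeros((3, 3))), 1.0)

    def test_edge_count_matches_brute_force(self):
        rng = np.random.default_rng(0)
        m = rng.uniform(0, 1, (10, 10))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        net = adjacency_to_network(_adj(m), 0.3)
        iu, ju = np.triu_indices(10, 1)
        assert net.n_edges == int((m[iu, ju] > 0.3).sum())
        assert net.n_nodes == 10  # isolated nodes retained


class TestCentralityOracles:
    @pytest.mark.parametrize("seed", range(8))
    def test_degree_equals_row_sums(self, seed):
        rng = np.random.default_rng(seed)
        net = _random_weighted_network(rng, 6)
        assert np.allclose(degree_centrality(net), brute_force_degree(net.graph))

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("transform", ["reciprocal", "unit"])
    def test_betweenness_matches_exhaustive_enumeration(self, seed, transform):
        rng = np.random.default_rng(100 + seed)
        net = _random_weighted_network(rng, rng.integers(4, 9))
        bc = betweenness_centrality(net, transform)
        length = (lambda w: 1.0 / w) if transform == "reciprocal" else (lambda w: 1.0)
        assert np.allclose(bc, brute_force_betweenness(net.graph, length), atol=1e-8)

    def test_unknown_transform_rejected(self):
        net = generate_toy_graph("path", n=3)
        with pytest.raises(ConfigError):
            betweenness_centrality(net, "logistic")

    def test_adding_an_edge_never_decreases_degree(self):
        rng = np.random.default_rng(42)
        net = _random_weighted_network(rng, 7)
        dc0 = degree_centrality(net)
        g = net.graph.copy()
        non_edges = list(nx.non_edges(g))
        if non_edges:
            u, v = non_edges[0]
            g.add_edge(u, v, weight=0.5)
        dc1 = degree_centrality(ResidueNetwork(g, net.labels, 0.0))
        assert np.all(dc1 >= dc0 - 1e-12)

    def test_weight_scaling_scales_dc_and_preserves_bc_order(self):
        rng = np.random.default_rng(43)
        net = _random_weighted_network(rng, 7)
        c = 0.37
        g = net.graph.copy()
        for _, _, data in g.edges(data=True):
            data["weight"] *= c
        scaled = ResidueNetwork(g, net.labels, 0.0)
        assert np.allclose(degree_centrality(scaled), c * degree_centrality(net))
        bc0 = betweenness_centrality(net, "reciprocal")
        bc1 = betweenness_centrality(scaled, "reciprocal")
        assert np.array_equal(np.argsort(bc0, kind="stable"), np.argsort(bc1, kind="stable"))


class TestCentralityStats:
    def _networks(self, matrices):
        return [adjacency_to_network(_adj(m, i)) for i, m in enumerate(matrices)]

    def test_identical_windows_have_zero_se(self):
        m = np.array([[0.0, 0.5, 0.2], [0.5, 0.0, 0.0], [0.2, 0.0, 0.0]])
        profile = centrality_stats(self._networks([m] * 5))
        assert np.allclose(profile.dc_se, 0.0)
        assert np.allclose(profile.bc_se, 0.0)
        assert profile.n_windows == 5

    def test_se_is_sample_sd_over_sqrt_n(self):
        profile = CentralityProfile(
            labels=("a",),
            dc_replicates=np.array([[1.0], [2.0], [3.0], [4.0], [5.0]]),
            bc_replicates=np.zeros((5, 1)),
        )
        assert profile.dc_mean[0] == pytest.approx(3.0)
        assert profile.dc_se[0] == pytest.approx(math.sqrt(2.5) / math.sqrt(5.0))

    def test_single_window_is_an_error(self):
        m = np.array([[0.0, 0.5], [0.5, 0.0]])
        with pytest.raises(DegenerateInputError):
            centrality_stats(self._networks([m]))

    def test_mismatched_node_sets_raise(self):
        nets = [
            adjacency_to_network(_adj(np.zeros((3, 3)))),
            adjacency_to_network(_adj(np.zeros((4, 4)))),
        ]
        with pytest.raises(ComparisonError):
            centrality_stats(nets)


class TestDeltaCentrality:
    def _profile(self, dc, bc):
        dc = np.asarray(dc, float)
        bc = np.asarray(bc, float)
        return CentralityProfile(
            labels=tuple(f"n{i}" for i in range(dc.shape[1])),
            dc_replicates=dc,
            bc_replicates=bc,
        )

    def test_identical_profiles_give_zero_delta(self):
        p = self._profile(np.ones((3, 4)), np.ones((3, 4)))
        delta = delta_centrality(p, p)
        assert np.allclose(delta.delta_dc, 0.0)
        assert np.allclose(delta.delta_bc, 0.0)

    def test_channels_reconstruct_delta_exactly(self):
        rng = np.random.default_rng(1)
        wt = self._profile(rng.normal(5, 2, (5, 6)), rng.normal(20, 5, (5, 6)))
        mut = self._profile(rng.normal(5, 2, (5, 6)), rng.normal(20, 5, (5, 6)))
        delta = delta_centrality(wt, mut)
        assert np.allclose(delta.delta_dc_positive + delta.delta_dc_negative, delta.delta_dc)
        assert np.allclose(delta.delta_bc_positive + delta.delta_bc_negative, delta.delta_bc)
        assert np.all(delta.delta_dc_positive >= 0)
        assert np.all(delta.delta_dc_negative <= 0)


class TestExport:
    def test_gexf_round_trip(self, tmp_path):
        rng = np.random.default_rng(2)
        net = _random_weighted_network(rng, 5)
        profile = centrality_stats(
            [net, net],
        )
        path = export_network(net, profile, tmp_path / "net.gexf", tmp_path / "edges.tsv")
        back = nx.read_gexf(path, node_type=int)
        assert back.number_of_nodes() == net.n_nodes
        assert back.number_of_edges() == net.n_edges
        for u, v, data in net.graph.edges(data=True):
            assert back[u][v]["weight"] == pytest.approx(data["weight"], abs=1e-6)
        for i in range(net.n_nodes):
            assert back.nodes[i]["dc"] == pytest.approx(profile.dc_mean[i], abs=1e-6)
            assert back.nodes[i]["bc"] == pytest.approx(profile.bc_mean[i], abs=1e-6)
        assert (tmp_path / "edges.tsv").read_text().startswith("source\ttarget\tweight")
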