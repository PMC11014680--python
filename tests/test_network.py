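import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import oracles
from mitodnv.io import GeneSet
from mitodnv.network import (
    build_graph,
    centrality_scores,
    connectivity_permutation_test,
    connectivity_statistic,
    consensus_top_k,
    hub_genes,
    rank_by_centrality,
)
from mitodnv.simulate import simulate_ppi


def edge_frame(rows):
    return pd.DataFrame(rows, columns=["GeneA", "GeneB", "CombinedScore"])


class TestBuildGraph:
    def test_strictly_above_threshold(self):
        g = build_graph(
            edge_frame([("a", "b", 601), ("b", "c", 600), ("c", "d", 599)]),
            min_score=600,
        )
        assert set(g.edges) == {("a", "b")}

    def test_duplicate_pairs_collapse(self):
        g = build_graph(edge_frame([("a", "b", 700), ("b", "a", 800)]))
        assert g.number_of_edges() == 1
        assert g["a"]["b"]["score"] == 800

    def test_empty_table(self):
        assert build_graph(edge_frame([])).number_of_nodes() == 0

    def test_self_loops_dropped(self):
        g = build_graph(edge_frame([("a", "a", 900), ("a", "b", 900)]))
        assert set(g.edges) == {("a", "b")}

    def test_score_out_of_range_rejected_with_line(self):
        with pytest.raises(ValueError, match="line 2"):
            build_graph(edge_frame([("a", "b", 700), ("b", "c", 1500)]))


class TestConnectivityStatistic:
    def test_star_graph(self):
        g = nx.star_graph(5)  # hub 0, leaves 1..5
        assert connectivity_statistic(g, {0}, set(range(1, 6))) == 5

    def test_disjoint_components(self):
        g = nx.Graph([("a", "b"), ("c", "d")])
        assert connectivity_statistic(g, {"a", "b"}, {"c", "d"}) == 0

    def test_shared_genes_removed_from_second_set(self):
        g = nx.Graph([("a", "b"), ("b", "c")])
        # b is in both sets: removed from set_b, so only a-b counts via set_a
        assert connectivity_statistic(g, {"a", "b"}, {"b", "c"}) == 1

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(13)
        g = nx.gnp_random_graph(30, 0.2, seed=13)
        nodes = list(g.nodes)
        set_a = set(rng.choice(nodes, 8, replace=False).tolist())
        set_b = set(rng.choice(nodes, 10, replace=False).tolist())
        assert connectivity_statistic(g, set_a, set_b) == oracles.cross_edges_bruteforce(
            list(g.edges), set_a, set_b
        )

    def test_error_when_disjoint_from_graph(self):
        g = nx.Graph([("a", "b")])
        with pytest.raises(ValueError):
            connectivity_statistic(g, {"x"}, {"y"})


class TestConnectivityPermutation:
    def test_complete_graph_all_ties(self):
        # with a universe disjoint from set_b every draw gives the same
        # statistic on a complete graph, so the p-value is exactly 1
        g = nx.complete_graph(6)
        r = connectivity_permutation_test(
            g, {0, 1}, {2, 3}, n_perm=200, seed=4, universe=[0, 1, 4, 5]
        )
        assert r.empirical_p == 1.0

    def test_matches_exhaustive_enumeration_small_graph(self):
        rng = np.random.default_rng(21)
        g = nx.gnp_random_graph(8, 0.4, seed=21)
        nodes = list(g.nodes)
        set_a = {0, 1}
        set_b = {5, 6, 7}
        n_perm = 4000
        r = connectivity_permutation_test(g, set_a, set_b, n_perm=n_perm, seed=2)
        exact = oracles.enumerate_connectivity_p(
            list(g.edges), nodes, 2, set_b, r.observed_links
        )
        # the (+1)/(+1) estimator is slightly conservative; allow 3 MC SDs
        sd = math.sqrt(exact * (1 - exact) / n_perm)
        assert abs(r.empirical_p - exact) <= 3 * sd + 1 / n_perm

    def test_detects_engineered_connectivity(self):
        genes = [f"g{i}" for i in range(60)]
        risk = genes[:8]
        g = simulate_ppi(genes, risk, risk_boost=0.5, seed=7)
        strong = build_graph(
            pd.DataFrame(
                [(u, v, d["score"]) for u, v, d in g.edges(data=True)],
                columns=["GeneA", "GeneB", "CombinedScore"],
            )
        )
        r = connectivity_permutation_test(
            strong, risk[:4], risk[4:], n_perm=10000, seed=7
        )
        assert r.empirical_p <= 0.01

    def test_bit_reproducible(self):
        g = nx.gnp_random_graph(20, 0.3, seed=3)
        a = connectivity_permutation_test(g, {0, 1, 2}, {5, 6}, n_perm=300, seed=11)
        b = connectivity_permutation_test(g, {0, 1, 2}, {5, 6}, n_perm=300, seed=11)
        assert a == b

    def test_p_at_least_one_over_nperm_plus_one(self):
        g = nx.star_graph(10)
        r = connectivity_permutation_test(
            g, {0}, set(range(1, 11)), n_perm=100, seed=1
        )
        assert r.empirical_p >= 1 / 101


class TestCentralities:
    def test_triangle_mcc(self):
        g = nx.complete_graph(3)
        assert centrality_scores(g, "mcc") == {0: 2.0, 1: 2.0, 2: 2.0}

    def test_isolated_node_mcc_zero(self):
        g = nx.Graph()
        g.add_node("lonely")
        g.add_edge("a", "b")
        scores = centrality_scores(g, "mcc")
        assert scores["lonely"] == 0.0
        assert scores["a"] == 1.0  # K2 clique: (2-1)! = 1

    def test_path_degree(self):
        g = nx.path_graph(["a", "b", "c"])
        assert centrality_scores(g, "degree") == {"a": 1.0, "b": 2.0, "c": 1.0}

    def test_betweenness_matches_bruteforce(self):
        g = nx.gnp_random_graph(12, 0.3, seed=5)
        mine = centrality_scores(g, "betweenness")
        oracle = oracles.betweenness_bruteforce(g)
        for v in g.nodes:
            assert mine[v] == pytest.approx(oracle[v], abs=1e-9)

    def test_stress_matches_bruteforce(self):
        g = nx.gnp_random_graph(12, 0.35, seed=8)
        mine = centrality_scores(g, "stress")
        oracle = oracles.stress_bruteforce(g)
        for v in g.nodes:
            assert mine[v] == pytest.approx(oracle[v], abs=1e-9)

    def test_mcc_matches_bruteforce(self):
        g = nx.gnp_random_graph(10, 0.45, seed=2)
        mine = centrality_scores(g, "mcc")
        oracle = oracles.mcc_bruteforce(g)
        assert mine == oracle

    def test_closeness_componentwise(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("x", "y")])
        scores = centrality_scores(g, "closeness")
        assert scores["b"] == pytest.approx(1.0)  # distance 1 to both neighbors
        assert scores["x"] == pytest.approx(1.0)  # its component is a single edge

    def test_eccentricity_disconnected(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("x", "y")])
        scores = centrality_scores(g, "eccentricity")
        assert scores["b"] == 1 and scores["a"] == 2 and scores["x"] == 1

    def test_unknown_method_lists_supported(self):
        with pytest.raises(ValueError, match="degree"):
            centrality_scores(nx.Graph(), "pagerank")


class TestConsensus:
    def test_single_ranking_is_identity(self):
        assert consensus_top_k([["a", "b", "c"]], k=2) == ["a", "b"]

    def test_reversed_rankings_tie_lexicographic(self):
        r1 = ["a", "b", "c", "d"]
        assert consensus_top_k([r1, r1[::-1]], k=4) == ["a", "b", "c", "d"]

    def test_matches_mean_rank_oracle(self):
        rng = np.random.default_rng(15)
        genes = [f"g{i}" for i in range(12)]
        rankings = [list(rng.permutation(genes)) for _ in range(3)]
        assert consensus_top_k(rankings, k=5) == oracles.mean_rank_consensus(rankings, 5)

    def test_hub_genes_on_hub_and_spoke(self):
        g = nx.star_graph(8)
        hubs = hub_genes(g, k=1)
        assert hubs == [0]

    def test_eccentricity_ranking_prefers_center(self):
        g = nx.path_graph(5)  # center node 2
        assert rank_by_centrality(g, "eccentricity")[0] == 2
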