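import math

import networkx as nx
import numpy as np
import pytest

from essprofile.ppi_topology import (
    EPCConfig,
    asp,
    betweenness,
    bottleneck,
    clean_graph,
    closeness,
    clustering_coefficient,
    degree,
    dmnc,
    epc,
    epc_all,
    mnc,
    node_metrics_table,
)
from oracles import brute_centralities


def path_graph(n):
    g = nx.path_graph(n)
    return nx.relabel_nodes(g, {i: chr(ord("a") + i) for i in range(n)})


class TestCleanGraph:
    def test_self_loop_and_reverse_duplicate(self):
        g, rep = clean_graph([("a", "a"), ("a", "b"), ("b", "a")])
        assert set(map(frozenset, g.edges)) == {frozenset(("a", "b"))}
        assert rep.self_loops_removed == 1
        assert rep.duplicate_edges_removed == 1

    def test_empty_input(self):
        g, rep = clean_graph([])
        assert g.number_of_nodes() == 0
        assert rep == type(rep)(0, 0)

    def test_duplicate_count(self):
        edges = [(1, 2), (2, 3), (3, 4), (1, 2), (2, 1), (3, 4),
                 (4, 5), (5, 6), (6, 7), (7, 1)]
        g, rep = clean_graph(edges)
        assert g.number_of_edges() == 7
        assert rep.duplicate_edges_removed == 3

    def test_malformed_entry(self):
        with pytest.raises(ValueError, match="malformed"):
            clean_graph([("a",)])


class TestBasicCentralities:
    def test_path_of_three(self):
        g = path_graph(3)
        assert degree(g, "b") == 2
        assert asp(g, "b") == pytest.approx(1.0)
        assert betweenness(g, "b") == pytest.approx(1.0)
        assert closeness(g, "b") == pytest.approx(0.5)

    def test_star_center_and_leaf(self):
        g = nx.star_graph(4)  # center 0, leaves 1..4
        assert asp(g, 0) == pytest.approx(1.0)
        assert asp(g, 1) == pytest.approx((1 + 2 + 2 + 2) / 4)
        assert closeness(g, 0) == pytest.approx(0.25)
        assert clustering_coefficient(g, 0) == 0.0

    def test_isolated_node(self):
        g = nx.Graph()
        g.add_node("x")
        g.add_edge("a", "b")
        assert degree(g, "x") == 0
        assert math.isnan(asp(g, "x"))
        assert betweenness(g, "x") == 0.0
        assert closeness(g, "x") == 0.0
        assert mnc(g, "x") == 0
        assert dmnc(g, "x") == 0.0

    def test_tree_leaf_and_complete_graph_betweenness_zero(self):
        tree = nx.random_labeled_tree(8, seed=1)
        leaf = min(tree.degree, key=lambda t: t[1])[0]
        assert betweenness(tree, leaf) == 0.0
        k4 = nx.complete_graph(4)
        assert betweenness(k4, 0) == 0.0

    def test_triangle_and_k4_minus_edge_clustering(self):
        tri = nx.complete_graph(3)
        assert clustering_coefficient(tri, 0) == pytest.approx(1.0)
        k4 = nx.complete_graph(4)
        k4.remove_edge(0, 1)
        # node 2 keeps k=3 neighbours {0,1,3} with 2 edges among them
        assert clustering_coefficient(k4, 2) == pytest.approx(2 / 3)
        # a node incident to the missing edge has k=2, both neighbours joined
        assert clustering_coefficient(k4, 0) == pytest.approx(1.0)

    def test_single_edge_closeness(self):
        g = nx.Graph([("a", "b")])
        assert closeness(g, "a") == pytest.approx(1.0)

    def test_missing_node_raises(self):
        g = nx.Graph([("a", "b")])
        with pytest.raises(KeyError):
            degree(g, "z")

    @pytest.mark.parametrize("seed", range(40))
    def test_agree_with_brute_force_on_small_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        g = nx.gnp_random_graph(n, float(rng.uniform(0.15, 0.9)), seed=seed)
        oracle = brute_centralities(list(g.nodes), list(g.edges))
        for v in g.nodes:
            exp = oracle[v]
            assert degree(g, v) == exp["degree"]
            got_asp = asp(g, v)
            if exp["asp"] is None:
                assert math.isnan(got_asp)
            else:
                assert got_asp == pytest.approx(exp["asp"])
            assert betweenness(g, v) == pytest.approx(exp["bc"], abs=1e-9)
            assert clustering_coefficient(g, v) == pytest.approx(exp["cco"])
            assert closeness(g, v) == pytest.approx(exp["cc"])


class TestBottleneck:
    def test_path_of_five_center(self):
        g = path_graph(5)
        assert bottleneck(g, "c") >= 2

    def test_triangle_scores_zero(self):
        g = nx.relabel_nodes(nx.complete_graph(3), {0: "a", 1: "b", 2: "c"})
        for v in g.nodes:
            assert bottleneck(g, v) == 0

    def test_isolated_node_zero(self):
        g = nx.Graph()
        g.add_node("x")
        assert bottleneck(g, "x") == 0

    def test_deterministic_across_input_orderings(self):
        edges = [("a", "b"), ("b", "c"), ("c", "d"), ("b", "d"), ("d", "e")]
        g1, _ = clean_graph(edges)
        g2, _ = clean_graph(list(reversed(edges)))
        assert bottleneck(g1) == bottleneck(g2)

    def test_star_center_is_bottleneck_for_all_leaves(self):
        g = nx.star_graph(7)
        # for each leaf root, the center carries all other 6 leaves
        assert bottleneck(g, 0) == 7


class TestEPC:
    def test_retention_one_equals_component_size_minus_one(self):
        g = nx.gnp_random_graph(12, 0.3, seed=3)
        cfg = EPCConfig(repetitions=3, edge_retention_probability=1.0, seed=0)
        comp = {v: len(c) for c in nx.connected_components(g) for v in c}
        for v in g.nodes:
            assert epc(g, v, cfg) == pytest.approx(comp[v] - 1)

    def test_retention_zero_is_zero(self):
        g = nx.complete_graph(5)
        cfg = EPCConfig(repetitions=3, edge_retention_probability=0.0, seed=0)
        assert all(val == 0.0 for val in epc_all(g, cfg).values())

    def test_single_edge_converges_to_retention_probability(self):
        g = nx.Graph([("a", "b")])
        n = 10_000
        cfg = EPCConfig(repetitions=n, edge_retention_probability=0.5, seed=7)
        se = math.sqrt(0.25 / n)
        assert abs(epc(g, "a", cfg) - 0.5) <= 3 * se

    def test_two_edge_path_matches_analytic_expectation(self):
        # E[EPC(center)] = 2p; E[EPC(end)] = p + p^2
        g = path_graph(3)
        p, n = 0.5, 10_000
        cfg = EPCConfig(repetitions=n, edge_retention_probability=p, seed=9)
        vals = epc_all(g, cfg)
        assert abs(vals["b"] - 2 * p) <= 3 * math.sqrt(2 * 0.25 / n)
        assert abs(vals["a"] - (p + p * p)) <= 4 * math.sqrt(0.5 / n)

    def test_seeded_reproducibility(self):
        g = nx.gnp_random_graph(10, 0.4, seed=2)
        cfg = EPCConfig(repetitions=50, edge_retention_probability=0.5, seed=5)
        assert epc_all(g, cfg) == epc_all(g, cfg)


class TestNeighbourhoodScores:
    def test_star_center(self):
        g = nx.star_graph(4)
        assert mnc(g, 0) == 1
        assert dmnc(g, 0) == 0.0

    def test_triangle(self):
        g = nx.complete_graph(3)
        assert mnc(g, 0) == 2
        assert dmnc(g, 0) == pytest.approx(1 / 2 ** 1.7)

    def test_mnc_bounded_by_degree(self):
        g = nx.gnp_random_graph(15, 0.3, seed=6)
        for v in g.nodes:
            if g.degree(v):
                assert mnc(g, v) <= g.degree(v)


class TestMetricsTable:
    def test_all_nine_columns_and_consistency(self):
        g = nx.gnp_random_graph(12, 0.3, seed=1)
        table = node_metrics_table(
            g, EPCConfig(repetitions=20, edge_retention_probability=0.5, seed=0))
        assert list(table.columns) == [
            "degree", "asp", "bc", "cco", "cc", "bn", "epc", "mnc", "dmnc"]
        for v in g.nodes:
            assert table.loc[v, "degree"] == g.degree(v)
            assert table.loc[v, "bn"] == bottleneck(g, v)
            assert table.loc[v, "mnc"] == mnc(g, v)

    def test_relabelling_invariance_except_bn(self):
        g = nx.gnp_random_graph(10, 0.35, seed=4)
        mapping = {i: f"z{9 - i}" for i in range(10)}
        h = nx.relabel_nodes(g, mapping)
        for v in g.nodes:
            assert degree(g, v) == degree(h, mapping[v])
            assert betweenness(g, v) == pytest.approx(
                betweenness(h, mapping[v]))
            assert closeness(g, v) == pytest.approx(closeness(h, mapping[v]))
            assert mnc(g, v) == mnc(h, mapping[v])
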