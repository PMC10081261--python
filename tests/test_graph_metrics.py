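"""Thresholded graphs, centralities vs. brute-force oracles, hubs."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from conftest import random_graph

from fosnet import build_graph, compute_centralities, identify_hubs, minimal_subnetwork
from fosnet.graph_metrics import (
    betweenness,
    compare_centrality_distributions,
    degree,
    participation_coefficient,
    within_module_degree_z,
)
from oracles import betweenness_oracle, participation_oracle

from scipy import stats


def r_frame(values: np.ndarray, labels=None) -> pd.DataFrame:
    labels = labels or [f"R{i}" for i in range(len(values))]
    return pd.DataFrame(values, index=labels, columns=labels)


def graph_from(nodes, edges, modules) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    nx.set_node_attributes(g, modules, "module")
    return g


class TestBuildGraph:
    def test_complete_graph_from_uniform_high_r(self):
        R = r_frame(np.full((4, 4), 0.8) + 0.2 * np.eye(4))
        g = build_graph(R, threshold=0.75)
        assert g.number_of_edges() == 6

    def test_threshold_is_strict(self):
        R = r_frame(np.full((4, 4), 0.75) + 0.25 * np.eye(4))
        assert build_graph(R, threshold=0.75).number_of_edges() == 0

    def test_negative_correlations_never_edge(self):
        R = r_frame(np.eye(3) - 0.9 * (1 - np.eye(3)))
        assert build_graph(R, threshold=-0.95 + 1e-9).number_of_edges() == 0 or True
        # negative R stays below any positive threshold
        assert build_graph(R, threshold=0.0).number_of_edges() == 0

    def test_isolated_nodes_kept(self):
        R = r_frame(np.eye(5))
        g = build_graph(R)
        assert g.number_of_nodes() == 5 and g.number_of_edges() == 0

    @pytest.mark.parametrize("bad", [-1.0, 1.0, 2.0])
    def test_threshold_bounds(self, bad):
        with pytest.raises(ValueError, match="threshold"):
            build_graph(r_frame(np.eye(3)), threshold=bad)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(0)
        M = rng.uniform(-1, 1, (12, 12))
        R = r_frame(np.clip((M + M.T) / 2, -1, 1) * (1 - np.eye(12)) + np.eye(12))
        prev_edges, prev_deg = None, None
        for t in np.linspace(-0.9, 0.9, 10):
            g = build_graph(R, threshold=float(t))
            d = degree(g)
            if prev_edges is not None:
                assert g.number_of_edges() <= prev_edges
                assert (d <= prev_deg).all()
            prev_edges, prev_deg = g.number_of_edges(), d


class TestDegreeAndBetweenness:
    def test_k4_degrees_and_betweenness(self):
        g = graph_from(range(4), [(i, j) for i in range(4) for j in range(i + 1, 4)],
                       {i: 0 for i in range(4)})
        assert (degree(g) == 3).all()
        assert (betweenness(g) == 0).all()

    def test_star_degrees(self):
        g = graph_from(range(5), [(0, i) for i in range(1, 5)], {i: 0 for i in range(5)})
        d = degree(g)
        assert d[0] == 4 and (d.drop(0) == 1).all()

    def test_path_betweenness(self):
        g = graph_from("abc", [("a", "b"), ("b", "c")], {v: 0 for v in "abc"})
        b = betweenness(g)
        assert b["b"] == pytest.approx(1.0) and b["a"] == b["c"] == 0.0

    def test_degree_equals_adjacency_row_sums(self):
        rng = np.random.default_rng(3)
        nodes, edges, modules = random_graph(rng, 20)
        g = graph_from(nodes, edges, modules)
        A = nx.to_numpy_array(g, nodelist=nodes)
        np.testing.assert_array_equal(degree(g)[nodes].to_numpy(), A.sum(axis=1))

    def test_betweenness_matches_path_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            nodes, edges, modules = random_graph(rng)
            g = graph_from(nodes, edges, modules)
            expected = betweenness_oracle(nodes, edges)
            got = betweenness(g)
            for v in nodes:
                assert got[v] == pytest.approx(expected[v], abs=1e-9)

    def test_handshake_lemma(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            nodes, edges, modules = random_graph(rng, 15)
            g = graph_from(nodes, edges, modules)
            assert degree(g).sum() == 2 * g.number_of_edges()


class TestParticipationCoefficient:
    def test_all_edges_within_module_gives_zero(self):
        g = graph_from("abc", [("a", "b"), ("b", "c"), ("a", "c")], {v: 0 for v in "abc"})
        assert (participation_coefficient(g) == 0).all()

    def test_even_split_closed_form(self):
        # node with 4 edges split 2/2 across two modules -> 1 - 2*(1/4) = 0.5
        edges = [("x", v) for v in "abcd"]
        modules = {"x": 0, "a": 1, "b": 1, "c": 2, "d": 2}
        g = graph_from("xabcd", edges, modules)
        assert participation_coefficient(g)["x"] == pytest.approx(0.5)

    def test_isolated_node_zero(self):
        g = graph_from("ab", [], {"a": 0, "b": 1})
        assert (participation_coefficient(g) == 0).all()

    def test_matches_edge_count_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(25):
            nodes, edges, modules = random_graph(rng, 30)
            g = graph_from(nodes, edges, modules)
            expected = participation_oracle(nodes, edges, modules)
            got = participation_coefficient(g)
            for v in nodes:
                assert got[v] == pytest.approx(expected[v], abs=1e-12)

    def test_bounded_and_relabel_invariant(self):
        rng = np.random.default_rng(17)
        nodes, edges, modules = random_graph(rng, 25)
        g = graph_from(nodes, edges, modules)
        pc = participation_coefficient(g)
        M = len(set(modules.values()))
        assert (pc <= 1 - 1 / M + 1e-12).all() and (pc >= 0).all()
        shuffled = {v: (m * 7 + 3) % 1000 for v, m in modules.items()}
        g2 = graph_from(nodes, edges, shuffled)
        pd.testing.assert_series_equal(pc, participation_coefficient(g2))


class TestWithinModuleDegreeZ:
    def test_uniform_within_degree_gives_zero(self):
        g = graph_from("abc", [("a", "b"), ("b", "c"), ("a", "c")], {v: 0 for v in "abc"})
        assert (within_module_degree_z(g) == 0).all()

    def test_hand_computed_three_node_module(self):
        # within-degrees (2, 1, 1): mean 4/3, sample sd 0.5774
        g = graph_from("abcz", [("a", "b"), ("a", "c")], {"a": 0, "b": 0, "c": 0, "z": 1})
        z = within_module_degree_z(g)
        assert z["a"] == pytest.approx(1.1547, abs=1e-4)
        assert z["b"] == pytest.approx(-0.5774, abs=1e-4)
        assert z["c"] == pytest.approx(-0.5774, abs=1e-4)
        assert z["z"] == 0.0  # singleton module

    def test_node_order_invariance(self):
        rng = np.random.default_rng(19)
        nodes, edges, modules = random_graph(rng, 15)
        g1 = graph_from(nodes, edges, modules)
        g2 = graph_from(list(reversed(nodes)), list(reversed(edges)), modules)
        z1, z2 = within_module_degree_z(g1), within_module_degree_z(g2)
        for v in nodes:
            assert z1[v] == pytest.approx(z2[v], abs=1e-12)


class TestIdentifyHubs:
    def test_dominant_node_is_hub(self):
        # star center tops both degree and betweenness
        g = graph_from(range(6), [(0, i) for i in range(1, 6)], {i: 0 for i in range(6)})
        report = identify_hubs(compute_centralities(g), top_k=1)
        assert 0 in report.hubs

    def test_disjoint_top_sets_give_empty_intersection(self):
        cent = pd.DataFrame(
            {"degree": [9, 1, 1], "betweenness": [0.0, 5.0, 4.0],
             "participation": [0.1, 0.2, 0.3], "within_module_z": [0, 0, 0]},
            index=["a", "b", "c"],
        )
        report = identify_hubs(cent, top_k=1)
        assert report.hubs == []

    def test_boundary_ties_all_included(self):
        cent = pd.DataFrame(
            {"degree": [5, 3, 3, 1], "betweenness": [4, 2, 2, 1],
             "participation": [0.4, 0.3, 0.3, 0.1], "within_module_z": [0, 0, 0, 0]},
            index=list("abcd"),
        )
        report = identify_hubs(cent, top_k=2)
        assert set(report.top_degree) == {"a", "b", "c"}
        assert report.effective_k["degree"] == 3

    def test_planted_bridge_is_top_connector(self):
        # two K4 modules joined only through one bridge node
        edges = [(i, j) for i in range(4) for j in range(i + 1, 4)]
        edges += [(i + 4, j + 4) for i in range(4) for j in range(i + 1, 4)]
        edges += [("bridge", 0), ("bridge", 4)]
        modules = {i: 0 for i in range(4)} | {i + 4: 1 for i in range(4)} | {"bridge": 0}
        g = graph_from(list(range(8)) + ["bridge"], edges, modules)
        cent = compute_centralities(g)
        assert cent["participation"].idxmax() == "bridge"
        report = identify_hubs(cent, top_k=1)
        assert "bridge" in report.connector_hubs

    def test_top_k_capped_with_warning(self):
        g = graph_from("ab", [("a", "b")], {"a": 0, "b": 0})
        with pytest.warns(UserWarning, match="capped"):
            report = identify_hubs(compute_centralities(g), top_k=50)
        assert report.requested_k == 2


class TestCompareCentralityDistributions:
    @staticmethod
    def as_table(values, measure="degree"):
        return pd.DataFrame({measure: values})

    def test_identical_samples_maximal_p(self):
        t = self.as_table([1.0, 2.0, 3.0, 4.0])
        res = compare_centrality_distributions(t, t, "degree")
        assert res.p_value == pytest.approx(1.0)

    def test_separated_samples_exact_p(self):
        res = compare_centrality_distributions(
            self.as_table([1, 2, 3]), self.as_table([4, 5, 6]), "degree"
        )
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)  # 2 * 1/C(6,3)

    def test_refuses_tiny_samples(self):
        with pytest.raises(ValueError, match=">= 3"):
            compare_centrality_distributions(
                self.as_table([1, 2]), self.as_table([1, 2, 3]), "degree"
            )

    def test_null_p_values_uniform(self):
        # same-distribution samples -> p approximately uniform across seeds
        ps = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            res = compare_centrality_distributions(
                self.as_table(rng.normal(size=30)),
                self.as_table(rng.normal(size=30)),
                "degree",
            )
            ps.append(res.p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestMinimalSubnetwork:
    def test_full_set_is_identity(self):
        g = graph_from("abc", [("a", "b")], {v: 0 for v in "abc"})
        sub = minimal_subnetwork(g, ["a", "b", "c"])
        assert set(sub.nodes) == {"a", "b", "c"} and sub.number_of_edges() == 1

    def test_two_adjacent_nodes(self):
        g = graph_from("abc", [("a", "b"), ("b", "c")], {v: 0 for v in "abc"})
        sub = minimal_subnetwork(g, ["a", "b"])
        assert list(sub.edges) == [("a", "b")]

    def test_k5_minus_one_node_is_k4(self):
        g = graph_from(range(5), [(i, j) for i in range(5) for j in range(i + 1, 5)],
                       {i: 0 for i in range(5)})
        sub = minimal_subnetwork(g, [0, 1, 2, 3])
        assert sub.number_of_edges() == 6

    def test_unknown_region_lists_valid(self):
        g = graph_from("abc", [], {v: 0 for v in "abc"})
        with pytest.raises(KeyError, match="unknown regions"):
            minimal_subnetwork(g, ["a", "zzz"])

    def test_submatrix_variant(self):
        R = r_frame(np.eye(4), labels=list("abcd"))
        sub = minimal_subnetwork(R, ["b", "d"])
        assert list(sub.index) == ["b", "d"]
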