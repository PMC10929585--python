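import networkx as nx
import numpy as np
import pytest

from calcinet import (
    betweenness,
    betweenness_change_table,
    connection_sign_counts,
    detect_communities,
    graph_diameter,
    split_signed_graph,
)
from conftest import brute_force_betweenness, floyd_warshall_distances, random_weighted_digraph


class TestSplitSignedGraph:
    def test_signs_route_to_the_right_graph(self):
        T = np.zeros((3, 3))
        T[0, 1] = 0.2
        T[1, 2] = -0.3
        pair = split_signed_graph(T)
        assert pair.excitatory[1][0]["weight"] == pytest.approx(0.2)
        assert pair.inhibitory[2][1]["weight"] == pytest.approx(0.3)

    def test_diagonal_only_matrix_is_edgeless(self):
        pair = split_signed_graph(np.diag([1.0, -2.0, 3.0]))
        assert pair.excitatory.number_of_edges() == 0
        assert pair.inhibitory.number_of_edges() == 0

    def test_edge_counts_match_sign_counts(self):
        rng = np.random.default_rng(0)
        T = rng.normal(size=(8, 8))
        pair = split_signed_graph(T)
        n_pos, n_neg, _ = connection_sign_counts(T)
        assert pair.excitatory.number_of_edges() == n_pos
        assert pair.inhibitory.number_of_edges() == n_neg

    def test_edge_sets_disjoint_and_no_self_loops(self):
        rng = np.random.default_rng(1)
        T = rng.normal(size=(6, 6))
        pair = split_signed_graph(T)
        exc = set(pair.excitatory.edges)
        inh = set(pair.inhibitory.edges)
        assert not exc & inh
        assert all(u != v for u, v in exc | inh)

    def test_remerging_reconstructs_off_diagonal(self):
        rng = np.random.default_rng(2)
        T = rng.normal(size=(7, 7))
        pair = split_signed_graph(T)
        rebuilt = np.zeros_like(T)
        for j, i, data in pair.excitatory.edges(data=True):
            rebuilt[i, j] = data["weight"]
        for j, i, data in pair.inhibitory.edges(data=True):
            rebuilt[i, j] = -data["weight"]
        off = ~np.eye(7, dtype=bool)
        np.testing.assert_allclose(rebuilt[off], T[off], rtol=1e-12)


class TestGraphDiameter:
    def test_reciprocal_pair(self):
        g = nx.DiGraph()
        g.add_edge(0, 1, weight=0.5)
        g.add_edge(1, 0, weight=0.5)
        assert graph_diameter(g) == (0.5, 1.0)

    def test_three_node_path(self):
        g = nx.DiGraph()
        for u, v, w in [(0, 1, 0.2), (1, 0, 0.2), (1, 2, 0.3), (2, 1, 0.3)]:
            g.add_edge(u, v, weight=w)
        diam, cov = graph_diameter(g)
        assert diam == pytest.approx(0.5)
        assert cov == 1.0

    def test_edgeless_graph_warns_and_degrades(self):
        g = nx.DiGraph()
        g.add_nodes_from(range(4))
        assert graph_diameter(g) == (0.0, 0.25)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_floyd_warshall_oracle(self, seed):
        rng = np.random.default_rng(seed)
        g = random_weighted_digraph(8, 0.5, rng)
        nodes, d = floyd_warshall_distances(g)
        # oracle diameter: largest strongly-connected block of the distance matrix
        finite = np.isfinite(d)
        comps = list(nx.strongly_connected_components(g))
        comp = max(comps, key=len)
        idx = [nodes.index(u) for u in comp]
        expected = d[np.ix_(idx, idx)].max() if len(idx) > 1 else 0.0
        diam, cov = graph_diameter(g)
        assert diam == pytest.approx(expected, abs=1e-12)
        assert cov == len(comp) / 8

    def test_monotone_under_edge_addition(self):
        rng = np.random.default_rng(42)
        g = random_weighted_digraph(7, 0.6, rng)
        comp = max(nx.strongly_connected_components(g), key=len)
        sub = nx.DiGraph(g.subgraph(comp))
        if sub.number_of_nodes() < 3:
            pytest.skip("degenerate draw")
        before = dict(nx.all_pairs_dijkstra_path_length(sub, weight="weight"))
        nodes = list(sub.nodes)
        u, v = nodes[0], nodes[-1]
        sub.add_edge(u, v, weight=0.01)
        after = dict(nx.all_pairs_dijkstra_path_length(sub, weight="weight"))
        for s in before:
            for t in before[s]:
                assert after[s][t] <= before[s][t] + 1e-12


class TestBetweenness:
    def test_star_center_dominates(self):
        g = nx.star_graph(5)
        nx.set_edge_attributes(g, 1.0, "weight")
        scores = betweenness(g)
        assert scores[0] == pytest.approx(1.0)
        assert all(scores[k] == 0.0 for k in range(1, 6))

    def test_directed_path_middle_node(self):
        g = nx.DiGraph()
        g.add_edge("a", "b", weight=1.0)
        g.add_edge("b", "c", weight=1.0)
        assert betweenness(g)["b"] == pytest.approx(0.5)  # 1 / ((3-1)(3-2))

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_path_enumeration_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        g = random_weighted_digraph(7, 0.4, rng)
        scores = betweenness(g)
        oracle = brute_force_betweenness(g)
        for v in g.nodes:
            assert scores[v] == pytest.approx(oracle[v], abs=1e-9)

    def test_scores_within_unit_interval(self):
        rng = np.random.default_rng(9)
        g = random_weighted_digraph(8, 0.6, rng)
        assert all(0.0 <= s <= 1.0 for s in betweenness(g).values())


class TestBetweennessChangeTable:
    def test_identical_summaries_order_by_id(self):
        scores = {2: 0.1, 0: 0.3, 1: 0.2}
        table = betweenness_change_table(scores, scores, top_k=3)
        assert list(table["neuron"]) == [0, 1, 2]
        assert np.all(table["abs_change"] == 0)

    def test_largest_change_ranks_first(self):
        before = {0: 0.1, 1: 0.1, 2: 0.1}
        after = {0: 0.1, 1: 0.3, 2: 0.1}
        table = betweenness_change_table(before, after)
        assert table.loc[0, "neuron"] == 1
        assert table.loc[0, "abs_change"] == pytest.approx(0.2)

    def test_ordering_matches_sort_oracle(self):
        rng = np.random.default_rng(3)
        before = {k: float(rng.random()) for k in range(10)}
        after = {k: float(rng.random()) for k in range(10)}
        table = betweenness_change_table(before, after, top_k=10)
        expected = sorted(
            range(10), key=lambda k: (-abs(after[k] - before[k]), k)
        )
        assert list(table["neuron"]) == expected

    def test_node_mismatch_rejected(self):
        with pytest.raises(ValueError):
            betweenness_change_table({0: 0.0}, {1: 0.0})


class TestCommunities:
    @staticmethod
    def _two_cliques():
        g = nx.Graph()
        for offset in (0, 4):
            for i in range(4):
                for j in range(i + 1, 4):
                    g.add_edge(offset + i, offset + j, weight=1.0)
        g.add_edge(0, 4, weight=0.01)
        return g

    def test_two_cliques_split_cleanly(self):
        parts, q = detect_communities(self._two_cliques(), seed=0)
        assert sorted(sorted(p) for p in parts) == [[0, 1, 2, 3], [4, 5, 6, 7]]
        assert q > 0.3

    def test_single_clique_is_one_community(self):
        g = nx.complete_graph(5)
        nx.set_edge_attributes(g, 1.0, "weight")
        parts, _ = detect_communities(g, seed=0)
        assert len(parts) == 1

    def test_edgeless_graph_gives_singletons(self):
        g = nx.Graph()
        g.add_nodes_from(range(3))
        parts, q = detect_communities(g, seed=0)
        assert parts == [{0}, {1}, {2}] and q == 0.0

    def test_modularity_matches_direct_formula(self):
        g = self._two_cliques()
        parts, q = detect_communities(g, seed=1)
        # Q = sum_c (in_c / m2 - (deg_c / m2)^2) with m2 = total weight * 2
        m2 = 2 * sum(d["weight"] for _, _, d in g.edges(data=True))
        q_direct = 0.0
        for part in parts:
            internal = sum(
                d["weight"] for u, v, d in g.edges(data=True) if u in part and v in part
            )
            degree = sum(dict(g.degree(weight="weight"))[u] for u in part)
            q_direct += 2 * internal / m2 - (degree / m2) ** 2
        assert q == pytest.approx(q_direct, abs=1e-12)
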