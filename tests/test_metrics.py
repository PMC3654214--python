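"""Graph measures against documented fixtures and brute-force oracles."""

import math

import numpy as np
import pytest

from fcgraph import (
    BinaryGraph,
    betweenness_centrality,
    characteristic_path_length,
    clustering_coefficients,
    compute_metric_table,
    degree_distribution,
    degrees,
    global_efficiency,
    identify_hubs,
    local_efficiency,
    make_random_graph,
    make_toy_graph,
    shortest_path_lengths,
)

import oracles


class TestDegrees:
    def test_schematic_central_node(self):
        d, _ = degrees(make_toy_graph("figure1_clustering"))
        assert d[0] == 3

    def test_edgeless(self):
        d, mean = degrees(BinaryGraph(np.zeros((4, 4), dtype=bool)))
        assert np.all(d == 0) and mean == 0

    def test_complete_k5(self):
        d, mean = degrees(make_toy_graph("complete_k5"))
        assert np.all(d == 4) and mean == 4

    def test_handshake_lemma(self, small_random_graphs):
        for g in small_random_graphs:
            assert g.degree_vector().sum() == 2 * g.n_edges


class TestShortestPaths:
    def test_path5_endpoints(self):
        d = shortest_path_lengths(make_toy_graph("path5"))
        assert d.lengths[0, 4] == 4

    def test_complete_graph_all_ones(self):
        d = shortest_path_lengths(make_toy_graph("complete_k5")).lengths
        off = d[~np.eye(5, dtype=bool)]
        assert np.all(off == 1)

    def test_unreachable_flagged_as_inf(self):
        d = shortest_path_lengths(make_toy_graph("two_cliques"))
        assert math.isinf(d.lengths[0, 3])
        assert not d.reachable()[0, 3]

    def test_matches_floyd_warshall(self, small_random_graphs):
        for g in small_random_graphs[:30]:
            mine = shortest_path_lengths(g).lengths
            ref = oracles.floyd_warshall(g.adjacency)
            np.testing.assert_array_equal(mine, ref)

    def test_triangle_inequality_on_reachable_triples(self, small_random_graphs):
        for g in small_random_graphs[:10]:
            d = shortest_path_lengths(g).lengths
            n = g.n_nodes
            for i in range(n):
                for j in range(n):
                    for k in range(n):
                        if np.isfinite(d[i, k]) and np.isfinite(d[k, j]):
                            assert d[i, j] <= d[i, k] + d[k, j]


class TestPathLength:
    def test_complete_graph(self):
        l, _, defined = characteristic_path_length(make_toy_graph("complete_k4"))
        assert defined and l == 1

    def test_path5(self):
        l, _, _ = characteristic_path_length(make_toy_graph("path5"))
        assert l == pytest.approx(2.0)

    def test_disconnected_triangles_exclude_unreachable(self):
        l, _, defined = characteristic_path_length(make_toy_graph("two_cliques"))
        assert defined and l == 1

    def test_edgeless_flagged_undefined(self):
        l, _, defined = characteristic_path_length(
            BinaryGraph(np.zeros((3, 3), dtype=bool))
        )
        assert not defined and math.isnan(l)


class TestGlobalEfficiency:
    def test_complete_graph(self):
        assert global_efficiency(make_toy_graph("complete_k5")) == 1

    def test_edgeless(self):
        assert global_efficiency(BinaryGraph(np.zeros((4, 4), dtype=bool))) == 0

    def test_path5_closed_form(self):
        # unordered pairs: four at distance 1, three at 2, two at 3, one at 4
        expected = (4 * 1 + 3 / 2 + 2 / 3 + 1 / 4) / 10
        assert global_efficiency(make_toy_graph("path5")) == pytest.approx(expected)

    def test_jensen_bound_on_connected_graphs(self, small_random_graphs):
        for g in small_random_graphs:
            d = shortest_path_lengths(g).lengths
            if not np.all(np.isfinite(d)):
                continue
            l, _, _ = characteristic_path_length(g)
            assert global_efficiency(g) >= 1 / l - 1e-12


class TestClustering:
    def test_schematic_value(self):
        c, _ = clustering_coefficients(make_toy_graph("figure1_clustering"))
        assert c[0] == pytest.approx(2 / 3)

    def test_complete_k4(self):
        c, mean = clustering_coefficients(make_toy_graph("complete_k4"))
        assert np.all(c == 1) and mean == 1

    def test_star_centre_zero(self):
        c, _ = clustering_coefficients(make_toy_graph("star"))
        assert np.all(c == 0)


class TestLocalEfficiency:
    def test_complete_k4(self):
        e, _ = local_efficiency(make_toy_graph("complete_k4"))
        np.testing.assert_allclose(e, 1.0)

    def test_degree_one_node_zero(self):
        e, _ = local_efficiency(make_toy_graph("path5"))
        assert e[0] == 0 and e[4] == 0


class TestBetweenness:
    def test_path3_middle(self):
        x = betweenness_centrality(make_toy_graph("path3"))
        np.testing.assert_allclose(x, [0, 1, 0])

    def test_complete_graph_zero(self):
        assert np.all(betweenness_centrality(make_toy_graph("complete_k5")) == 0)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            betweenness_centrality(BinaryGraph(np.zeros((2, 2), dtype=bool)))


class TestOracleEquivalence:
    """Fast implementations agree with naive enumeration on random graphs."""

    def test_all_measures(self, small_random_graphs):
        for g in small_random_graphs:
            a = g.adjacency
            np.testing.assert_array_equal(
                shortest_path_lengths(g).lengths, oracles.floyd_warshall(a)
            )
            c, _ = clustering_coefficients(g)
            np.testing.assert_allclose(c, oracles.clustering(a), atol=1e-12)
            e, _ = local_efficiency(g)
            np.testing.assert_allclose(e, oracles.local_eff(a), atol=1e-12)
            assert global_efficiency(g) == pytest.approx(
                oracles.global_eff(a), abs=1e-12
            )
            np.testing.assert_allclose(
                betweenness_centrality(g), oracles.betweenness(a), atol=1e-12
            )


class TestHubs:
    def test_star_centre_by_degree(self):
        assert identify_hubs(make_toy_graph("star"), "degree", 1) == [0]

    def test_path5_middle_by_betweenness(self):
        assert identify_hubs(make_toy_graph("path5"), "betweenness", 1) == [2]

    def test_tie_break_by_node_order(self):
        assert identify_hubs(make_toy_graph("complete_k4"), "degree", 2) == [0, 1]

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            identify_hubs(make_toy_graph("path5"), "degree", 0)


class TestDegreeDistribution:
    def test_complete_k5_mass_at_four(self):
        counts = degree_distribution(
            make_toy_graph("complete_k5"), np.arange(-0.5, 6.5)
        )
        assert counts[4] == 5 and counts.sum() == 5

    def test_path5_counts(self):
        counts = degree_distribution(make_toy_graph("path5"), np.arange(-0.5, 3.5))
        assert counts[1] == 2 and counts[2] == 3

    def test_er_mean_degree_near_binomial(self):
        g = make_random_graph("erdos_renyi", n=200, p=0.1, seed=4)
        counts = degree_distribution(g, np.arange(-0.5, 200.5))
        mean = (counts * np.arange(200)).sum() / 200
        assert abs(mean - 19.9) < 3 * np.sqrt(19.9 * 0.9)

    def test_degrees_outside_bins_rejected(self):
        with pytest.raises(ValueError):
            degree_distribution(make_toy_graph("complete_k5"), [0, 1, 2])


class TestMetricTable:
    def test_monotone_under_edge_addition(self, rng):
        a = oracles.random_adjacency(rng, 8, 0.3)
        g1 = BinaryGraph(a)
        free = [(i, j) for i in range(8) for j in range(i + 1, 8) if not a[i, j]]
        i, j = free[0]
        a2 = a.copy(); a2[i, j] = a2[j, i] = True
        g2 = BinaryGraph(a2)
        assert np.all(g2.degree_vector() >= g1.degree_vector())
        assert global_efficiency(g2) >= global_efficiency(g1)

    def test_long_format_covers_all_measures(self):
        t = compute_metric_table(make_toy_graph("complete_k4"), "s1", "pre",
                                 strength=np.ones(4))
        df = t.to_long()
        assert set(df["measure"]) == {
            "degree", "path_length", "clustering", "local_efficiency",
            "betweenness", "strength", "global_efficiency",
        }
        node_rows = df[df["node"].notna()]
        assert len(node_rows) == 4 * 6
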