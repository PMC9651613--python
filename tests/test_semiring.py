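import math

import numpy as np
import pytest

from nbflink.graph import GraphDataError
from nbflink.semiring import (
    CLASSIC_METHODS,
    MAX_MIN,
    MAX_TIMES,
    MIN_PLUS,
    SUM_PRODUCT,
    EnumerationRefusedError,
    Semiring,
    classic_link_score,
    enumerate_path_score,
    generalized_bellman_ford,
    katz_closed_form,
    ppr_edge_values,
)

from conftest import make_graph, random_edge_values, random_graph

SEMIRINGS = [MIN_PLUS, SUM_PRODUCT, MAX_MIN, MAX_TIMES]


@pytest.fixture
def triangle_weights():
    return {("a", "b"): 1.0, ("b", "c"): 1.0, ("a", "c"): 3.0}


class TestBellmanFord:
    def test_boundary_condition_t0(self, triangle, triangle_weights):
        for sr in SEMIRINGS:
            r = generalized_bellman_ford(triangle, "a", sr, triangle_weights, 0)
            assert r["a"] == sr.one
            assert r["b"] == sr.zero and r["c"] == sr.zero

    def test_min_plus_triangle(self, triangle, triangle_weights):
        r = generalized_bellman_ford(triangle, "a", MIN_PLUS, triangle_weights, 2)
        assert r["c"] == 2.0  # two-hop route beats the weight-3 direct edge

    def test_sum_product_path(self, path_graph):
        ev = {("a", "b"): 0.5, ("b", "c"): 0.5}
        r = generalized_bellman_ford(path_graph, "a", SUM_PRODUCT, ev, 2)
        assert r["c"] == pytest.approx(0.25)
        assert r["b"] == pytest.approx(0.5)

    def test_negative_iterations_rejected(self, triangle, triangle_weights):
        with pytest.raises(ValueError):
            generalized_bellman_ford(triangle, "a", MIN_PLUS, triangle_weights, -1)

    def test_missing_edge_value_rejected(self, triangle):
        with pytest.raises(GraphDataError):
            generalized_bellman_ford(triangle, "a", MIN_PLUS, {("a", "b"): 1.0}, 2)

    def test_monotone_stabilization(self, rng):
        # min-plus and max-min values are monotone in T, fixed after |V|-1
        for _ in range(5):
            g = random_graph(rng, n_nodes=6)
            ev = random_edge_values(rng, g)
            for sr, better in ((MIN_PLUS, np.less_equal), (MAX_MIN, np.greater_equal)):
                prev = None
                for T in range(g.n_nodes + 2):
                    r = generalized_bellman_ford(g, g.nodes[0], sr, ev, T)
                    vals = np.array([r[v] for v in g.nodes])
                    if prev is not None:
                        assert better(vals, prev).all() or np.allclose(vals, prev)
                    prev = vals
                fixed = generalized_bellman_ford(
                    g, g.nodes[0], sr, ev, g.n_nodes - 1
                )
                more = generalized_bellman_ford(g, g.nodes[0], sr, ev, g.n_nodes + 1)
                assert all(
                    np.isclose(fixed[v], more[v]) or fixed[v] == more[v]
                    for v in g.nodes
                )


class TestEnumerationOracle:
    def test_empty_walk_conventions(self, path_graph):
        ev = {("a", "b"): 0.5, ("b", "c"): 0.5}
        assert enumerate_path_score(path_graph, "a", "a", SUM_PRODUCT, ev, 0) == 1.0
        assert enumerate_path_score(path_graph, "a", "c", SUM_PRODUCT, ev, 0) == 0.0

    def test_disconnected_gives_zero(self):
        g = make_graph([("a", "DNA"), ("b", "PROTEIN"), ("x", "DNA")], [("a", "b")])
        ev = {("a", "b"): 1.0}
        assert enumerate_path_score(g, "a", "x", SUM_PRODUCT, ev, 4) == 0.0
        assert enumerate_path_score(g, "a", "x", MIN_PLUS, ev, 4) == math.inf

    def test_refuses_exponential_lengths(self, triangle, triangle_weights):
        with pytest.raises(EnumerationRefusedError):
            enumerate_path_score(triangle, "a", "c", MIN_PLUS, triangle_weights, 9)

    @pytest.mark.parametrize("sr", SEMIRINGS, ids=lambda s: s.name)
    def test_oracle_equivalence_random_graphs(self, sr, rng):
        """Dynamic program == brute-force walk aggregation (the core check)."""
        for _ in range(20):
            g = random_graph(rng, n_nodes=int(rng.integers(2, 9)), max_edges=12)
            ev = random_edge_values(rng, g)
            T = int(rng.integers(0, 5))
            src = g.nodes[int(rng.integers(g.n_nodes))]
            dp = generalized_bellman_ford(g, src, sr, ev, T)
            for v in g.nodes:
                expected = enumerate_path_score(g, src, v, sr, ev, T)
                assert dp[v] == pytest.approx(expected, abs=1e-9), (sr.name, src, v, T)

    def test_edge_order_independence(self, rng):
        # scores must not depend on edge insertion order (distributivity)
        g1 = make_graph(
            [("a", "DNA"), ("b", "PROTEIN"), ("c", "DNA"), ("d", "PROTEIN")],
            [("a", "b"), ("b", "c"), ("c", "d"), ("a", "d")],
        )
        g2 = make_graph(
            [("a", "DNA"), ("b", "PROTEIN"), ("c", "DNA"), ("d", "PROTEIN")],
            [("a", "d"), ("c", "d"), ("b", "c"), ("a", "b")],
        )
        ev = {("a", "b"): 0.3, ("b", "c"): 0.7, ("c", "d"): 0.2, ("a", "d"): 0.9}
        for sr in SEMIRINGS:
            r1 = generalized_bellman_ford(g1, "a", sr, ev, 3)
            r2 = generalized_bellman_ford(g2, "a", sr, ev, 3)
            for v in "abcd":
                assert r1[v] == pytest.approx(r2[v], abs=1e-12)

    def test_noncommutative_matrix_semiring(self):
        # matrix-valued edge representations: ⊗ = matrix product
        sr = Semiring(
            plus=lambda a, b: a + b,
            times=lambda a, b: a @ b,
            zero=np.zeros((2, 2)),
            one=np.eye(2),
            name="matrix",
        )
        g = make_graph(
            [("a", "DNA"), ("b", "PROTEIN"), ("c", "DNA")],
            [("a", "b"), ("b", "c")],
        )
        ev = {
            ("a", "b"): np.array([[1.0, 1.0], [0.0, 1.0]]),
            ("b", "c"): np.array([[1.0, 0.0], [2.0, 1.0]]),
        }
        dp = generalized_bellman_ford(g, "a", sr, ev, 2)
        oracle = enumerate_path_score(g, "a", "c", sr, ev, 2)
        np.testing.assert_allclose(dp["c"], oracle)


class TestClassicMethods:
    def test_graph_distance_triangle(self, triangle, triangle_weights):
        r = classic_link_score(
            triangle, "graph_distance", {"edge_values": triangle_weights}, "a", 4
        )
        assert (r["a"], r["b"], r["c"]) == (0.0, 1.0, 2.0)

    def test_widest_path(self):
        g = make_graph(
            [("a", "DNA"), ("b", "PROTEIN"), ("c", "DNA")],
            [("a", "b"), ("b", "c"), ("a", "c")],
        )
        ev = {("a", "b"): 5.0, ("b", "c"): 3.0, ("a", "c"): 2.0}
        r = classic_link_score(g, "widest_path", {"edge_values": ev}, "a", 3)
        assert r["c"] == 3.0  # max-min over both routes

    def test_katz_matches_closed_form(self, path_graph):
        # geometric truncation error (beta * sqrt(2))^T is ~1e-11 here
        beta, T = 0.3, 30
        r = classic_link_score(path_graph, "katz", {"beta": beta}, "a", T)
        closed = katz_closed_form(path_graph, beta)
        idx = path_graph.node_index()
        assert r["c"] == pytest.approx(closed[idx["a"], idx["c"]], abs=1e-6)

    def test_katz_warns_outside_convergence_bound(self, triangle):
        with pytest.warns(UserWarning):
            classic_link_score(triangle, "katz", {"beta": 0.9}, "a", 3)

    def test_most_reliable_path_requires_probabilities(self, triangle):
        bad = {e: 1.5 for e in triangle.edges}
        with pytest.raises(ValueError):
            classic_link_score(
                triangle, "most_reliable_path", {"edge_values": bad}, "a", 2
            )

    def test_most_reliable_path_value(self):
        g = make_graph(
            [("a", "DNA"), ("b", "PROTEIN"), ("c", "DNA")],
            [("a", "b"), ("b", "c"), ("a", "c")],
        )
        ev = {("a", "b"): 0.9, ("b", "c"): 0.9, ("a", "c"): 0.5}
        r = classic_link_score(g, "most_reliable_path", {"edge_values": ev}, "a", 3)
        assert r["c"] == pytest.approx(0.81)

    def test_personalized_pagerank_fixed_point(self, rng):
        # long truncation approaches the exact restart-walk fixed point
        g = random_graph(rng, n_nodes=6, max_edges=10)
        alpha = 0.85
        src = g.nodes[0]
        r = classic_link_score(g, "personalized_pagerank", {"alpha": alpha}, src, 200)
        A = g.adjacency_csr().toarray()
        deg = A.sum(axis=1, keepdims=True)
        P = np.divide(A, deg, out=np.zeros_like(A), where=deg > 0)
        idx = g.node_index()
        e = np.zeros(g.n_nodes)
        e[idx[src]] = 1.0
        exact = (1 - alpha) * np.linalg.solve(np.eye(g.n_nodes) - alpha * P.T, e)
        for v in g.nodes:
            assert r[v] == pytest.approx(exact[idx[v]], abs=1e-9)

    def test_unknown_method_rejected(self, triangle):
        with pytest.raises(ValueError):
            classic_link_score(triangle, "dijkstra", {}, "a", 2)

    def test_ppr_engine_matches_enumeration(self, rng):
        # the damped transition values run through the same oracle contract
        g = random_graph(rng, n_nodes=5, max_edges=8)
        ev = ppr_edge_values(g, alpha=0.85)
        src = g.nodes[0]
        dp = generalized_bellman_ford(g, src, SUM_PRODUCT, ev, 4)
        for v in g.nodes:
            assert dp[v] == pytest.approx(
                enumerate_path_score(g, src, v, SUM_PRODUCT, ev, 4), abs=1e-9
            )
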