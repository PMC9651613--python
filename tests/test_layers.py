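import numpy as np
import pytest

from nbflink import autodiff as ad
from nbflink.autodiff import Tensor
from nbflink.graph import DNA, PROTEIN, GraphDataError, InteractionGraph
from nbflink.layers import (
    GraphArrays,
    aggregate,
    identity_layer_params,
    indicator,
    message,
    nbfnet_forward,
)
from nbflink.semiring import SUM_PRODUCT, generalized_bellman_ford

from conftest import make_graph, random_edge_values, random_graph


class TestIndicator:
    def test_query_on_source_row_only(self, triangle):
        q = Tensor(np.array([1.0, 1.0]))
        state = indicator(triangle, "a", q)
        np.testing.assert_allclose(state.data[0], [[1, 1], [0, 0], [0, 0]])

    def test_changing_source_moves_the_row(self, triangle):
        q = Tensor(np.array([2.0, 3.0]))
        sa = indicator(triangle, "a", q).data[0]
        sb = indicator(triangle, "b", q).data[0]
        np.testing.assert_allclose(sa[0], sb[1])
        assert sa[1].sum() == 0 and sb[0].sum() == 0

    def test_zero_query_gives_zero_state(self, triangle):
        state = indicator(triangle, "b", Tensor(np.zeros(4)))
        assert not state.data.any()

    def test_unknown_source_rejected(self, triangle):
        with pytest.raises(GraphDataError):
            indicator(triangle, "zzz", Tensor(np.ones(2)))


class TestMessage:
    def test_distmult_elementwise_product(self):
        out = message(Tensor([1.0, 2.0]), Tensor([3.0, 4.0]), "distmult")
        np.testing.assert_allclose(out.data, [3.0, 8.0])

    def test_transe_translation(self):
        out = message(Tensor([1.0, 2.0]), Tensor([3.0, 4.0]), "transe")
        np.testing.assert_allclose(out.data, [4.0, 6.0])

    def test_rotate_quarter_turn(self):
        # (1, 0) as 1+0i rotated by pi/2 -> (0, 1)
        out = message(Tensor([1.0, 0.0]), Tensor([np.pi / 2]), "rotate")
        np.testing.assert_allclose(out.data, [0.0, 1.0], atol=1e-12)

    def test_rotate_rejects_odd_dimension(self):
        with pytest.raises(ValueError):
            message(Tensor([1.0, 2.0, 3.0]), Tensor([0.1]), "rotate")

    def test_rotate_preserves_modulus(self, rng):
        h = Tensor(rng.normal(size=6))
        theta = Tensor(rng.uniform(-np.pi, np.pi, size=3))
        out = message(h, theta, "rotate").data
        for i in range(3):
            a = np.hypot(h.data[2 * i], h.data[2 * i + 1])
            b = np.hypot(out[2 * i], out[2 * i + 1])
            assert b == pytest.approx(a, abs=1e-12)

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            message(Tensor([1.0]), Tensor([1.0]), "hadamard")


class TestAggregate:
    def test_sum_with_boundary(self):
        out = aggregate([Tensor([1.0, 2.0]), Tensor([3.0, 4.0])], Tensor([0.0, 0.0]), "sum")
        np.testing.assert_allclose(out.data, [4.0, 6.0])

    def test_max_coordinatewise(self):
        out = aggregate([Tensor([1.0, 5.0]), Tensor([3.0, 4.0])], Tensor([0.0, 0.0]), "max")
        np.testing.assert_allclose(out.data, [3.0, 5.0])

    def test_no_messages_returns_boundary(self):
        for kind in ("sum", "mean", "max"):
            out = aggregate([], Tensor([7.0, -1.0]), kind)
            np.testing.assert_allclose(out.data, [7.0, -1.0])

    def test_mean_counts_boundary_as_element(self):
        out = aggregate([Tensor([3.0])], Tensor([0.0]), "mean")
        np.testing.assert_allclose(out.data, [1.5])


class TestNBFnetForward:
    def _scalar_forward(self, g, src, edge_value, T, **kinds):
        q = Tensor(np.array([1.0]), requires_grad=True)
        layers = [identity_layer_params(1, edge_value) for _ in range(T)]
        return q, nbfnet_forward(g, src, q, layers, **kinds)

    def test_walk_counting_on_path(self, path_graph):
        _, states = self._scalar_forward(path_graph, "a", 1.0, 2)
        np.testing.assert_allclose(states[-1].data[0].ravel(), [2.0, 1.0, 1.0])
        # a: empty walk + a-b-a; b: walk a-b; c: walk a-b-c

    def test_t0_is_indicator(self, triangle):
        q = Tensor(np.array([1.0, 2.0]))
        layers = [identity_layer_params(2, 1.0)]
        states = nbfnet_forward(triangle, "a", q, layers)
        np.testing.assert_allclose(states[0].data[0, 0], [1.0, 2.0])
        assert not states[0].data[0, 1:].any()

    def test_disconnected_rows_stay_zero(self):
        g = make_graph(
            [("a", DNA), ("b", PROTEIN), ("x", DNA), ("y", PROTEIN)],
            [("a", "b"), ("x", "y")],
        )
        _, states = self._scalar_forward(g, "a", 0.7, 3)
        idx = g.node_index()
        for n in ("x", "y"):
            assert not states[-1].data[0, idx[n]].any()

    @pytest.mark.parametrize("trial", range(10))
    def test_semiring_reduction_keystone(self, trial):
        """d=1 DistMult+sum with identity mixing == sum-product Bellman-Ford."""
        rng = np.random.default_rng(100 + trial)
        g = random_graph(rng, n_nodes=int(rng.integers(3, 8)), max_edges=10)
        w = float(rng.uniform(0.2, 0.9))
        T = int(rng.integers(1, 5))
        src = g.nodes[int(rng.integers(g.n_nodes))]
        _, states = self._scalar_forward(g, src, w, T)
        ev = {e: w for e in g.edges}
        ref = generalized_bellman_ford(g, src, SUM_PRODUCT, ev, T)
        idx = g.node_index()
        for v in g.nodes:
            assert states[-1].data[0, idx[v], 0] == pytest.approx(ref[v], abs=1e-9)

    def test_permutation_equivariance(self, rng):
        g1 = make_graph(
            [("a", DNA), ("b", PROTEIN), ("c", DNA), ("d", PROTEIN)],
            [("a", "b"), ("b", "c"), ("c", "d")],
        )
        # same graph, nodes declared in a different order
        g2 = make_graph(
            [("d", PROTEIN), ("b", PROTEIN), ("a", DNA), ("c", DNA)],
            [("c", "d"), ("a", "b"), ("b", "c")],
        )
        q = Tensor(rng.normal(size=3))
        layers = [identity_layer_params(3, 0.5) for _ in range(2)]
        s1 = nbfnet_forward(g1, "a", q, layers)[-1]
        s2 = nbfnet_forward(g2, "a", q, layers)[-1]
        i1, i2 = g1.node_index(), g2.node_index()
        for n in "abcd":
            np.testing.assert_allclose(s1.data[0, i1[n]], s2.data[0, i2[n]], atol=1e-12)

    @pytest.mark.parametrize("msg", ["distmult", "transe", "rotate"])
    @pytest.mark.parametrize("agg", ["sum", "mean", "max"])
    def test_sparse_and_dense_paths_agree_and_grads_flow(self, msg, agg, rng):
        """Finite-difference gradient check across all message/aggregate kinds."""
        g = make_graph(
            [("a", DNA), ("b", PROTEIN), ("c", DNA)],
            [("a", "b"), ("b", "c"), ("a", "c")],
        )
        d = 2
        e_dim = 1 if msg == "rotate" else d
        q0 = rng.normal(size=d)
        w0 = rng.normal(size=e_dim) * 0.5

        def run(q_arr, w_arr):
            q = Tensor(q_arr, requires_grad=True)
            lp = identity_layer_params(d, 1.0)
            lp.edge = Tensor(w_arr, requires_grad=True)
            states = nbfnet_forward(g, "a", q, [lp], message_kind=msg, aggregate_kind=agg)
            return q, lp.edge, states[-1]

        q, w, out = run(q0, w0)
        loss = (out * out).sum()
        loss.backward()
        assert q.grad is not None and np.isfinite(q.grad).all()
        assert w.grad is not None and np.isfinite(w.grad).all()
        assert np.abs(q.grad).sum() > 0
        eps = 1e-6
        for i in range(e_dim):
            wp, wm = w0.copy(), w0.copy()
            wp[i] += eps
            wm[i] -= eps
            _, _, op = run(q0, wp)
            _, _, om = run(q0, wm)
            num = ((op.data**2).sum() - (om.data**2).sum()) / (2 * eps)
            assert w.grad[i] == pytest.approx(num, abs=1e-4, rel=1e-3)

    def test_layer_count_zero_rejected(self, triangle):
        with pytest.raises(ValueError):
            nbfnet_forward(triangle, "a", Tensor(np.ones(2)), [])
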