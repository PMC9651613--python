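"""Neural parametrization of the generalized Bellman-Ford iteration.

The three learnable pieces mirror the algebraic recursion: an INDICATOR
writes a learned query embedding onto the source row (boundary condition),
a MESSAGE combines a neighbor state with a learned edge representation
(DistMult ∘, TransE +, or RotatE complex rotation), and an AGGREGATE
reduces incident messages together with the boundary term (sum, mean or
elementwise max).  With scalar states, multiplicative messages and sum
aggregation the layer is exactly one sum-product Bellman-Ford step — the
reduction the test-suite pins down.

States are batched as (B, |V|, d) tensors over B source nodes.  For sum
and mean aggregation the message+reduce pair is linear in the neighbor
states, so it is evaluated as a sparse adjacency product; max aggregation
materializes per-edge messages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .graph import GraphDataError, InteractionGraph

MESSAGE_KINDS = ("distmult", "transe", "rotate")
AGGREGATE_KINDS = ("sum", "mean", "max")


def indicator(
    graph: InteractionGraph, u: str | list[str], q: Tensor
) -> Tensor:
    """Boundary state h⁰: the query embedding on each source row, zeros elsewhere."""
    sources = [u] if isinstance(u, str) else list(u)
    idx_map = graph.node_index()
    try:
        src_idx = np.array([idx_map[s] for s in sources])
    except KeyError as exc:
        raise GraphDataError(f"unknown source node {exc.args[0]!r}") from None
    return ad.indicator_state(q, src_idx, graph.n_nodes)


def message(h: Tensor, w: Tensor, kind: str) -> Tensor:
    """Combine a node state with an edge representation.

    DistMult: h ∘ w;  TransE: h + w;  RotatE: elementwise complex rotation
    of h (consecutive pairs as real/imaginary parts) by the unit-modulus
    rotation encoded by the angles in w.
    """
    if kind == "distmult":
        return h * w
    if kind == "transe":
        return h + w
    if kind == "rotate":
        return _rotate(h, w)
    raise ValueError(f"unknown message kind {kind!r}; choose from {MESSAGE_KINDS}")


def _rotate(h: Tensor, theta: Tensor) -> Tensor:
    """Rotate pairs (h[2i], h[2i+1]) by angle theta[i] (unit-modulus RotatE)."""
    d = h.shape[-1]
    if d % 2:
        raise ValueError(f"RotatE requires even dimension, got d={d}")
    cos, sin = np.cos(theta.data), np.sin(theta.data)
    re = h[..., 0::2]
    im = h[..., 1::2]
    cos_t, sin_t = Tensor(cos), Tensor(sin)
    # carry the angle gradient through explicit product rule
    out_re = re * cos_t - im * sin_t
    out_im = re * sin_t + im * cos_t
    out = _interleave(out_re, out_im)
    if theta.requires_grad:
        out = _attach_angle_grad(out, h, theta, cos, sin)
    return out


def _interleave(re: Tensor, im: Tensor) -> Tensor:
    stacked = ad.concat([re, im], axis=-1)
    d2 = re.shape[-1]
    perm = np.empty(2 * d2, dtype=np.int64)
    perm[0::2] = np.arange(d2)
    perm[1::2] = np.arange(d2) + d2
    return stacked[..., perm]

def _attach_angle_grad(out: Tensor, h: Tensor, theta: Tensor, cos, sin) -> Tensor:
    """Route gradients to the rotation angles (d/dθ of the rotation matrix)."""

    prev_bw = out._backward

    def bw(g):
        if prev_bw is not None:
            prev_bw(g)
        g_re, g_im = g[..., 0::2], g[..., 1::2]
        re, im = h.data[..., 0::2], h.data[..., 1::2]
        d_theta = g_re * (-re * sin - im * cos) + g_im * (re * cos - im * sin)
        theta._accumulate(d_theta.reshape(-1, d_theta.shape[-1]).sum(axis=0))

    out._backward = bw
    out._parents = out._parents + (theta, h)
    return out


def aggregate(messages: list[Tensor], boundary: Tensor, kind: str) -> Tensor:
    """Reduce a multiset of messages together with the boundary term h⁰."""
    if kind not in AGGREGATE_KINDS:
        raise ValueError(f"unknown aggregate kind {kind!r}; choose from {AGGREGATE_KINDS}")
    if boundary is None and not messages:
        raise ValueError("aggregate of empty input")
    items = list(messages) + [boundary]
    if kind == "max":
        acc = items[0]
        for m in items[1:]:
            acc = ad.maximum(acc, m)
        return acc
    acc = items[0]
    for m in items[1:]:
        acc = acc + m
    if kind == "mean":
        acc = acc * (1.0 / len(items))
    return acc


@dataclass
class LayerParams:
    """Learned quantities of one NBFnet layer.

    ``edge`` is the edge representation shared by every edge of the single
    binding relation (angles for RotatE); ``W``/``b`` the post-aggregation
    linear mixing (identity/zero disables mixing and recovers the plain
    algebraic recursion).
    """

    edge: Tensor
    W: Tensor
    b: Tensor


@dataclass
class GraphArrays:
    """Dense/sparse views of a graph frozen for the numeric engines."""

    A: object  # csr adjacency (V, V)
    deg: np.ndarray  # (V,)
    src: np.ndarray  # directed arc sources (2E,)
    dst: np.ndarray  # directed arc destinations (2E,)
    index: dict[str, int]

    @classmethod
    def from_graph(cls, graph: InteractionGraph) -> "GraphArrays":
        idx = graph.node_index()
        arcs = [(idx[u], idx[v]) for u, v in graph.edges]
        arcs += [(v, u) for u, v in arcs]
        src = np.array([a for a, _ in arcs], dtype=np.int64)
        dst = np.array([b for _, b in arcs], dtype=np.int64)
        A = graph.adjacency_csr()
        deg = np.asarray(A.sum(axis=1)).ravel()
        return cls(A=A, deg=deg, src=src, dst=dst, index=idx)


def nbf_layer(
    H: Tensor,
    h0: Tensor,
    ga: GraphArrays,
    params: LayerParams,
    message_kind: str,
    aggregate_kind: str,
) -> Tensor:
    """One neural Bellman-Ford step on batched states (B, V, d)."""
    if message_kind not in MESSAGE_KINDS:
        raise ValueError(f"unknown message kind {message_kind!r}")
    if aggregate_kind not in AGGREGATE_KINDS:
        raise ValueError(f"unknown aggregate kind {aggregate_kind!r}")
    w = params.edge
    deg = ga.deg[None, :, None]

    if aggregate_kind in ("sum", "mean"):
        # message+sum is linear in the neighbor states -> sparse matmul
        if message_kind == "distmult":
            msg_sum = ad.spmm_nodes(ga.A, H) * w
        elif message_kind == "transe":
            msg_sum = ad.spmm_nodes(ga.A, H) + Tensor(deg) * w
        else:  # rotate
            msg_sum = ad.spmm_nodes(ga.A, _rotate(H, w))
        agg = msg_sum + h0
        if aggregate_kind == "mean":
            agg = agg / Tensor(deg + 1.0)
    else:  # max: materialize per-edge messages
        h_src = H[:, ga.src, :]
        msgs = message(h_src, w, message_kind)
        agg = ad.segment_max_messages(msgs, ga.dst, h0)

    return ad.linear(agg, params.W, params.b)


def identity_layer_params(d: int, edge_value: np.ndarray | float) -> LayerParams:
    """Layer parameters with identity mixing — the algebraic recursion itself."""
    edge = np.full(d, float(edge_value)) if np.isscalar(edge_value) else np.asarray(edge_value, float)
    return LayerParams(
        edge=Tensor(edge, requires_grad=True),
        W=Tensor(np.eye(d), requires_grad=True),
        b=Tensor(np.zeros(d), requires_grad=True),
    )


def nbfnet_forward(
    graph: InteractionGraph,
    u: str | list[str],
    q: Tensor,
    layers: list[LayerParams],
    message_kind: str = "distmult",
    aggregate_kind: str = "sum",
    ga: GraphArrays | None = None,
) -> list[Tensor]:
    """Run the layered NBFnet pass; returns states for t = 0 … T.

    Layer t updates every node's source-conditioned state from layer t−1
    via MESSAGE/AGGREGATE with that layer's edge representation; the
    boundary state h⁰ participates in every layer's aggregation.
    """
    if len(layers) < 1:
        raise ValueError("at least one layer required")
    ga = ga or GraphArrays.from_graph(graph)
    h0 = indicator(graph, u, q)
    states = [h0]
    H = h0
    for lp in layers:
        if lp.edge.shape[-1] not in (q.shape[-1], q.shape[-1] // 2):
            raise ValueError("edge representation dimension mismatch")
        H = nbf_layer(H, h0, ga, lp, message_kind, aggregate_kind)
        states.append(H)
    return states
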