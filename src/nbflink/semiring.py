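"""Exact generalized Bellman-Ford over pluggable semirings.

A semiring (⊕, ⊗, 0̄, 1̄) plugged into the Bellman-Ford recursion

    h⁰(u, v) = 1̄ if v == u else 0̄
    hᵗ(u, v) = [ ⊕ over incident edges (x, v) of hᵗ⁻¹(u, x) ⊗ w(x, v) ] ⊕ h⁰(u, v)

computes, for every target v, the ⊕-aggregation over all walks u→v of
length ≤ t of the ⊗-product of edge values along the walk.  Different
semirings recover the classical link-prediction scores: shortest path
(min/+), Katz (sum/product), widest path (max/min), most reliable path
(max/product) and personalized PageRank (damped sum/product).

The module also houses the brute-force walk-enumeration oracle used to
validate the dynamic program.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np

from .graph import GraphDataError, InteractionGraph

MAX_ENUMERATION_LEN = 8


class EnumerationRefusedError(ValueError):
    """Walk enumeration refused: exponential cost beyond the hard cap."""


@dataclass(frozen=True)
class Semiring:
    """A (⊕, ⊗, 0̄, 1̄) algebra for the generalized Bellman-Ford engine.

    ``plus`` must be commutative and associative, ``times`` associative and
    distributive over ``plus``; ``zero`` is the ⊕-identity and ⊗-annihilator,
    ``one`` the ⊗-identity.  ``times`` need not be commutative (matrix-valued
    edge representations are legal).
    """

    plus: Callable
    times: Callable
    zero: object
    one: object
    name: str = "semiring"


MIN_PLUS = Semiring(min, lambda a, b: a + b, math.inf, 0.0, "min_plus")
SUM_PRODUCT = Semiring(lambda a, b: a + b, lambda a, b: a * b, 0.0, 1.0, "sum_product")
MAX_MIN = Semiring(max, min, -math.inf, math.inf, "max_min")
MAX_TIMES = Semiring(max, lambda a, b: a * b, 0.0, 1.0, "max_times")


@dataclass
class PathScoreVector:
    """Source-conditioned scores h^(t)(u, ·) for every node of the graph."""

    source: str
    values: dict[str, object]
    iteration: int

    def __getitem__(self, node: str):
        return self.values[node]


def _edge_value(edge_values: Mapping, x: str, v: str):
    """Look up w(x, v) under either (x, v) or the undirected key."""
    for key in ((x, v), (v, x), frozenset((x, v))):
        if key in edge_values:
            return edge_values[key]
    raise GraphDataError(f"missing edge value for ({x!r}, {v!r})")


def generalized_bellman_ford(
    graph: InteractionGraph,
    source: str,
    sr: Semiring,
    edge_values: Mapping,
    T: int,
) -> PathScoreVector:
    """Run T iterations of the generalized Bellman-Ford recursion.

    Returns scores equal to the ⊕-aggregation over all walks of length ≤ T
    from ``source`` to each node.  Undirected edges are traversed in both
    directions with the same edge value.
    """
    if T < 0:
        raise ValueError(f"iteration count must be >= 0, got {T}")
    if not graph.has_node(source):
        raise GraphDataError(f"unknown source node {source!r}")

    h0 = {v: (sr.one if v == source else sr.zero) for v in graph.nodes}
    h = dict(h0)
    for _ in range(T):
        new = {}
        for v in graph.nodes:
            acc = h0[v]
            for (_, x) in graph.neighbors(v):
                acc = sr.plus(acc, sr.times(h[x], _edge_value(edge_values, x, v)))
            new[v] = acc
        h = new
    return PathScoreVector(source=source, values=h, iteration=T)


def enumerate_path_score(
    graph: InteractionGraph,
    u: str,
    v: str,
    sr: Semiring,
    edge_values: Mapping,
    max_len: int,
) -> object:
    """Brute-force oracle: ⊕ over all walks u→v of length ≤ max_len.

    Walks (repeated nodes allowed) are enumerated explicitly; each walk's
    representation is the ⊗-product of its edge values in traversal order.
    Cost is exponential in ``max_len``; lengths above 8 are refused.
    """
    if max_len > MAX_ENUMERATION_LEN:
        raise EnumerationRefusedError(
            f"max_len={max_len} exceeds enumeration cap {MAX_ENUMERATION_LEN}"
        )
    if max_len < 0:
        raise ValueError("max_len must be >= 0")
    for node in (u, v):
        if not graph.has_node(node):
            raise GraphDataError(f"unknown node {node!r}")

    acc = sr.one if u == v else sr.zero  # the empty walk, when admissible
    stack = [(u, sr.one, 0)]
    while stack:
        node, value, length = stack.pop()
        if length == max_len:
            continue
        for (_, nxt) in graph.neighbors(node):
            walk_val = sr.times(value, _edge_value(edge_values, node, nxt))
            if nxt == v:
                acc = sr.plus(acc, walk_val)
            stack.append((nxt, walk_val, length + 1))
    return acc


# ---------------------------------------------------------------------------
# Classical instantiations

CLASSIC_METHODS = (
    "katz",
    "personalized_pagerank",
    "graph_distance",
    "widest_path",
    "most_reliable_path",
)


def classic_link_score(
    graph: InteractionGraph,
    method: str,
    params: Mapping | None,
    source: str,
    T: int,
) -> PathScoreVector:
    """Classical link-prediction scores via the semiring engine.

    ``params`` per method: katz — ``beta`` (damping, default 0.05);
    personalized_pagerank — ``alpha`` (damping, default 0.85);
    graph_distance / widest_path / most_reliable_path — ``edge_values``
    mapping (defaults: unit lengths / unit capacities / must be given in
    [0, 1] for reliabilities, default 0.5).
    """
    params = dict(params or {})
    if method not in CLASSIC_METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {CLASSIC_METHODS}")

    edges = graph.edges
    if method == "katz":
        beta = float(params.get("beta", 0.05))
        max_deg = max((graph.degree(n) for n in graph.nodes), default=0)
        if beta * max_deg >= 1:
            warnings.warn(
                f"katz beta={beta} with max degree {max_deg} may not converge",
                stacklevel=2,
            )
        ev = {e: beta for e in edges}
        return generalized_bellman_ford(graph, source, SUM_PRODUCT, ev, T)

    if method == "graph_distance":
        ev = params.get("edge_values") or {e: 1.0 for e in edges}
        return generalized_bellman_ford(graph, source, MIN_PLUS, ev, T)

    if method == "widest_path":
        ev = params.get("edge_values") or {e: 1.0 for e in edges}
        return generalized_bellman_ford(graph, source, MAX_MIN, ev, T)

    if method == "most_reliable_path":
        ev = params.get("edge_values") or {e: 0.5 for e in edges}
        for e, p in ev.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"reliability {p} for edge {e} outside [0, 1]")
        return generalized_bellman_ford(graph, source, MAX_TIMES, ev, T)

    # personalized PageRank: damped sum-product walk aggregation with
    # degree-normalized transition values; the restart mass (1 - alpha)
    # scales the whole walk sum.
    alpha = float(params.get("alpha", 0.85))
    ev = {
        (x, v): alpha / graph.degree(x)
        for x, v in _both_directions(edges)
    }
    res = generalized_bellman_ford(graph, source, SUM_PRODUCT, ev, T)
    res.values = {v: (1.0 - alpha) * val for v, val in res.values.items()}
    return res


def _both_directions(edges):
    for u, v in edges:
        yield u, v
        yield v, u


def ppr_edge_values(graph: InteractionGraph, alpha: float) -> dict:
    """Directed damped transition values α / deg(x) for each arc (x, v)."""
    return {
        (x, v): alpha / graph.degree(x) for x, v in _both_directions(graph.edges)
    }


def katz_closed_form(graph: InteractionGraph, beta: float) -> np.ndarray:
    """Exact Katz matrix (I − βA)⁻¹ − I under the graph's stable node index.

    Oracle/test helper: valid when β is below the spectral-radius bound.
    """
    A = graph.adjacency_csr().toarray()
    n = A.shape[0]
    return np.linalg.inv(np.eye(n) - beta * A) - np.eye(n)
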