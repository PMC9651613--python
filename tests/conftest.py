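import numpy as np
import pytest

from nbflink.graph import DNA, PROTEIN, InteractionGraph, LinkExample


def make_graph(nodes, edges):
    """Build an InteractionGraph from [(id, class)] and [(u, v)] lists."""
    g = InteractionGraph()
    for n, c in nodes:
        g.add_node(n, c)
    for u, v in edges:
        g.add_edge(u, v)
    return g


def random_graph(rng, n_nodes=6, max_edges=12):
    """Random small connected-ish graph with alternating node classes."""
    names = [f"n{i}" for i in range(n_nodes)]
    g = InteractionGraph()
    for i, n in enumerate(names):
        g.add_node(n, DNA if i % 2 == 0 else PROTEIN)
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    k = int(rng.integers(1, min(max_edges, len(pairs)) + 1))
    chosen = rng.choice(len(pairs), size=k, replace=False)
    for c in chosen:
        g.add_edge(*pairs[c])
    return g


def random_edge_values(rng, graph, low=0.1, high=0.9):
    return {e: float(rng.uniform(low, high)) for e in graph.edges}


@pytest.fixture
def triangle():
    """Triangle a-b, b-c, a-c with unit-ish weights used across modules."""
    return make_graph(
        [("a", DNA), ("b", PROTEIN), ("c", DNA)],
        [("a", "b"), ("b", "c"), ("a", "c")],
    )


@pytest.fixture
def path_graph():
    return make_graph(
        [("a", DNA), ("b", PROTEIN), ("c", DNA)],
        [("a", "b"), ("b", "c")],
    )


@pytest.fixture
def bipartite_toy():
    """Small planted bipartite graph for model-level tests."""
    from nbflink.synthetic import generate

    return generate(n_dna=12, n_protein=12, f=3, density=0.15, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
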