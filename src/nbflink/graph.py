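"""Interaction-graph data model, TSV/FASTA I/O, negative sampling and CV splitting.

The graph is a homogeneous undirected graph over DNA and protein vertices
with a single relation type ("binds").  Node identity is an opaque string;
a stable dense index (insertion order) is maintained for array-based code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

DNA = "DNA"
PROTEIN = "PROTEIN"
_CLASSES = (DNA, PROTEIN)

EDGE_TSV_COLUMNS = ["node_a", "class_a", "node_b", "class_b", "label"]


class GraphDataError(ValueError):
    """Malformed or inconsistent interaction-graph input."""


class CorruptionExhaustedError(RuntimeError):
    """No admissible corrupted negative exists for a positive pair."""


@dataclass(frozen=True)
class LinkExample:
    """A candidate link (u, v) with binary label: 1 = binding, 0 = no binding."""

    u: str
    v: str
    label: int

    def __post_init__(self) -> None:
        if self.u == self.v:
            raise GraphDataError(f"self-loop example ({self.u!r}, {self.v!r})")
        if self.label not in (0, 1):
            raise GraphDataError(f"label must be 0/1, got {self.label!r}")

    def key(self) -> frozenset:
        return frozenset((self.u, self.v))


@dataclass
class DatasetSplit:
    """One cross-validation fold: disjoint train and test example lists."""

    train: list[LinkExample]
    test: list[LinkExample]
    fold_index: int

    def __post_init__(self) -> None:
        overlap = {(e.u, e.v, e.label) for e in self.train} & {
            (e.u, e.v, e.label) for e in self.test
        }
        if overlap:
            raise GraphDataError(f"train/test overlap in fold {self.fold_index}: {overlap}")


class InteractionGraph:
    """Undirected homogeneous graph of DNA and protein vertices.

    Backed by a :class:`networkx.Graph`; node class labels live in the
    ``node_class`` node attribute.  Insertion order of nodes defines the
    stable dense indexing used by the numeric engines.
    """

    def __init__(self) -> None:
        self._g = nx.Graph()

    # -- construction -------------------------------------------------
    def add_node(self, node: str, node_class: str) -> None:
        if node_class not in _CLASSES:
            raise GraphDataError(f"unknown node class {node_class!r} for {node!r}")
        if node in self._g:
            existing = self._g.nodes[node]["node_class"]
            if existing != node_class:
                raise GraphDataError(
                    f"node {node!r} redeclared with class {node_class!r} != {existing!r}"
                )
            return
        self._g.add_node(node, node_class=node_class)

    def add_edge(self, u: str, v: str) -> None:
        if u == v:
            raise GraphDataError(f"self-loop edge ({u!r}, {v!r})")
        for n in (u, v):
            if n not in self._g:
                raise GraphDataError(f"edge endpoint {n!r} not a known node")
        self._g.add_edge(u, v)

    def remove_edges(self, pairs: Iterable[tuple[str, str]]) -> None:
        for u, v in pairs:
            if self._g.has_edge(u, v):
                self._g.remove_edge(u, v)

    def copy(self) -> "InteractionGraph":
        out = InteractionGraph()
        out._g = self._g.copy()
        return out

    # -- queries ------------------------------------------------------
    @property
    def relation_count(self) -> int:
        return 1

    @property
    def nodes(self) -> list[str]:
        return list(self._g.nodes)

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def edges(self) -> list[tuple[str, str]]:
        return [tuple(e) for e in self._g.edges]

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def node_class(self, node: str) -> str:
        try:
            return self._g.nodes[node]["node_class"]
        except KeyError:
            raise GraphDataError(f"unknown node {node!r}") from None

    def nodes_of_class(self, node_class: str) -> list[str]:
        return [n for n, c in self._g.nodes(data="node_class") if c == node_class]

    def has_node(self, node: str) -> bool:
        return node in self._g

    def has_edge(self, u: str, v: str) -> bool:
        return self._g.has_edge(u, v)

    def neighbors(self, u: str) -> set[tuple[tuple[str, str], str]]:
        """Incident edges and opposite endpoints of ``u``: E(u) and N(u)."""
        if u not in self._g:
            raise GraphDataError(f"unknown node {u!r}")
        return {((u, v), v) for v in self._g.neighbors(u)}

    def degree(self, u: str) -> int:
        if u not in self._g:
            raise GraphDataError(f"unknown node {u!r}")
        return self._g.degree[u]

    def node_index(self) -> dict[str, int]:
        """Stable node -> dense index map (insertion order)."""
        return {n: i for i, n in enumerate(self._g.nodes)}

    def adjacency_csr(self):
        """Symmetric {0,1} adjacency in CSR form under the stable index."""
        import scipy.sparse as sp

        idx = self.node_index()
        n = self.n_nodes
        rows, cols = [], []
        for u, v in self._g.edges:
            rows += [idx[u], idx[v]]
            cols += [idx[v], idx[u]]
        data = np.ones(len(rows))
        return sp.csr_matrix((data, (rows, cols)), shape=(n, n))

    def __iter__(self) -> Iterator[str]:
        return iter(self._g.nodes)


# ---------------------------------------------------------------------------
# TSV I/O


def read_edge_tsv(
    path, *, dedup: bool = True
) -> tuple[InteractionGraph, list[LinkExample]]:
    """Read an edge-list TSV into a graph plus labelled link examples.

    Columns: ``node_a  class_a  node_b  class_b  label`` (tab-separated,
    header required).  Rows with label 1 become graph edges; every row
    becomes a :class:`LinkExample`.  Duplicate edge rows are collapsed when
    ``dedup`` is true and rejected otherwise.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error passthrough
        raise GraphDataError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in EDGE_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise GraphDataError(f"{path}: missing columns {missing}")

    graph = InteractionGraph()
    examples: list[LinkExample] = []
    seen_edges: set[frozenset] = set()
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        try:
            label = int(row.label)
            if label not in (0, 1):
                raise ValueError(f"label {row.label!r} not in {{0,1}}")
            if any(pd.isna(x) for x in row):
                raise ValueError("missing field")
            graph.add_node(str(row.node_a), str(row.class_a))
            graph.add_node(str(row.node_b), str(row.class_b))
            ex = LinkExample(str(row.node_a), str(row.node_b), label)
        except (ValueError, GraphDataError) as exc:
            raise GraphDataError(f"{path}: line {lineno}: {exc}") from exc
        examples.append(ex)
        if label == 1:
            if ex.key() in seen_edges and not dedup:
                raise GraphDataError(f"{path}: line {lineno}: duplicate edge {ex.u}-{ex.v}")
            seen_edges.add(ex.key())
            graph.add_edge(ex.u, ex.v)
    return graph, examples


def write_edge_tsv(path, graph: InteractionGraph, examples: list[LinkExample]) -> None:
    """Write examples back to the edge TSV format read by :func:`read_edge_tsv`."""
    rows = [
        {
            "node_a": e.u,
            "class_a": graph.node_class(e.u),
            "node_b": e.v,
            "class_b": graph.node_class(e.v),
            "label": e.label,
        }
        for e in examples
    ]
    pd.DataFrame(rows, columns=EDGE_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_fasta_features(path) -> dict[str, str]:
    """Record id -> sequence from a FASTA file (ids must match node ids)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# Negative sampling and CV splitting


def corrupt_negative(
    graph: InteractionGraph,
    pos: LinkExample,
    rng: np.random.Generator,
    *,
    forbidden: set[frozenset] | None = None,
) -> LinkExample:
    """Corrupt one endpoint of a positive pair into a negative example.

    The side to corrupt is chosen by a fair coin; the replacement is drawn
    uniformly among nodes of the same class whose substitution does not
    recreate a known positive edge (or a pair in ``forbidden``).  Raises
    :class:`CorruptionExhaustedError` when no admissible corruption exists.
    """
    if pos.label != 1:
        raise GraphDataError("can only corrupt a positive example")
    forbidden = forbidden or set()

    sides = [0, 1] if rng.random() < 0.5 else [1, 0]
    for side in sides:
        kept, replaced = (pos.v, pos.u) if side == 0 else (pos.u, pos.v)
        cls = graph.node_class(replaced)
        candidates = [
            c
            for c in graph.nodes_of_class(cls)
            if c != replaced
            and c != kept
            and not graph.has_edge(kept, c)
            and frozenset((kept, c)) not in forbidden
        ]
        if not candidates:
            continue
        pick = candidates[int(rng.integers(len(candidates)))]
        u, v = (pick, kept) if side == 0 else (kept, pick)
        return LinkExample(u, v, 0)
    raise CorruptionExhaustedError(f"no admissible corruption for ({pos.u}, {pos.v})")


def kfold_split(
    examples: list[LinkExample], k: int, rng: np.random.Generator
) -> list[DatasetSplit]:
    """Stratified k-fold split over link examples (labels balanced per fold)."""
    if k < 2:
        raise GraphDataError(f"k must be >= 2, got {k}")
    if k > len(examples):
        raise GraphDataError(f"k={k} exceeds number of examples ({len(examples)})")
    labels = np.array([e.label for e in examples])
    seed = int(rng.integers(2**31 - 1))
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    splits = []
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(examples)), labels)):
        splits.append(
            DatasetSplit(
                train=[examples[i] for i in tr],
                test=[examples[i] for i in te],
                fold_index=fold,
            )
        )
    return splits


def message_passing_graph(
    graph: InteractionGraph, test_examples: list[LinkExample]
) -> InteractionGraph:
    """Copy of ``graph`` with test-fold positive edges removed (leakage hygiene)."""
    out = graph.copy()
    out.remove_edges([(e.u, e.v) for e in test_examples if e.label == 1])
    return out
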