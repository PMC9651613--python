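"""The full DPB-NBFnet link classifier.

Architecture (per candidate pair (u, v), conditioned on source u):

1. Indicator writes the learned query embedding on row u (boundary h⁰).
2. Three feature-extraction modules, each = NBFnet layers → leaky ReLU
   (slope 0.2) → SortPooling over the pair's enclosing context (nodes
   within two hops of u or v), giving a K × d matrix per module.
3. Each pooled matrix is reduced by its own AlphaMEX global pool; the
   addition module sums the three d-vectors.
4. The summed pool is concatenated with the source-conditioned state of
   the target node, h(u, v), from the final module, then passed through
   fully connected layers of 256, 64 and 2 units (leaky ReLU between),
   and a jointly computed log-softmax yields (log p₊, log p₋).

Training minimizes the mean negative log-likelihood over positive pairs
plus freshly corrupted negatives each epoch (Adam, deterministic given
the seed).  The estimator follows the scikit-learn protocol: ``fit(X, y)``
with X an array/list of (u, v) node-id pairs, ``predict_proba`` columns
ordered as classes ``[0, 1]``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import autodiff as ad
from .autodiff import Adam, Tensor
from .graph import (
    CorruptionExhaustedError,
    GraphDataError,
    InteractionGraph,
    LinkExample,
    corrupt_negative,
)
from .layers import GraphArrays, LayerParams, indicator, nbf_layer
from .pooling import AlphaParameter, rank_context_rows, sort_pool_batch, alphamex_t

LEAKY_SLOPE = 0.2
FC_WIDTHS = (256, 64, 2)
CONTEXT_HOPS = 2


@dataclass
class PredictionPair:
    """Log-probabilities (log p₊, log p₋) for one candidate pair."""

    log_p_pos: float
    log_p_neg: float


def nll_loss(preds: list[PredictionPair], labels) -> float:
    """Mean negative log-likelihood of labelled predictions."""
    labels = list(labels)
    if len(preds) != len(labels):
        raise ValueError(f"length mismatch: {len(preds)} preds vs {len(labels)} labels")
    if not preds:
        raise ValueError("empty prediction list")
    total = 0.0
    for p, l in zip(preds, labels):
        total += l * p.log_p_pos + (1 - l) * p.log_p_neg
    return -total / len(preds)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    lim = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape)


class DPBNBFnet(BaseEstimator, ClassifierMixin):
    """Path-based graph neural link predictor for DNA-protein binding.

    Parameters
    ----------
    graph : InteractionGraph
        The interaction graph used for message passing.  Candidate pairs in
        ``fit``/``predict`` must reference its nodes (transductive setting).
    hidden_dim : int
        Width d of node states and edge representations.
    message : {'distmult', 'transe', 'rotate'}
        MESSAGE function combining neighbor state and edge representation.
    aggregate : {'sum', 'mean', 'max'}
        AGGREGATE reduction over incident messages plus the boundary term.
    module_layers : tuple of int
        NBFnet layers in each of the three feature-extraction modules.
    sortpool_k : int
        Rows kept by SortPooling.
    alpha_init : float
        Initial AlphaMEX α, strictly inside (0.5, 1).
    epochs, lr, batch_size, negatives_per_positive : training knobs.
    random_state : int
        Seeds initialization and all sampling; runs are bit-reproducible.
    """

    def __init__(
        self,
        graph: InteractionGraph | None = None,
        hidden_dim: int = 32,
        message: str = "distmult",
        aggregate: str = "sum",
        module_layers: tuple[int, ...] = (2, 2, 2),
        sortpool_k: int = 10,
        alpha_init: float = 0.9,
        epochs: int = 30,
        lr: float = 1e-3,
        batch_size: int = 32,
        negatives_per_positive: int = 1,
        leaky_slope: float = LEAKY_SLOPE,
        random_state: int = 0,
    ):
        self.graph = graph
        self.hidden_dim = hidden_dim
        self.message = message
        self.aggregate = aggregate
        self.module_layers = module_layers
        self.sortpool_k = sortpool_k
        self.alpha_init = alpha_init
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.negatives_per_positive = negatives_per_positive
        self.leaky_slope = leaky_slope
        self.random_state = random_state

    # -- parameters ---------------------------------------------------
    def _init_params(self, rng: np.random.Generator) -> None:
        d = self.hidden_dim
        # multiplicative messages compound like walk counts (~mean degree per
        # hop); start edge magnitudes near 1/deg so states stay O(1) at init
        mean_deg = float(self.ga_.deg.mean()) if hasattr(self, "ga_") else 1.0
        edge_mu = 1.0 / max(1.0, mean_deg)
        if self.message == "rotate" and d % 2:
            raise ValueError("RotatE requires an even hidden_dim")
        e_dim = d // 2 if self.message == "rotate" else d
        self.params_: dict[str, Tensor] = {}
        self.params_["q"] = Tensor(rng.normal(0.0, 1.0, size=d), requires_grad=True)
        self.modules_: list[list[LayerParams]] = []
        self.alphas_: list[AlphaParameter] = []
        for m, n_layers in enumerate(self.module_layers):
            layers = []
            for l in range(n_layers):
                if self.message == "rotate":
                    edge = Tensor(rng.uniform(-math.pi, math.pi, e_dim), requires_grad=True)
                elif self.message == "transe":
                    edge = Tensor(rng.normal(0.0, 0.1, e_dim), requires_grad=True)
                else:
                    edge = Tensor(
                        rng.normal(edge_mu, 0.1 * edge_mu, e_dim), requires_grad=True
                    )
                W = Tensor(np.eye(d) + _glorot(rng, d, d, (d, d)) * 0.1, requires_grad=True)
                b = Tensor(np.zeros(d), requires_grad=True)
                lp = LayerParams(edge=edge, W=W, b=b)
                layers.append(lp)
                self.params_[f"m{m}l{l}_edge"] = edge
                self.params_[f"m{m}l{l}_W"] = W
                self.params_[f"m{m}l{l}_b"] = b
            self.modules_.append(layers)
            alpha = AlphaParameter(self.alpha_init)
            self.alphas_.append(alpha)
            self.params_[f"m{m}_alpha_theta"] = alpha.theta
        widths = (2 * d,) + FC_WIDTHS
        for i in range(len(FC_WIDTHS)):
            fi, fo = widths[i], widths[i + 1]
            self.params_[f"fc{i}_W"] = Tensor(_glorot(rng, fi, fo, (fi, fo)), requires_grad=True)
            self.params_[f"fc{i}_b"] = Tensor(np.zeros(fo), requires_grad=True)

    # -- graph plumbing -----------------------------------------------
    def _prepare_graph(self, graph: InteractionGraph) -> None:
        self.graph_ = graph
        self.ga_ = GraphArrays.from_graph(graph)
        self.node_index_ = self.ga_.index
        A = self.ga_.A.astype(bool)
        reach = sp.identity(graph.n_nodes, dtype=bool, format="csr")
        hop = reach
        for _ in range(CONTEXT_HOPS):
            hop = (A @ hop).astype(bool)
            reach = (reach + hop).astype(bool)
        self._reach_ = reach.toarray()

    def _pair_indices(self, X) -> tuple[np.ndarray, np.ndarray]:
        us, vs = [], []
        for u, v in X:
            for n in (u, v):
                if n not in self.node_index_:
                    raise GraphDataError(f"unknown node {n!r} in candidate pair")
            us.append(self.node_index_[u])
            vs.append(self.node_index_[v])
        return np.array(us, dtype=np.int64), np.array(vs, dtype=np.int64)

    def _masked_graph_arrays(self, src_idx, dst_idx, labels) -> GraphArrays:
        """Adjacency with the batch's own positive edges hidden.

        During training each positive query edge is removed from its own
        batch's message-passing graph, otherwise the model learns to read
        off first-hop adjacency and cannot generalize to held-out links.
        """
        V = self.graph_.n_nodes
        keys = self.ga_.src * V + self.ga_.dst
        drop = set()
        for u, v, l in zip(src_idx, dst_idx, labels):
            if l == 1:
                drop.add(int(u) * V + int(v))
                drop.add(int(v) * V + int(u))
        if not drop:
            return self.ga_
        keep = ~np.isin(keys, np.fromiter(drop, dtype=np.int64))
        src, dst = self.ga_.src[keep], self.ga_.dst[keep]
        A = sp.csr_matrix(
            (np.ones(len(src)), (dst, src)), shape=(V, V)
        )
        deg = np.asarray(A.sum(axis=1)).ravel()
        return GraphArrays(A=A, deg=deg, src=src, dst=dst, index=self.ga_.index)

    # -- forward ------------------------------------------------------
    def _forward_batch(
        self, src_idx: np.ndarray, dst_idx: np.ndarray, ga: GraphArrays | None = None
    ) -> Tensor:
        """Log-probabilities (B, 2) as columns [log p₋, log p₊]."""
        ga = ga if ga is not None else self.ga_
        B = len(src_idx)
        q = self.params_["q"]
        h0 = ad.indicator_state(q, src_idx, self.graph_.n_nodes)
        ctx = self._reach_[src_idx] | self._reach_[dst_idx]  # (B, V)
        # u and v always belong to their own context
        ctx[np.arange(B), src_idx] = True
        ctx[np.arange(B), dst_idx] = True

        H = h0
        pooled_vecs = []
        for layers, alpha in zip(self.modules_, self.alphas_):
            for lp in layers:
                H = nbf_layer(H, h0, ga, lp, self.message, self.aggregate)
            H = H.leaky_relu(self.leaky_slope)
            idx, valid = rank_context_rows(H.data, ctx, self.sortpool_k)
            pooled = sort_pool_batch(H, idx, valid)  # (B, K, d)
            pooled_vecs.append(alphamex_t(pooled, alpha, axis=-2))  # (B, d)
        added = pooled_vecs[0]
        for p in pooled_vecs[1:]:
            added = added + p
        target = H[np.arange(B), dst_idx]  # (B, d) source-conditioned h(u,v)
        z = ad.concat([added, target], axis=-1)
        for i in range(len(FC_WIDTHS)):
            z = ad.linear(z, self.params_[f"fc{i}_W"], self.params_[f"fc{i}_b"])
            if i < len(FC_WIDTHS) - 1:
                z = z.leaky_relu(self.leaky_slope)
        return z - z.logsumexp(axis=-1, keepdims=True)

    def _batch_loss(self, src, dst, labels, ga=None) -> Tensor:
        logp = self._forward_batch(src, dst, ga)
        lab = np.asarray(labels, dtype=np.int64)
        picked = logp[np.arange(len(lab)), lab]  # column 1 = positive class
        return -picked.mean()

    # -- scikit-learn surface -----------------------------------------
    def fit(self, X, y, graph: InteractionGraph | None = None) -> "DPBNBFnet":
        """Train on candidate pairs X (list of (u, v)) with binary labels y.

        The message-passing graph is ``graph`` if given, else the
        constructor's; callers are responsible for excluding held-out
        positive edges from it (see ``train_eval.train``).
        """
        g = graph if graph is not None else self.graph
        if g is None:
            raise ValueError("a message-passing graph is required")
        X = list(map(tuple, X))
        y = np.asarray(y, dtype=np.int64)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        positives = [LinkExample(u, v, 1) for (u, v), l in zip(X, y) if l == 1]
        if not positives:
            raise ValueError("training requires at least one positive example")

        self._prepare_graph(g)
        rng = np.random.default_rng(self.random_state)
        self._init_params(rng)
        self.classes_ = np.array([0, 1])
        known_pos = {frozenset((e.u, e.v)) for e in positives}

        opt = Adam(self.params_, lr=self.lr)
        self.loss_trace_ = []
        for _ in range(self.epochs):
            examples: list[LinkExample] = list(positives)
            for pos in positives:
                for _k in range(self.negatives_per_positive):
                    try:
                        examples.append(
                            corrupt_negative(g, pos, rng, forbidden=known_pos)
                        )
                    except CorruptionExhaustedError:
                        pass
            order = rng.permutation(len(examples))
            src_all, dst_all = self._pair_indices([(e.u, e.v) for e in examples])
            lab_all = np.array([e.label for e in examples], dtype=np.int64)
            epoch_loss = 0.0
            for start in range(0, len(order), self.batch_size):
                take = order[start : start + self.batch_size]
                ga = self._masked_graph_arrays(
                    src_all[take], dst_all[take], lab_all[take]
                )
                if self.lr == 0.0:
                    # zero step size: trace the loss without touching params
                    loss = self._batch_loss(src_all[take], dst_all[take], lab_all[take], ga)
                    epoch_loss += float(loss.data) * len(take)
                    continue
                opt.zero_grad()
                loss = self._batch_loss(src_all[take], dst_all[take], lab_all[take], ga)
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"training diverged: loss={float(loss.data)} at step {opt.t}"
                    )
                loss.backward()
                opt.step()
                epoch_loss += float(loss.data) * len(take)
            self.loss_trace_.append(epoch_loss / len(order))
        return self

    def predict_log_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "params_")
        X = list(map(tuple, X))
        out = np.zeros((len(X), 2))
        for start in range(0, len(X), max(self.batch_size, 64)):
            chunk = X[start : start + max(self.batch_size, 64)]
            src, dst = self._pair_indices(chunk)
            out[start : start + len(chunk)] = self._forward_batch(src, dst).data
        return out

    def predict_proba(self, X) -> np.ndarray:
        return np.exp(self.predict_log_proba(X))

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def decision_function(self, X) -> np.ndarray:
        lp = self.predict_log_proba(X)
        return lp[:, 1] - lp[:, 0]

    # -- single-pair conveniences -------------------------------------
    def forward_pair(self, pair: LinkExample | tuple[str, str]) -> PredictionPair:
        """Single-pair forward pass returning (log p₊, log p₋)."""
        u, v = (pair.u, pair.v) if isinstance(pair, LinkExample) else pair
        lp = self.predict_log_proba([(u, v)])[0]
        return PredictionPair(log_p_pos=float(lp[1]), log_p_neg=float(lp[0]))


def forward(graph: InteractionGraph, pair, model: DPBNBFnet) -> PredictionPair:
    """Functional face of the estimator's forward pass for one pair."""
    if graph is not model.graph_:
        raise ValueError("model was fitted on a different graph")
    return model.forward_pair(pair)
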