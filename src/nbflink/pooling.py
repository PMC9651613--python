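"""Graph read-out layers: SortPooling and the AlphaMEX log-mean-exp pool.

SortPooling produces a fixed-size K × d matrix by sorting node rows on a
continuous Weisfeiler-Lehman-style color — here the last feature channel,
ties broken by the preceding channels right-to-left and finally by the
stable canonical node order — keeping the top K rows and zero-padding.

AlphaMEX is a trainable global pool: per channel,

    AlphaMEX_α(h) = 1/log(α/(1−α)) · log( (1/n) Σ_i (α/(1−α))^{h_i} )

which interpolates smoothly toward the channel maximum as α → 1.  α is
kept strictly inside (0.5, 1): at α = 0.5 the normalizer log(α/(1−α))
vanishes and below it the pool flips toward a soft minimum, so only the
soft-max branch is exposed.  Internally the sum is evaluated in log-space
with a max-shift for overflow safety.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

ALPHA_LOW, ALPHA_HIGH = 0.5, 1.0


class AlphaParameter:
    """Unconstrained scalar θ realizing α = 0.5 + 0.5·σ(θ) ∈ (0.5, 1)."""

    def __init__(self, alpha_init: float = 0.9):
        if not ALPHA_LOW < alpha_init < ALPHA_HIGH:
            raise ValueError(f"alpha_init must lie in (0.5, 1), got {alpha_init}")
        # invert the squash for the requested initial value
        s = (alpha_init - 0.5) / 0.5
        self.theta = Tensor(np.log(s / (1.0 - s)), requires_grad=True)

    def alpha_tensor(self) -> Tensor:
        return self.theta.sigmoid() * 0.5 + 0.5

    @property
    def alpha(self) -> float:
        return float(self.alpha_tensor().data)


def sort_indices(states: np.ndarray) -> np.ndarray:
    """Row order: descending last channel, ties by earlier channels, stable."""
    keys = tuple(-states[:, j] for j in range(states.shape[1]))
    return np.lexsort(keys)  # last key (= last channel) is primary


def sort_pooling(states: np.ndarray, K: int) -> np.ndarray:
    """Select the top-K rows by continuous WL color; zero-pad if K > N."""
    states = np.asarray(states, dtype=float)
    if states.ndim != 2 or states.shape[0] < 1:
        raise ValueError("sort_pooling requires a nonempty N x d matrix")
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    order = sort_indices(states)
    out = states[order[:K]]
    if out.shape[0] < K:
        pad = np.zeros((K - out.shape[0], states.shape[1]))
        out = np.vstack([out, pad])
    return out


def alphamex(states, alpha) -> np.ndarray:
    """AlphaMEX global pool of an M × d matrix down to a d-vector (numpy)."""
    states = np.asarray(states, dtype=float)
    if states.ndim != 2 or states.shape[0] < 1:
        raise ValueError("alphamex requires a nonempty M x d matrix")
    a = alpha.alpha if isinstance(alpha, AlphaParameter) else float(alpha)
    if not ALPHA_LOW < a < ALPHA_HIGH:
        raise ValueError(f"alpha must lie in (0.5, 1), got {a}")
    log_r = np.log(a) - np.log1p(-a)  # log(α/(1−α)) > 0
    z = states * log_r
    m = z.max(axis=0)
    lse = np.log(np.exp(z - m).sum(axis=0)) + m
    return (lse - np.log(states.shape[0])) / log_r


def alphamex_t(states: Tensor, alpha: AlphaParameter, axis: int = -2) -> Tensor:
    """Differentiable AlphaMEX over one axis of a batched tensor."""
    a = alpha.alpha_tensor()
    log_r = a.log() - (1.0 - a).log()
    n = states.shape[axis]
    z = states * log_r
    lse = z.logsumexp(axis=axis)
    return (lse - np.log(n)) / log_r


def sort_pool_batch(states: Tensor, ctx_idx: np.ndarray, ctx_valid: np.ndarray) -> Tensor:
    """Batched SortPooling over per-example context node sets.

    ``ctx_idx`` (B, K) holds, per example, the indices of the K context
    rows ranked by WL color (already resolved from the forward values);
    ``ctx_valid`` (B, K) flags real rows, the rest are zero padding.
    """
    pooled = ad.stack_rows(states, ctx_idx)
    return pooled * ctx_valid[:, :, None]


def rank_context_rows(
    values: np.ndarray, ctx_mask: np.ndarray, K: int
) -> tuple[np.ndarray, np.ndarray]:
    """Resolve SortPooling row selection outside the autodiff tape.

    ``values`` (B, V, d) are the forward state values, ``ctx_mask`` (B, V)
    flags each example's context nodes.  Returns top-K context indices by
    the canonical sort key and a validity mask for zero padding.
    """
    B, V, d = values.shape
    idx = np.zeros((B, K), dtype=np.int64)
    valid = np.zeros((B, K), dtype=float)
    for b in range(B):
        rows = np.nonzero(ctx_mask[b])[0]
        order = sort_indices(values[b, rows])
        take = rows[order[:K]]
        idx[b, : len(take)] = take
        valid[b, : len(take)] = 1.0
    return idx, valid
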