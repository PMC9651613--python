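"""Minimal reverse-mode automatic differentiation over numpy arrays.

A small tape-based engine sized to what the model needs: broadcasting
arithmetic, dense/sparse matrix products, indexing with gradient
scatter-add, stable log-sum-exp, leaky ReLU, sigmoid and segment max.
Float64 throughout; everything runs on one CPU core deterministically.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple["Tensor", ...] = ()
        self._backward = None

    # -- bookkeeping --------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        """Backpropagate from a scalar output through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- helpers ------------------------------------------------------
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad or p._parents for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    # -- arithmetic ---------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)

        def bw(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(g, other.data.shape))

        return self._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accumulate(-g)

        return self._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def bw(g):
            self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return self._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)

        def bw(g):
            self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            other._accumulate(
                _unbroadcast(-g * self.data / other.data**2, other.data.shape)
            )

        return self._make(self.data / other.data, (self, other), bw)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __getitem__(self, key):
        def bw(g):
            buf = np.zeros_like(self.data)
            np.add.at(buf, key, g)
            self._accumulate(buf)

        return self._make(self.data[key], (self,), bw)

    # -- reductions & elementwise ------------------------------------
    def sum(self, axis=None, keepdims=False):
        def bw(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            self._accumulate(g * out_data)

        return self._make(out_data, (self,), bw)

    def log(self):
        def bw(g):
            self._accumulate(g / self.data)

        return self._make(np.log(self.data), (self,), bw)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            self._accumulate(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), bw)

    def leaky_relu(self, slope: float = 0.2):
        mask = np.where(self.data > 0, 1.0, slope)

        def bw(g):
            self._accumulate(g * mask)

        return self._make(self.data * mask, (self,), bw)

    def logsumexp(self, axis: int, keepdims: bool = False):
        m = np.max(self.data, axis=axis, keepdims=True)
        m = np.where(np.isfinite(m), m, 0.0)
        e = np.exp(self.data - m)
        s = e.sum(axis=axis, keepdims=True)
        out_data = np.log(s) + m
        soft = e / s

        def bw(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(g * soft)

        return self._make(
            out_data if keepdims else np.squeeze(out_data, axis), (self,), bw
        )

    def reshape(self, *shape):
        old = self.data.shape

        def bw(g):
            self._accumulate(g.reshape(old))

        return self._make(self.data.reshape(*shape), (self,), bw)


# ---------------------------------------------------------------------------
# Free functions


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(a, b)
            t._accumulate(g[tuple(idx)])

    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    out.requires_grad = True
    out._parents = tuple(tensors)
    out._backward = bw
    return out


def maximum(a: Tensor, b: Tensor) -> Tensor:
    a, b = Tensor._wrap(a), Tensor._wrap(b)
    take_a = a.data >= b.data  # ties route to the first argument

    def bw(g):
        a._accumulate(_unbroadcast(g * take_a, a.data.shape))
        b._accumulate(_unbroadcast(g * (~take_a), b.data.shape))

    return a._make(np.maximum(a.data, b.data), (a, b), bw)


def linear(x: Tensor, W: Tensor, b: Tensor | None = None) -> Tensor:
    """x @ W (+ b) with x of shape (..., in) and W of shape (in, out)."""
    out_data = x.data @ W.data
    if b is not None:
        out_data = out_data + b.data

    def bw(g):
        x._accumulate(g @ W.data.T)
        axes = tuple(range(g.ndim - 1))
        W._accumulate(np.tensordot(x.data, g, axes=(axes, axes)))
        if b is not None:
            b._accumulate(g.sum(axis=axes))

    parents = (x, W) if b is None else (x, W, b)
    return x._make(out_data, parents, bw)


def spmm_nodes(A, x: Tensor) -> Tensor:
    """Sparse adjacency product along the node axis of a (B, V, d) tensor.

    Computes y[b, v] = Σ_x A[v, x] · x[b, x]; the gradient flows through
    Aᵀ.  ``A`` is a constant scipy.sparse matrix.
    """
    B, V, d = x.data.shape
    flat = x.data.transpose(1, 0, 2).reshape(V, B * d)
    y = (A @ flat).reshape(V, B, d).transpose(1, 0, 2)

    def bw(g):
        gf = g.transpose(1, 0, 2).reshape(V, B * d)
        gx = (A.T @ gf).reshape(V, B, d).transpose(1, 0, 2)
        x._accumulate(gx)

    return x._make(y, (x,), bw)


def indicator_state(q: Tensor, src_idx: np.ndarray, n_nodes: int) -> Tensor:
    """Batched boundary condition: zeros everywhere, q at each source row."""
    B = len(src_idx)
    d = q.data.shape[0]
    out_data = np.zeros((B, n_nodes, d))
    out_data[np.arange(B), src_idx] = q.data

    def bw(g):
        q._accumulate(g[np.arange(B), src_idx].sum(axis=0))

    return q._make(out_data, (q,), bw)


def segment_max_messages(
    msgs: Tensor, dst: np.ndarray, boundary: Tensor
) -> Tensor:
    """Per-node elementwise max of incident-edge messages and the boundary.

    ``msgs`` has shape (B, E, d) with destination node ``dst[e]`` per edge;
    ``boundary`` has shape (B, V, d) and participates in every node's max.
    Gradient routes to the unique argmax entry (boundary wins ties).
    """
    B, E, d = msgs.data.shape
    V = boundary.data.shape[1]
    out_data = boundary.data.copy()
    # argmax bookkeeping: -1 means the boundary term
    arg = np.full((B, V, d), -1, dtype=np.int64)
    for e in range(E):
        v = dst[e]
        better = msgs.data[:, e, :] > out_data[:, v, :]
        out_data[:, v, :] = np.where(better, msgs.data[:, e, :], out_data[:, v, :])
        arg[:, v, :] = np.where(better, e, arg[:, v, :])

    def bw(g):
        gb = np.where(arg == -1, g, 0.0)
        boundary._accumulate(gb)
        gm = np.zeros_like(msgs.data)
        b_i, v_i, d_i = np.nonzero(arg >= 0)
        gm[b_i, arg[b_i, v_i, d_i], d_i] += g[b_i, v_i, d_i]
        msgs._accumulate(gm)

    return msgs._make(out_data, (msgs, boundary), bw)


def stack_rows(x: Tensor, row_idx: np.ndarray) -> Tensor:
    """Gather rows (B, K) from a (B, V, d) tensor -> (B, K, d)."""
    B = x.data.shape[0]
    key = (np.arange(B)[:, None], row_idx)
    return x[key]


class Adam:
    """Adam optimizer over a list of named Tensors (deterministic)."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()
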