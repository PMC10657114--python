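"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Only the operations needed by the duplex-graph classifier are implemented:
dense matmul, broadcasting add/mul, ReLU/LeakyReLU, row gather/scatter
(message passing), segment softmax (attention normalisation), row-wise L2
normalisation, segment max (pooling), dropout and a fused softmax
cross-entropy loss.  Everything is float64.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np

__all__ = [
    "Tensor",
    "backward",
    "matmul",
    "add",
    "mul",
    "relu",
    "leaky_relu",
    "concat_cols",
    "gather_rows",
    "scatter_sum",
    "segment_max",
    "segment_softmax",
    "l2_normalize_rows",
    "expand_col",
    "gat_edge_scores",
    "dropout",
    "softmax_cross_entropy",
]


class Tensor:
    """A NumPy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[], None] | None = None

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _result(data: np.ndarray, parents: Iterable[Tensor],
            backward_fn: Callable[[], None]) -> Tensor:
    out = Tensor(data)
    parents = tuple(parents)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = parents
        out._backward = backward_fn
    return out


def _accumulate(t: Tensor, grad: np.ndarray) -> None:
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = np.zeros_like(t.data)
    t.grad += grad


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, (g_dim, s_dim) in enumerate(zip(grad.shape, shape)):
        if s_dim == 1 and g_dim != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


def backward(loss: Tensor) -> None:
    """Back-propagate from a scalar tensor, accumulating into `.grad`."""
    topo: list[Tensor] = []
    seen: set[int] = set()

    stack: list[tuple[Tensor, bool]] = [(loss, False)]
    while stack:  # iterative DFS; graphs can be deep for many layers/batches
        node, processed = stack.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in seen or not node.requires_grad:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            stack.append((p, False))

    loss.grad = np.ones_like(loss.data)
    for node in reversed(topo):
        if node._backward is not None:
            node._backward()


# ---------------------------------------------------------------------------
# elementary ops
# ---------------------------------------------------------------------------

def matmul(a: Tensor, b: Tensor) -> Tensor:
    def bwd():
        g = out.grad
        _accumulate(a, g @ b.data.T)
        _accumulate(b, a.data.T @ g)

    out = _result(a.data @ b.data, (a, b), bwd)
    return out


def add(a: Tensor, b: Tensor) -> Tensor:
    def bwd():
        _accumulate(a, _unbroadcast(out.grad, a.data.shape))
        _accumulate(b, _unbroadcast(out.grad, b.data.shape))

    out = _result(a.data + b.data, (a, b), bwd)
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    def bwd():
        _accumulate(a, _unbroadcast(out.grad * b.data, a.data.shape))
        _accumulate(b, _unbroadcast(out.grad * a.data, b.data.shape))

    out = _result(a.data * b.data, (a, b), bwd)
    return out


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def bwd():
        _accumulate(a, out.grad * mask)

    out = _result(np.where(mask, a.data, 0.0), (a,), bwd)
    return out


def leaky_relu(a: Tensor, negative_slope: float = 0.2) -> Tensor:
    mask = a.data > 0

    def bwd():
        _accumulate(a, out.grad * np.where(mask, 1.0, negative_slope))

    out = _result(np.where(mask, a.data, negative_slope * a.data), (a,), bwd)
    return out


def concat_cols(a: Tensor, b: Tensor) -> Tensor:
    na = a.data.shape[1]

    def bwd():
        _accumulate(a, out.grad[:, :na])
        _accumulate(b, out.grad[:, na:])

    out = _result(np.concatenate([a.data, b.data], axis=1), (a, b), bwd)
    return out


def expand_col(a: Tensor) -> Tensor:
    """Reshape a length-E vector to an (E, 1) column."""

    def bwd():
        _accumulate(a, out.grad.reshape(a.data.shape))

    out = _result(a.data.reshape(-1, 1), (a,), bwd)
    return out


# ---------------------------------------------------------------------------
# gather / scatter (message passing)
# ---------------------------------------------------------------------------

def gather_rows(a: Tensor, index: np.ndarray) -> Tensor:
    index = np.asarray(index, dtype=np.intp)

    def bwd():
        g_full = np.zeros_like(a.data)
        np.add.at(g_full, index, out.grad)
        _accumulate(a, g_full)

    out = _result(a.data[index], (a,), bwd)
    return out


def scatter_sum(a: Tensor, index: np.ndarray, n_rows: int) -> Tensor:
    """out[k] = sum of rows i of `a` with index[i] == k."""
    index = np.asarray(index, dtype=np.intp)
    data = np.zeros((n_rows, a.data.shape[1]), dtype=np.float64)
    np.add.at(data, index, a.data)

    def bwd():
        _accumulate(a, out.grad[index])

    out = _result(data, (a,), bwd)
    return out


def segment_max(a: Tensor, index: np.ndarray, n_rows: int) -> Tensor:
    """Per-segment element-wise max; gradient flows to the first arg-max row."""
    index = np.asarray(index, dtype=np.intp)
    n_cols = a.data.shape[1]
    data = np.full((n_rows, n_cols), -np.inf)
    np.maximum.at(data, index, a.data)

    # first row achieving the max, per (segment, column)
    hit_rows, hit_cols = np.nonzero(a.data == data[index])
    winner = np.full((n_rows, n_cols), a.data.shape[0], dtype=np.intp)
    np.minimum.at(winner, (index[hit_rows], hit_cols), hit_rows)

    def bwd():
        g_full = np.zeros_like(a.data)
        cols = np.tile(np.arange(n_cols), n_rows)
        rows = winner.ravel()
        valid = rows < a.data.shape[0]
        np.add.at(g_full, (rows[valid], cols[valid]), out.grad.ravel()[valid])
        _accumulate(a, g_full)

    out = _result(data, (a,), bwd)
    return out


def segment_softmax(scores: Tensor, index: np.ndarray, n_segments: int) -> Tensor:
    """Softmax of a score vector within each segment (max-shifted for stability)."""
    index = np.asarray(index, dtype=np.intp)
    s = scores.data
    seg_max = np.full(n_segments, -np.inf)
    np.maximum.at(seg_max, index, s)
    ex = np.exp(s - seg_max[index])
    denom = np.zeros(n_segments)
    np.add.at(denom, index, ex)
    alpha = ex / denom[index]

    def bwd():
        g = out.grad
        dot = np.zeros(n_segments)
        np.add.at(dot, index, alpha * g)
        _accumulate(scores, alpha * (g - dot[index]))

    out = _result(alpha, (scores,), bwd)
    return out


def l2_normalize_rows(a: Tensor) -> Tensor:
    """Divide each row by its L2 norm; all-zero rows map to zero."""
    norms = np.linalg.norm(a.data, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    y = a.data / safe[:, None]

    def bwd():
        g = out.grad
        proj = (g * y).sum(axis=1, keepdims=True)
        gx = (g - y * proj) / safe[:, None]
        gx[norms == 0] = 0.0
        _accumulate(a, gx)

    out = _result(y, (a,), bwd)
    return out


def gat_edge_scores(hw: Tensor, a: Tensor, src: np.ndarray, dst: np.ndarray) -> Tensor:
    """Per-edge raw attention score a . concat(HW[dst], HW[src]).

    `dst` is the centre node, `src` the neighbour providing the message.
    """
    src = np.asarray(src, dtype=np.intp)
    dst = np.asarray(dst, dtype=np.intp)
    n_out = hw.data.shape[1]
    a_centre, a_neigh = a.data[:n_out], a.data[n_out:]
    scores = hw.data[dst] @ a_centre + hw.data[src] @ a_neigh

    def bwd():
        g = out.grad
        g_hw = np.zeros_like(hw.data)
        np.add.at(g_hw, dst, g[:, None] * a_centre)
        np.add.at(g_hw, src, g[:, None] * a_neigh)
        _accumulate(hw, g_hw)
        _accumulate(a, np.concatenate([g @ hw.data[dst], g @ hw.data[src]]))

    out = _result(scores, (hw, a), bwd)
    return out


def dropout(a: Tensor, rate: float, rng: np.random.Generator | None,
            training: bool) -> Tensor:
    if not training or rate <= 0.0:
        return a
    if rng is None:
        raise ValueError("dropout in training mode requires an RNG")
    mask = (rng.random(a.data.shape) >= rate) / (1.0 - rate)

    def bwd():
        _accumulate(a, out.grad * mask)

    out = _result(a.data * mask, (a,), bwd)
    return out


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of row-wise softmax(logits) against integer labels."""
    labels = np.asarray(labels, dtype=np.intp)
    z = logits.data
    z_max = z.max(axis=1, keepdims=True)
    log_norm = np.log(np.exp(z - z_max).sum(axis=1, keepdims=True)) + z_max
    log_p = z - log_norm
    n = z.shape[0]
    loss = -log_p[np.arange(n), labels].mean()

    def bwd():
        p = np.exp(log_p)
        p[np.arange(n), labels] -= 1.0
        _accumulate(logits, out.grad * p / n)

    out = _result(np.float64(loss), (logits,), bwd)
    return out


def softmax_rows(z: np.ndarray) -> np.ndarray:
    """Plain (non-differentiable) row-wise softmax used at inference time."""
    z = np.asarray(z, dtype=np.float64)
    z_max = z.max(axis=-1, keepdims=True)
    e = np.exp(z - z_max)
    return e / e.sum(axis=-1, keepdims=True)
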