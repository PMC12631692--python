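"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is the numerical substrate for the graph layers in molgat.model:
a small tape-based autograd supporting exactly the operations a graph
attention / convolution stack needs — dense matmul, broadcast add/mul,
tanh and leaky-ReLU nonlinearities, row gather, and segment (per-node
neighborhood) sum and softmax.  Gradients are accumulated by reverse
topological traversal of the recorded graph.

The engine is deliberately tiny: 2-D float64 arrays only, no shape
polymorphism beyond broadcasting a (1, F) or (E, 1) operand, no second
derivatives.  The models it serves have ~3.7K parameters and run
full-batch on CPU, where numpy's BLAS is more than fast enough.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
import scipy.sparse as sparse

__all__ = ["Tensor", "RMSProp", "Segmentation", "matmul", "add", "mul",
           "sub", "tanh", "leaky_relu", "gather", "segment_sum",
           "segment_softmax", "mean_squared_error"]


class Segmentation:
    """Precomputed structure for fast per-segment reductions.

    Segment reductions on a static edge structure are the hot loop of
    training.  Sums use a cached sparse scatter matrix (one spmm per
    reduction); other reductions (max, for softmax stabilization) use
    contiguous ``np.ufunc.reduceat`` on rows pre-sorted by segment id.
    Requires every segment to be non-empty (graph batches guarantee
    this via self-loops: every node appears as both a source and a
    destination).
    """

    __slots__ = ("ids", "n_segments", "order", "starts", "_sorted", "_sum")

    def __init__(self, ids: np.ndarray, n_segments: int):
        self.ids = np.asarray(ids, dtype=np.int64)
        self.n_segments = n_segments
        self._sorted = bool(np.all(self.ids[:-1] <= self.ids[1:]))
        self.order = (None if self._sorted
                      else np.argsort(self.ids, kind="stable"))
        sorted_ids = self.ids if self._sorted else self.ids[self.order]
        self.starts = np.searchsorted(sorted_ids, np.arange(n_segments))
        counts = np.diff(np.append(self.starts, len(self.ids)))
        if np.any(counts == 0):
            raise ValueError("every segment must be non-empty")
        # summation as a cached sparse matrix: one BLAS-like spmm per
        # reduction instead of the slower ufunc.reduceat path
        self._sum = sparse.csr_matrix(
            (np.ones(len(self.ids)), (self.ids, np.arange(len(self.ids)))),
            shape=(n_segments, len(self.ids)),
        )

    def sum(self, x: np.ndarray) -> np.ndarray:
        """Per-segment row sums, shape (n_segments, C)."""
        return self._sum @ x

    def reduce(self, x: np.ndarray, ufunc=np.add) -> np.ndarray:
        """Per-segment reduction of rows of x, shape (n_segments, C)."""
        if ufunc is np.add:
            return self.sum(x)
        if not self._sorted:
            x = x[self.order]
        return ufunc.reduceat(x, self.starts, axis=0)


def _as_segmentation(seg, n_segments: int) -> Segmentation:
    return seg if isinstance(seg, Segmentation) else Segmentation(seg, n_segments)


class Tensor:
    """A 2-D array node in the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward: Callable | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        if self.data.ndim == 1:
            self.data = self.data[:, None]
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in parents
        )
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def backward(self) -> None:
        """Backpropagate from this (scalar-valued) tensor through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; molecules can make deep tapes
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def _accumulate(t: Tensor, g: np.ndarray) -> None:
    # first contribution may alias g (gradients are never mutated in
    # place: later contributions rebind to a fresh sum array)
    if not t.requires_grad:
        return
    t.grad = g if t.grad is None else t.grad + g


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient g down to `shape` (inverse of numpy broadcasting)."""
    for axis in range(2):
        if shape[axis] == 1 and g.shape[axis] != 1:
            g = g.sum(axis=axis, keepdims=True)
    return g


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data @ b.data, parents=(a, b))

    def backward(g):
        _accumulate(a, g @ b.data.T)
        _accumulate(b, a.data.T @ g)

    out._backward = backward
    return out


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, parents=(a, b))

    def backward(g):
        _accumulate(a, _unbroadcast(g, a.data.shape))
        _accumulate(b, _unbroadcast(g, b.data.shape))

    out._backward = backward
    return out


def sub(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data - b.data, parents=(a, b))

    def backward(g):
        _accumulate(a, _unbroadcast(g, a.data.shape))
        _accumulate(b, _unbroadcast(-g, b.data.shape))

    out._backward = backward
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, parents=(a, b))

    def backward(g):
        _accumulate(a, _unbroadcast(g * b.data, a.data.shape))
        _accumulate(b, _unbroadcast(g * a.data, b.data.shape))

    out._backward = backward
    return out


def tanh(a: Tensor) -> Tensor:
    y = np.tanh(a.data)
    out = Tensor(y, parents=(a,))

    def backward(g):
        _accumulate(a, g * (1.0 - y * y))

    out._backward = backward
    return out


def leaky_relu(a: Tensor, negative_slope: float = 0.2) -> Tensor:
    mask = np.where(a.data > 0, 1.0, negative_slope)
    out = Tensor(a.data * mask, parents=(a,))

    def backward(g):
        _accumulate(a, g * mask)

    out._backward = backward
    return out


def gather(a: Tensor, idx: np.ndarray,
           scatter_seg: Segmentation | None = None) -> Tensor:
    """Select rows a[idx]; backward scatter-adds into the source rows.

    When the same index vector is reused across epochs, pass its
    Segmentation (over a's row count) so the backward scatter uses the
    fast sorted-reduction path.
    """
    idx = np.asarray(idx, dtype=np.int64)
    out = Tensor(a.data[idx], parents=(a,))

    def backward(g):
        if not a.requires_grad:
            return
        if scatter_seg is not None:
            _accumulate(a, scatter_seg.sum(g))
        else:
            acc = np.zeros_like(a.data)
            np.add.at(acc, idx, g)
            _accumulate(a, acc)

    out._backward = backward
    return out


def segment_sum(a: Tensor, seg, n_segments: int) -> Tensor:
    """Sum rows of a into n_segments buckets given per-row segment ids.

    The backward of a segment sum is a plain gather: row i receives the
    gradient of its segment.
    """
    seg = _as_segmentation(seg, n_segments)
    out = Tensor(seg.sum(a.data), parents=(a,))

    def backward(g):
        _accumulate(a, g[seg.ids])

    out._backward = backward
    return out


def segment_softmax(a: Tensor, seg, n_segments: int) -> Tensor:
    """Softmax of column-vector a within each segment (attention weights).

    Numerically stabilized by subtracting the per-segment max.  The
    Jacobian within a segment is diag(s) - s s^T, giving the usual
    grad_a = s * (g - sum_segment(g * s)).
    """
    seg = _as_segmentation(seg, n_segments)
    x = a.data
    mx = seg.reduce(x, np.maximum)
    ex = np.exp(x - mx[seg.ids])
    s = ex / seg.sum(ex)[seg.ids]
    out = Tensor(s, parents=(a,))

    def backward(g):
        dot = seg.sum(g * s)
        _accumulate(a, s * (g - dot[seg.ids]))

    out._backward = backward
    return out


def mean_squared_error(pred: Tensor, target: np.ndarray) -> Tensor:
    """Scalar MSE between a (G, 1) prediction tensor and targets."""
    t = np.asarray(target, dtype=np.float64).reshape(-1, 1)
    diff = pred.data - t
    out = Tensor(np.array([[np.mean(diff ** 2)]]), parents=(pred,))

    def backward(g):
        _accumulate(pred, g * 2.0 * diff / diff.size)

    out._backward = backward
    return out


class RMSProp:
    """RMSprop with exponentially decaying squared-gradient average.

    v <- alpha v + (1 - alpha) g^2 ;  w <- w - lr g / (sqrt(v) + eps)
    """

    def __init__(self, params: dict[str, Tensor], lr: float = 5e-3,
                 alpha: float = 0.99, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.alpha = alpha
        self.eps = eps
        self._v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        for k, p in self.params.items():
            if p.grad is None:
                continue
            v = self._v[k]
            v *= self.alpha
            v += (1.0 - self.alpha) * p.grad ** 2
            p.data -= self.lr * p.grad / (np.sqrt(v) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None
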