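"""Minimal reverse-mode automatic differentiation over numpy arrays.

Provides exactly the operations the node-classification networks need:
broadcast arithmetic, matmul, reductions, exact GELU, row gathering,
segment sum/mean/max aggregation over edge lists, and a fused
softmax/cross-entropy loss.  Gradients are accumulated by topologically
sorted reverse traversal; correctness is pinned down by central-difference
checks in the test suite.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import erf

__all__ = [
    "Tensor",
    "gelu",
    "concat",
    "gather_rows",
    "segment_sum",
    "segment_mean",
    "segment_max",
    "softmax",
    "softmax_cross_entropy",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` to undo numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # -- graph plumbing ---------------------------------------------------

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- arithmetic -------------------------------------------------------

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        out._backward = backward
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        out._backward = backward
        return out

    def pow(self, exponent: float) -> "Tensor":
        out = Tensor(self.data**exponent, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1))

        out._backward = backward
        return out

    def sqrt(self) -> "Tensor":
        return self.pow(0.5)

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def backward(g):
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)


def gelu(x: Tensor) -> Tensor:
    """Exact Gaussian-error linear unit: x * Phi(x)."""
    cdf = 0.5 * (1.0 + erf(x.data / math.sqrt(2.0)))
    out = Tensor(x.data * cdf, parents=(x,))

    def backward(g):
        if x.requires_grad:
            pdf = np.exp(-0.5 * x.data**2) / math.sqrt(2.0 * math.pi)
            x._accum(g * (cdf + x.data * pdf))

    out._backward = backward
    return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    out._backward = backward
    return out


def gather_rows(x: Tensor, index: np.ndarray) -> Tensor:
    index = np.asarray(index, dtype=np.int64)
    out = Tensor(x.data[index], parents=(x,))

    def backward(g):
        if x.requires_grad:
            acc = np.zeros_like(x.data)
            np.add.at(acc, index, g)
            x._accum(acc)

    out._backward = backward
    return out


def segment_sum(x: Tensor, segment_ids: np.ndarray, n_segments: int) -> Tensor:
    """Sum rows of ``x`` into ``n_segments`` buckets; empty bucket -> zeros."""
    seg = np.asarray(segment_ids, dtype=np.int64)
    data = np.zeros((n_segments,) + x.data.shape[1:])
    np.add.at(data, seg, x.data)
    out = Tensor(data, parents=(x,))

    def backward(g):
        if x.requires_grad:
            x._accum(g[seg])

    out._backward = backward
    return out


def segment_mean(x: Tensor, segment_ids: np.ndarray, n_segments: int) -> Tensor:
    """Mean rows per bucket; empty bucket -> zeros."""
    seg = np.asarray(segment_ids, dtype=np.int64)
    counts = np.bincount(seg, minlength=n_segments).astype(np.float64)
    safe = np.maximum(counts, 1.0)
    data = np.zeros((n_segments,) + x.data.shape[1:])
    np.add.at(data, seg, x.data)
    data /= safe[:, None]
    out = Tensor(data, parents=(x,))

    def backward(g):
        if x.requires_grad:
            x._accum(g[seg] / safe[seg][:, None])

    out._backward = backward
    return out


def segment_max(x: Tensor, segment_ids: np.ndarray, n_segments: int) -> Tensor:
    """Elementwise max per bucket; empty bucket -> zeros by convention.

    The gradient is split equally among rows attaining the bucket maximum.
    """
    seg = np.asarray(segment_ids, dtype=np.int64)
    data = np.full((n_segments,) + x.data.shape[1:], -np.inf)
    np.maximum.at(data, seg, x.data)
    empty = ~np.isin(np.arange(n_segments), seg)
    data[empty] = 0.0
    is_max = x.data == data[seg]
    tie_count = np.zeros_like(data)
    np.add.at(tie_count, seg, is_max.astype(np.float64))
    tie_count = np.maximum(tie_count, 1.0)
    out = Tensor(data, parents=(x,))

    def backward(g):
        if x.requires_grad:
            x._accum(np.where(is_max, g[seg] / tie_count[seg], 0.0))

    out._backward = backward
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax of a plain array (prediction path, no gradient)."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean integer-label cross-entropy with a fused softmax gradient."""
    labels = np.asarray(labels, dtype=np.int64)
    probs = softmax(logits.data)
    n = len(labels)
    eps = 1e-12
    loss = -np.log(probs[np.arange(n), labels] + eps).mean()
    out = Tensor(loss, parents=(logits,))

    def backward(g):
        if logits.requires_grad:
            grad = probs.copy()
            grad[np.arange(n), labels] -= 1.0
            logits._accum(g * grad / n)

    out._backward = backward
    return out


class Adam:
    """Adam optimiser over a list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 0.01,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g**2
            mhat = self.m[i] / (1 - self.beta1**self.t)
            vhat = self.v[i] / (1 - self.beta2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
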