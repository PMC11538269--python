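"""Minimal reverse-mode automatic differentiation over numpy arrays.

The desk-scale encoders and contrastive objectives in this package are small
enough (patch-embedding stacks, batches of a few dozen) that a compact tape
of numpy primitives is sufficient for end-to-end gradient training on one
CPU.  Tensors carry float64 data; gradients are accumulated on ``.grad``
during :meth:`Tensor.backward`.  Only the primitives the package needs are
implemented: elementwise arithmetic, matmul, reductions, exp/log/sqrt/tanh,
relu, reshape/transpose, slicing and concatenation.

Correctness is guarded by finite-difference gradient checks in the test
suite rather than by exhaustive op coverage.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the context (evaluation mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


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
    """A numpy array with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self.grad: np.ndarray | None = None
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def T(self) -> "Tensor":
        return self.transpose()

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def __float__(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self) -> None:
        """Backpropagate from a scalar tensor."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(
            self.data + other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
            None,
        )

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = bw if out.requires_grad else None
        return out

    __radd__ = __add__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(
            self.data * other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
            None,
        )

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = bw if out.requires_grad else None
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return as_tensor(other) * self ** -1.0

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, self.requires_grad, (self,), None)

        def bw(g):
            self._accumulate(g * p * self.data ** (p - 1.0))

        out._backward = bw if out.requires_grad else None
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(
            self.data @ other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
            None,
        )

        def bw(g):
            if self.requires_grad:
                self._accumulate(_matmul_grad_a(g, self.data, other.data))
            if other.requires_grad:
                other._accumulate(_matmul_grad_b(g, self.data, other.data))

        out._backward = bw if out.requires_grad else None
        return out

    # ----------------------------------------------------------- elementwise
    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, self.requires_grad, (self,), None)
        out._backward = (lambda g: self._accumulate(g * val)) if out.requires_grad else None
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,), None)
        out._backward = (lambda g: self._accumulate(g / self.data)) if out.requires_grad else None
        return out

    def sqrt(self):
        val = np.sqrt(self.data)
        out = Tensor(val, self.requires_grad, (self,), None)
        out._backward = (lambda g: self._accumulate(g * 0.5 / val)) if out.requires_grad else None
        return out

    def tanh(self):
        val = np.tanh(self.data)
        out = Tensor(val, self.requires_grad, (self,), None)
        out._backward = (lambda g: self._accumulate(g * (1.0 - val ** 2))) if out.requires_grad else None
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, self.requires_grad, (self,), None)
        out._backward = (lambda g: self._accumulate(g * mask)) if out.requires_grad else None
        return out

    # -------------------------------------------------------------- reshapes
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        src = self.shape
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,), None)
        out._backward = (lambda g: self._accumulate(g.reshape(src))) if out.requires_grad else None
        return out

    def transpose(self, axes: Sequence[int] | None = None):
        if axes is None:
            axes = tuple(reversed(range(self.ndim)))
        axes = tuple(axes)
        inv = tuple(np.argsort(axes))
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,), None)
        out._backward = (lambda g: self._accumulate(g.transpose(inv))) if out.requires_grad else None
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad, (self,), None)

        def bw(g):
            buf = np.zeros_like(self.data)
            np.add.at(buf, idx, g)
            self._accumulate(buf)

        out._backward = bw if out.requires_grad else None
        return out

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), self.requires_grad, (self,), None)

        def bw(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        out._backward = bw if out.requires_grad else None
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        elif isinstance(axis, tuple):
            n = int(np.prod([self.shape[a] for a in axis]))
        else:
            n = self.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def _matmul_grad_a(g, a, b):
    if b.ndim == 1:
        if a.ndim == 1:
            return g * b
        return np.expand_dims(g, -1) * b
    if a.ndim == 1:
        return (g[..., None, :] @ np.swapaxes(b, -1, -2)).reshape(a.shape)
    grad = g @ np.swapaxes(b, -1, -2)
    return _unbroadcast(grad, a.shape)


def _matmul_grad_b(g, a, b):
    if a.ndim == 1:
        if b.ndim == 1:
            return g * a
        return np.outer(a, g)
    if b.ndim == 1:
        return np.swapaxes(a, -1, -2) @ g
    grad = np.swapaxes(a, -1, -2) @ g
    return _unbroadcast(grad, b.shape)


# ----------------------------------------------------------------- functions
def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concatenate(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    req = any(t.requires_grad for t in tensors)
    out = Tensor(data, req, tuple(tensors), None)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out._backward = bw if out.requires_grad else None
    return out


def logsumexp(t: Tensor, axis: int, keepdims: bool = False) -> Tensor:
    """Numerically stable log-sum-exp along ``axis`` (differentiable)."""
    t = as_tensor(t)
    m = np.max(t.data, axis=axis, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)  # all -inf row guard
    shifted = t - Tensor(m)
    s = shifted.exp().sum(axis=axis, keepdims=True).log() + Tensor(m)
    if keepdims:
        return s
    shape = tuple(d for i, d in enumerate(t.shape) if i != axis % t.ndim)
    return s.reshape(shape)


def l2_normalize(t: Tensor, axis: int = -1, eps: float = 1e-12) -> Tensor:
    """Rows (or the given axis) scaled to unit Euclidean norm."""
    t = as_tensor(t)
    sq = (t * t).sum(axis=axis, keepdims=True)
    return t * (sq + eps) ** -0.5


def clip_max(t: Tensor, hi: float) -> Tensor:
    """Differentiable upper clamp: gradient is zero above ``hi``."""
    return hi - (hi - t).relu()


def leaky_relu(t: Tensor, alpha: float = 0.1) -> Tensor:
    """max(x, alpha*x); keeps gradients alive on the negative side."""
    t = as_tensor(t)
    return t.relu() - alpha * (-t).relu()
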