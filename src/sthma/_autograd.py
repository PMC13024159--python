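"""Minimal reverse-mode automatic differentiation over numpy arrays.

A small tape-based engine in the micrograd style, lifted to ndarrays.  It
exists because this package trains neural networks in environments where no
deep-learning framework is available; only the operations the model needs
are implemented.  Gradients are accumulated in ``Tensor.grad`` by
:meth:`Tensor.backward`, which topologically sorts the recorded graph.

Broadcasting follows numpy semantics; gradients of broadcast operands are
summed back to the operand's shape.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.special import erf as _erf

__all__ = ["Tensor", "as_tensor", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph recording (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were size-1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An ndarray plus an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 _parents: Sequence["Tensor"] = (),
                 _backward: Callable[[np.ndarray], None] | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self.grad: np.ndarray | None = None
        self._parents = tuple(_parents) if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("grad must be supplied for non-scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs can exceed the recursion limit
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))
        out._backward = _bw if out.requires_grad else None
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))
        out._backward = _bw if out.requires_grad else None
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.shape))
        out._backward = _bw if out.requires_grad else None
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data**p, self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * p * self.data**(p - 1))
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def _bw(g):
            a, b = self.data, other.data
            if self.requires_grad:
                if b.ndim == 1:
                    ga = np.multiply.outer(g, b) if g.ndim else g * b
                else:
                    ga = g @ np.swapaxes(b, -1, -2)
                self._accumulate(_unbroadcast(ga, a.shape))
            if other.requires_grad:
                if a.ndim == 1:
                    gb = np.multiply.outer(a, g) if g.ndim else a * g
                else:
                    gb = np.swapaxes(a, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, b.shape))
        out._backward = _bw if out.requires_grad else None
        return out

    # ----------------------------------------------------------- elementwise
    def exp(self):
        out = Tensor(np.exp(self.data), self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def sqrt(self):
        out = Tensor(np.sqrt(self.data), self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * 0.5 / out.data)
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * (1.0 - out.data**2))
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * s * (1.0 - s))
        return out

    def silu(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(self.data * s, self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(
                g * (s + self.data * s * (1.0 - s)))
        return out

    def gelu(self):
        """Exact (erf-based) GELU."""
        x = self.data
        phi = 0.5 * (1.0 + _erf(x / np.sqrt(2.0)))
        out = Tensor(x * phi, self.requires_grad, (self,))
        if out.requires_grad:
            pdf = np.exp(-0.5 * x**2) / np.sqrt(2.0 * np.pi)
            out._backward = lambda g: self._accumulate(g * (phi + x * pdf))
        return out

    def elu(self, alpha: float = 1.0):
        x = self.data
        neg = alpha * (np.exp(np.minimum(x, 0.0)) - 1.0)
        y = np.where(x > 0, x, neg)
        out = Tensor(y, self.requires_grad, (self,))
        if out.requires_grad:
            dydx = np.where(x > 0, 1.0, neg + alpha)
            out._backward = lambda g: self._accumulate(g * dydx)
        return out

    def softplus(self):
        # numerically stable log(1 + e^x)
        y = np.logaddexp(0.0, self.data)
        out = Tensor(y, self.requires_grad, (self,))
        if out.requires_grad:
            s = 1.0 / (1.0 + np.exp(-self.data))
            out._backward = lambda g: self._accumulate(g * s)
        return out

    def clip(self, lo: float, hi: float):
        """Hard clamp; gradient is zero outside [lo, hi]."""
        y = np.clip(self.data, lo, hi)
        out = Tensor(y, self.requires_grad, (self,))
        if out.requires_grad:
            mask = (self.data >= lo) & (self.data <= hi)
            out._backward = lambda g: self._accumulate(g * mask)
        return out

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))
        if out.requires_grad:
            def _bw(g):
                if axis is None:
                    self._accumulate(np.broadcast_to(g, self.shape).copy())
                    return
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.shape).copy())
            out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max_detached(self, axis=None, keepdims: bool = False) -> np.ndarray:
        """Max as a constant (used for numerically stable softmax shifts)."""
        return self.data.max(axis=axis, keepdims=keepdims)

    # -------------------------------------------------------- shape plumbing
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g.reshape(self.shape))
        return out

    def transpose(self, axes: Sequence[int]):
        axes = tuple(axes)
        inv = tuple(np.argsort(axes))
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g.transpose(inv))
        return out

    def swapaxes(self, a: int, b: int):
        out = Tensor(np.swapaxes(self.data, a, b), self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(np.swapaxes(g, a, b))
        return out

    def flip(self, axis: int):
        out = Tensor(np.flip(self.data, axis=axis), self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(np.flip(g, axis=axis))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad, (self,))
        if out.requires_grad:
            def _bw(g):
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)
            out._backward = _bw
        return out

    def pad_axis(self, axis: int, before: int, after: int):
        """Zero-pad one axis."""
        widths = [(0, 0)] * self.ndim
        widths[axis] = (before, after)
        out = Tensor(np.pad(self.data, widths), self.requires_grad, (self,))
        if out.requires_grad:
            sl = [slice(None)] * self.ndim
            n = self.shape[axis]
            sl[axis] = slice(before, before + n)
            sl = tuple(sl)
            out._backward = lambda g: self._accumulate(g[sl])
        return out

    # ------------------------------------------------------------- composites
    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        y = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(y, self.requires_grad, (self,))
        if out.requires_grad:
            def _bw(g):
                dot = (g * y).sum(axis=axis, keepdims=True)
                self._accumulate(y * (g - dot))
            out._backward = _bw
        return out

    def log_softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
        y = shifted - lse
        out = Tensor(y, self.requires_grad, (self,))
        if out.requires_grad:
            def _bw(g):
                p = np.exp(y)
                self._accumulate(g - p * g.sum(axis=axis, keepdims=True))
            out._backward = _bw
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concatenate(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 any(t.requires_grad for t in tensors), tensors)
    if out.requires_grad:
        sizes = [t.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def _bw(g):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(lo, hi)
                    t._accumulate(g[tuple(sl)])
        out._backward = _bw
    return out
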