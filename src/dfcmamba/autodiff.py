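"""Minimal reverse-mode automatic differentiation over numpy arrays.

The whole model stack in this package (variational autoencoder, selective
state-space encoder, Kolmogorov-Arnold head) is small enough that a compact
tape-based engine is sufficient: every operation records its parents and a
closure that accumulates vector-Jacobian products into ``grad`` buffers.
Shapes follow numpy broadcasting; gradients of broadcast operands are summed
back to the operand's shape.

Only the operations the models need are provided.  All arithmetic is float64.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "stack", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (evaluation mode)."""

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


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading broadcast axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")
    __array_priority__ = 100  # defer numpy binary ops to Tensor

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self.grad: np.ndarray | None = None
        self._backward: Callable[[], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing ---------------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"], backward) -> "Tensor":
        req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out = Tensor(data)
        out.requires_grad = req
        if req:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray, fresh: bool = False) -> None:
        """Accumulate a vector-Jacobian product.

        ``fresh=True`` promises ``g`` is a newly allocated array no one else
        holds, letting the first accumulation adopt it without a copy.
        """
        if self.grad is None:
            self.grad = g if fresh and g.dtype == np.float64 else np.array(g, dtype=np.float64)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        # iterative DFS post-order (graphs can be thousands of nodes deep)
        while stack:
            node = stack.pop()
            if id(node) in seen:
                continue
            unvisited = [p for p in node._parents if id(p) not in seen]
            if unvisited:
                stack.append(node)
                stack.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(node)
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- conveniences -----------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out_data = self.data + other.data

        def backward():
            if self.requires_grad:
                g = _unbroadcast(out.grad, self.shape)
                self._accum(g, fresh=g is not out.grad)
            if other.requires_grad:
                g = _unbroadcast(out.grad, other.shape)
                other._accum(g, fresh=g is not out.grad)

        out = Tensor._make(out_data, (self, other), backward)
        return out

    __radd__ = __add__

    def __neg__(self):
        def backward():
            if self.requires_grad:
                self._accum(-out.grad, fresh=True)

        out = Tensor._make(-self.data, (self,), backward)
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out_data = self.data * other.data

        def backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.shape), fresh=True)
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.shape), fresh=True)

        out = Tensor._make(out_data, (self, other), backward)
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out_data = self.data / other.data

        def backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad / other.data, self.shape), fresh=True)
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-out.grad * self.data / other.data**2, other.shape),
                    fresh=True,
                )

        out = Tensor._make(out_data, (self, other), backward)
        return out

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, exponent: float):
        exponent = float(exponent)
        out_data = self.data**exponent

        def backward():
            if self.requires_grad:
                self._accum(out.grad * exponent * self.data ** (exponent - 1), fresh=True)

        out = Tensor._make(out_data, (self,), backward)
        return out

    def __matmul__(self, other):
        other = _as_tensor(other)
        out_data = self.data @ other.data

        def backward():
            g = out.grad
            if self.requires_grad:
                if other.data.ndim == 1:
                    self._accum(np.outer(g, other.data) if self.data.ndim == 2 else g * other.data,
                                fresh=True)
                else:
                    self._accum(_unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.shape),
                                fresh=True)
            if other.requires_grad:
                if self.data.ndim == 1:
                    other._accum(np.outer(self.data, g) if other.data.ndim == 2 else self.data * g,
                                 fresh=True)
                else:
                    other._accum(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.shape),
                                 fresh=True)

        out = Tensor._make(out_data, (self, other), backward)
        return out

    # -- elementwise nonlinearities --------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward():
            if self.requires_grad:
                self._accum(out.grad * out_data, fresh=True)

        out = Tensor._make(out_data, (self,), backward)
        return out

    def log(self):
        out_data = np.log(self.data)

        def backward():
            if self.requires_grad:
                self._accum(out.grad / self.data, fresh=True)

        out = Tensor._make(out_data, (self,), backward)
        return out

    def relu(self):
        mask = self.data > 0
        out_data = np.where(mask, self.data, 0.0)

        def backward():
            if self.requires_grad:
                self._accum(out.grad * mask, fresh=True)

        out = Tensor._make(out_data, (self,), backward)
        return out

    def sigmoid(self):
        out_data = _sigmoid(self.data)

        def backward():
            if self.requires_grad:
                self._accum(out.grad * out_data * (1.0 - out_data), fresh=True)

        out = Tensor._make(out_data, (self,), backward)
        return out

    def silu(self):
        """x * sigmoid(x)."""
        s = _sigmoid(self.data)
        out_data = self.data * s

        def backward():
            if self.requires_grad:
                self._accum(out.grad * (s * (1.0 + self.data * (1.0 - s))), fresh=True)

        out = Tensor._make(out_data, (self,), backward)
        return out

    def softplus(self):
        """log(1+exp(x)), numerically stable; derivative is sigmoid."""
        out_data = np.logaddexp(0.0, self.data)

        def backward():
            if self.requires_grad:
                self._accum(out.grad * _sigmoid(self.data), fresh=True)

        out = Tensor._make(out_data, (self,), backward)
        return out

    # -- reductions and shape ops ----------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward():
            g = out.grad
            if not keepdims and axis is not None:
                g = np.expand_dims(g, axis)
            if self.requires_grad:
                self._accum(np.broadcast_to(g, self.shape))

        out = Tensor._make(out_data, (self,), backward)
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) / n

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)
        orig = self.shape

        def backward():
            if self.requires_grad:
                self._accum(out.grad.reshape(orig))

        out = Tensor._make(out_data, (self,), backward)
        return out

    def transpose(self, *axes):
        axes = axes or None
        out_data = np.transpose(self.data, axes)
        inv = np.argsort(axes) if axes else None

        def backward():
            if self.requires_grad:
                self._accum(np.transpose(out.grad, inv))

        out = Tensor._make(out_data, (self,), backward)
        return out

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        out_data = self.data[idx]
        basic = _is_basic_index(idx)

        def backward():
            if self.requires_grad:
                if self.grad is None:
                    self.grad = np.zeros_like(self.data)
                if basic:  # view-based index: fast in-place add
                    self.grad[idx] += out.grad
                else:  # fancy index may repeat positions
                    np.add.at(self.grad, idx, out.grad)

        out = Tensor._make(out_data, (self,), backward)
        return out

    # -- numerically-stable composites ------------------------------------
    def logsumexp(self, axis: int = -1, keepdims: bool = False):
        shift = np.max(self.data, axis=axis, keepdims=True)
        shifted = self - Tensor(shift)  # constant shift, gradient exact
        out = shifted.exp().sum(axis=axis, keepdims=True).log() + Tensor(shift)
        if not keepdims:
            out = out.reshape(tuple(s for i, s in enumerate(out.shape) if i != (axis % out.ndim)))
        return out

    def log_softmax(self, axis: int = -1):
        return self - self.logsumexp(axis=axis, keepdims=True)

    def softmax(self, axis: int = -1):
        return self.log_softmax(axis=axis).exp()


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * out_data.ndim
                sl[axis] = slice(lo, hi)
                t._accum(out.grad[tuple(sl)])

    out = Tensor._make(out_data, tensors, backward)
    return out


def stack(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward():
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(out.grad, i, axis=axis), fresh=True)

    out = Tensor._make(out_data, tensors, backward)
    return out


def _is_basic_index(idx) -> bool:
    parts = idx if isinstance(idx, tuple) else (idx,)
    return all(isinstance(p, (int, np.integer, slice)) or p is Ellipsis or p is None
               for p in parts)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out
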