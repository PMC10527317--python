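"""Compact reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it on a tape; :meth:`Tensor.backward` walks the tape in reverse topological
order and accumulates gradients.  The op set is deliberately small — exactly
what the graph, convolutional and attention models in this package need —
but each op supports arbitrary batch dimensions and numpy broadcasting.

Gradients preserve the dtype of the tensor they flow into, so float32
convolutional stacks and float64 attention/graph stacks coexist in one
computation graph.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "Parameter", "concatenate", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling tape recording (evaluation mode)."""

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
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _as_array(x) -> np.ndarray:
    if isinstance(x, Tensor):
        raise TypeError("expected raw array, got Tensor")
    return np.asarray(x)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __len__(self) -> int:
        return len(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, dtype={self.dtype}, grad={self.requires_grad})"

    # -- autograd -------------------------------------------------------------
    def backward(self, grad=None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("grad must be supplied for non-scalar outputs")
            grad = np.ones_like(self.data)
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype).reshape(self.shape)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, pgrad in node._backward(node.grad):
                if not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad += pgrad.astype(parent.data.dtype, copy=False)

    def zero_grad(self) -> None:
        self.grad = None

    # -- elementwise arithmetic ----------------------------------------------
    def _coerce(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other))

    def __add__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def back(g):
            return ((a, _unbroadcast(g, a.shape)), (b, _unbroadcast(g, b.shape)))

        return Tensor._make(a.data + b.data, (a, b), back)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._make(-a.data, (a,), lambda g: ((a, -g),))

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def back(g):
            return (
                (a, _unbroadcast(g * b.data, a.shape)),
                (b, _unbroadcast(g * a.data, b.shape)),
            )

        return Tensor._make(a.data * b.data, (a, b), back)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def back(g):
            return (
                (a, _unbroadcast(g / b.data, a.shape)),
                (b, _unbroadcast(-g * a.data / (b.data**2), b.shape)),
            )

        return Tensor._make(a.data / b.data, (a, b), back)

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, exponent: float):
        a = self
        e = float(exponent)

        def back(g):
            return ((a, g * e * a.data ** (e - 1)),)

        return Tensor._make(a.data**e, (a,), back)

    def __matmul__(self, other):
        other = self._coerce(other)
        a, b = self, other
        out = np.matmul(a.data, b.data)

        def back(g):
            if b.data.ndim == 1:
                ga = np.multiply.outer(g, b.data) if g.ndim else g * b.data
                gb = np.tensordot(a.data, g, axes=(tuple(range(a.data.ndim - 1)),
                                                   tuple(range(g.ndim))))
                return ((a, _unbroadcast(ga, a.shape)), (b, _unbroadcast(gb, b.shape)))
            if a.data.ndim == 1:
                ga = np.matmul(g[..., None, :], np.swapaxes(b.data, -1, -2))[..., 0, :]
                gb = np.multiply.outer(a.data, g) if g.ndim == 1 else np.matmul(
                    a.data[:, None], g[..., None, :]
                )
                return ((a, _unbroadcast(ga, a.shape)), (b, _unbroadcast(gb, b.shape)))
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            return ((a, _unbroadcast(ga, a.shape)), (b, _unbroadcast(gb, b.shape)))

        return Tensor._make(out, (a, b), back)

    # -- nonlinearities -------------------------------------------------------
    def relu(self):
        a = self
        mask = a.data > 0
        return Tensor._make(a.data * mask, (a,), lambda g: ((a, g * mask),))

    def tanh(self):
        a = self
        out = np.tanh(a.data)
        return Tensor._make(out, (a,), lambda g: ((a, g * (1.0 - out**2)),))

    def sigmoid(self):
        a = self
        out = 1.0 / (1.0 + np.exp(-a.data))
        return Tensor._make(out, (a,), lambda g: ((a, g * out * (1.0 - out)),))

    def exp(self):
        a = self
        out = np.exp(a.data)
        return Tensor._make(out, (a,), lambda g: ((a, g * out),))

    def log(self):
        a = self
        return Tensor._make(np.log(a.data), (a,), lambda g: ((a, g / a.data),))

    def sqrt(self):
        a = self
        out = np.sqrt(a.data)
        return Tensor._make(out, (a,), lambda g: ((a, g * 0.5 / out),))

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def back(g):
            if axis is None:
                return ((a, np.broadcast_to(g, a.shape).copy()),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return ((a, np.broadcast_to(gg, a.shape).copy()),)

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), back)

    def mean(self, axis=None, keepdims: bool = False):
        a = self
        n = a.data.size if axis is None else (
            np.prod([a.shape[i] for i in np.atleast_1d(axis)])
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False):
        a = self
        idx = np.argmax(a.data, axis=axis)
        out = np.take_along_axis(a.data, np.expand_dims(idx, axis), axis=axis)

        def back(g):
            gg = g if keepdims else np.expand_dims(g, axis)
            grad = np.zeros_like(a.data)
            np.put_along_axis(grad, np.expand_dims(idx, axis), gg, axis=axis)
            return ((a, grad),)

        return Tensor._make(out if keepdims else np.squeeze(out, axis), (a,), back)

    # -- shape manipulation ---------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        return Tensor._make(
            a.data.reshape(shape), (a,), lambda g: ((a, g.reshape(a.shape)),)
        )

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = np.argsort(axes)
        return Tensor._make(
            a.data.transpose(axes), (a,), lambda g: ((a, g.transpose(inv)),)
        )

    def swapaxes(self, ax1: int, ax2: int):
        axes = list(range(self.ndim))
        axes[ax1], axes[ax2] = axes[ax2], axes[ax1]
        return self.transpose(*axes)

    def __getitem__(self, key):
        a = self
        out = a.data[key]

        def back(g):
            grad = np.zeros_like(a.data)
            np.add.at(grad, key, g)
            return ((a, grad),)

        return Tensor._make(np.ascontiguousarray(out), (a,), back)

    def pad(self, pad_width):
        a = self
        slices = tuple(
            slice(lo, lo + s) for (lo, _hi), s in zip(pad_width, a.shape)
        )
        return Tensor._make(
            np.pad(a.data, pad_width), (a,), lambda g: ((a, g[slices]),)
        )

    # -- softmax family (numerically stable fused ops) ------------------------
    def softmax(self, axis: int = -1):
        a = self
        shifted = a.data - a.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out = e / e.sum(axis=axis, keepdims=True)

        def back(g):
            dot = (g * out).sum(axis=axis, keepdims=True)
            return ((a, out * (g - dot)),)

        return Tensor._make(out, (a,), back)

    def log_softmax(self, axis: int = -1):
        a = self
        shifted = a.data - a.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
        out = shifted - lse

        def back(g):
            soft = np.exp(out)
            return ((a, g - soft * g.sum(axis=axis, keepdims=True)),)

        return Tensor._make(out, (a,), back)


class Parameter(Tensor):
    """A trainable tensor (requires_grad regardless of the grad context)."""

    def __init__(self, data):
        super().__init__(np.asarray(data))
        self.requires_grad = True


def concatenate(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    tensors = list(tensors)
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def back(g):
        grads = []
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(int(lo), int(hi))
            grads.append((t, g[tuple(sl)]))
        return tuple(grads)

    return Tensor._make(np.concatenate(datas, axis=axis), tensors, back)
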