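"""Minimal reverse-mode automatic differentiation over dense numpy arrays.

Supports exactly the operations the cooperative autoencoder needs: broadcast
arithmetic, matrix products, a handful of elementwise nonlinearities, masked
row-softmax (for graph attention) and reductions. Everything is float64 and
deterministic. Not a general framework — shapes are small and dense, which is
the regime this package targets (full-batch training on a few thousand cells).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum out prepended axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were broadcast from size 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents: tuple = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = _parents

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def T(self) -> "Tensor":
        out = Tensor(self.data.T, self.requires_grad, (self,))

        def bw(g):
            return (g.T,)

        out._backward = bw
        return out

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.ones_like(self.data)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.requires_grad and not t._parents:
                t.grad = g if t.grad is None else t.grad + g
            if t._backward is None:
                continue
            for p, pg in zip(t._parents, t._backward(g)):
                if pg is None:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, self.requires_grad or other.requires_grad,
                     (self, other))
        out._backward = lambda g: (_unbroadcast(g, self.shape),
                                   _unbroadcast(g, other.shape))
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))
        out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, self.requires_grad or other.requires_grad,
                     (self, other))
        out._backward = lambda g: (_unbroadcast(g * other.data, self.shape),
                                   _unbroadcast(g * self.data, other.shape))
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, self.requires_grad or other.requires_grad,
                     (self, other))
        out._backward = lambda g: (
            _unbroadcast(g / other.data, self.shape),
            _unbroadcast(-g * self.data / other.data ** 2, other.shape),
        )
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, self.requires_grad or other.requires_grad,
                     (self, other))
        out._backward = lambda g: (g @ other.data.T, self.data.T @ g)
        return out

    def square(self):
        out = Tensor(self.data ** 2, self.requires_grad, (self,))
        out._backward = lambda g: (2.0 * self.data * g,)
        return out

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, self.requires_grad, (self,))
        out._backward = lambda g: (g * exponent * self.data ** (exponent - 1.0),)
        return out

    # --------------------------------------------------------------- reducers
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def bw(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.shape).copy(),)

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ----------------------------------------------------------- elementwise
    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, self.requires_grad, (self,))
        out._backward = lambda g: (g * val,)
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))
        out._backward = lambda g: (g / self.data,)
        return out

    def sigmoid(self):
        val = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(val, self.requires_grad, (self,))
        out._backward = lambda g: (g * val * (1.0 - val),)
        return out

    def leaky_relu(self, slope: float = 0.2):
        pos = self.data > 0
        out = Tensor(np.where(pos, self.data, slope * self.data),
                     self.requires_grad, (self,))
        out._backward = lambda g: (np.where(pos, g, slope * g),)
        return out

    def elu(self, alpha: float = 1.0):
        pos = self.data > 0
        ex = alpha * (np.exp(np.minimum(self.data, 0.0)) - 1.0)
        out = Tensor(np.where(pos, self.data, ex), self.requires_grad, (self,))
        out._backward = lambda g: (np.where(pos, g, g * (ex + alpha)),)
        return out

    def masked_row_softmax(self, mask: np.ndarray):
        """Softmax over each row restricted to ``mask`` (binary, same shape).

        Entries outside the mask are exactly 0 in the output; each masked row
        must have at least one active entry.
        """
        m = np.asarray(mask, dtype=bool)
        shifted = np.where(m, self.data, -np.inf)
        shifted = shifted - shifted.max(axis=1, keepdims=True)
        e = np.exp(shifted)
        alpha = e / e.sum(axis=1, keepdims=True)
        out = Tensor(alpha, self.requires_grad, (self,))

        def bw(g):
            dot = (g * alpha).sum(axis=1, keepdims=True)
            return (alpha * (g - dot),)

        out._backward = bw
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)
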