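"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the segmentation framework needs: elementwise
arithmetic, exp/log/sigmoid/relu, reductions, channel softmax and concatenation.
Convolution, pooling and resampling primitives live in :mod:`chorangio.nn.ops`.
Everything is float32.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat", "softmax"]


def as_tensor(x) -> "Tensor":
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=np.float32))


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    # -- bookkeeping ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float32, copy=True)
        else:
            self.grad += g

    def _wants_grad(self) -> bool:
        return self.requires_grad or bool(self._parents)

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo, visited, stack = [], set(), [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
                if node is not self and not node.requires_grad:
                    node._backward = None
                    node.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={'yes' if self.grad is not None else 'no'})"

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = _node(self.data + other.data, (self, other))

        def bw(g):
            if self._wants_grad():
                self.accumulate(_unbroadcast(g, self.shape))
            if other._wants_grad():
                other.accumulate(_unbroadcast(g, other.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        out = _node(self.data * other.data, (self, other))

        def bw(g):
            if self._wants_grad():
                self.accumulate(_unbroadcast(g * other.data, self.shape))
            if other._wants_grad():
                other.accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * np.float32(-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = as_tensor(other)
        out = _node(self.data / other.data, (self, other))

        def bw(g):
            if self._wants_grad():
                self.accumulate(_unbroadcast(g / other.data, self.shape))
            if other._wants_grad():
                other.accumulate(
                    _unbroadcast(-g * self.data / (other.data ** 2), other.shape)
                )

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out = _node(self.data ** p, (self,))

        def bw(g):
            if self._wants_grad():
                self.accumulate(g * p * self.data ** (p - 1))

        out._backward = bw
        return out

    # -- elementwise nonlinearities -----------------------------------
    def exp(self):
        e = np.exp(self.data)
        out = _node(e, (self,))

        def bw(g):
            if self._wants_grad():
                self.accumulate(g * e)

        out._backward = bw
        return out

    def log(self):
        out = _node(np.log(self.data), (self,))

        def bw(g):
            if self._wants_grad():
                self.accumulate(g / self.data)

        out._backward = bw
        return out

    def sigmoid(self):
        x = self.data
        s = np.where(x >= 0, 1.0 / (1.0 + np.exp(-x)), np.exp(x) / (1.0 + np.exp(x))).astype(
            np.float32
        )
        out = _node(s, (self,))

        def bw(g):
            if self._wants_grad():
                self.accumulate(g * s * (1.0 - s))

        out._backward = bw
        return out

    def relu(self):
        out = _node(np.maximum(self.data, 0.0), (self,))

        def bw(g):
            if self._wants_grad():
                self.accumulate(g * (self.data > 0))

        out._backward = bw
        return out

    def leaky_relu(self, slope: float = 0.2):
        mask = self.data > 0
        out = _node(np.where(mask, self.data, slope * self.data), (self,))

        def bw(g):
            if self._wants_grad():
                self.accumulate(g * np.where(mask, 1.0, slope).astype(np.float32))

        out._backward = bw
        return out

    def clamp_min(self, lo: float):
        mask = self.data > lo
        out = _node(np.maximum(self.data, lo), (self,))

        def bw(g):
            if self._wants_grad():
                self.accumulate(g * mask)

        out._backward = bw
        return out

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = _node(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            if self._wants_grad():
                self.accumulate(np.broadcast_to(g, self.shape))

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * np.float32(1.0 / n)

    def reshape(self, *shape):
        out = _node(self.data.reshape(*shape), (self,))

        def bw(g):
            if self._wants_grad():
                self.accumulate(g.reshape(self.shape))

        out._backward = bw
        return out


def _node(data: np.ndarray, parents: tuple) -> Tensor:
    t = Tensor(data)
    t._parents = tuple(p for p in parents if isinstance(p, Tensor))
    return t


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    ndim_out = tensors[0].ndim

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t._wants_grad():
                sl = [slice(None)] * ndim_out
                sl[axis] = slice(lo, hi)
                t.accumulate(g[tuple(sl)])

    out._backward = bw
    return out


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    """Numerically stable softmax along `axis` with analytic backward."""
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=axis, keepdims=True)
    out = _node(p.astype(np.float32), (x,))

    pdata = out.data

    def bw(g):
        if x._wants_grad():
            dot = (g * pdata).sum(axis=axis, keepdims=True)
            x.accumulate(pdata * (g - dot))

    out._backward = bw
    return out
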