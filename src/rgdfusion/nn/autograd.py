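"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery to train the small convolutional backbones, the
two-layer GCN and the fusion heads: broadcasting elementwise arithmetic,
matmul, relu/sigmoid/log/power, reductions, reshape/concat, and an
im2col-style gather with a scatter-add backward (convolutions are expressed
as gather + matmul).  Float32 throughout.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "relu", "sigmoid", "clip"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph bookkeeping --------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def _child(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad += grad

    def backward(self) -> None:
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
                if p.requires_grad:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic ---------------------------------------------------------

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return self._child(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return self._child(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return self._child(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.shape))

        return self._child(np.matmul(self.data, other.data), (self, other), backward)

    def pow_const(self, exponent: float) -> "Tensor":
        out_data = np.power(self.data, exponent)

        def backward(g):
            if self.requires_grad:
                self._accum(g * exponent * np.power(self.data, exponent - 1.0))

        return self._child(out_data, (self,), backward)

    def log(self) -> "Tensor":
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return self._child(np.log(self.data), (self,), backward)

    # -- reductions / shaping ----------------------------------------------

    def sum(self, axis=None, keepdims=False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).astype(np.float32))
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.shape).astype(np.float32))

        return self._child(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape) -> "Tensor":
        orig = self.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))

        return self._child(self.data.reshape(*shape), (self,), backward)

    def gather_flat(self, index: np.ndarray, out_size_last: int | None = None):
        """Fancy-gather on the flattened trailing axes: ``x.reshape(B,-1)[:, index]``.

        ``index`` may be any integer ndarray; output shape (B, *index.shape).
        Backward scatter-adds into the flattened input.
        """
        B = self.data.shape[0]
        flat = self.data.reshape(B, -1)
        out_data = flat[:, index]

        def backward(g):
            if not self.requires_grad:
                return
            buf = np.zeros_like(flat)
            np.add.at(buf, (slice(None), index), g)
            self._accum(buf.reshape(self.shape))

        return self._child(out_data, (self,), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g):
        if x.requires_grad:
            x._accum(g * mask)

    return x._child(x.data * mask, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -30.0, 30.0)))

    def backward(g):
        if x.requires_grad:
            x._accum(g * s * (1.0 - s))

    return x._child(s, (x,), backward)


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    mask = (x.data >= lo) & (x.data <= hi)

    def backward(g):
        if x.requires_grad:
            x._accum(g * mask)

    return x._child(np.clip(x.data, lo, hi), (x,), backward)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    out = Tensor(out_data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)

        def backward(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accum(piece)

        out._backward = backward
    return out
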