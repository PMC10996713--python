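"""Minimal reverse-mode automatic differentiation on numpy arrays.

Float64 tensors, a dynamically built tape, and exactly the operator set the
transformer backbone and its losses need: broadcasting arithmetic, matmul,
reductions, exp/log/sigmoid/relu/sqrt, a numerically stable softmax, basic
slicing, concatenation, and an embedding gather with scatter-add gradients.
Gradient correctness is enforced by finite-difference tests rather than by
construction, so keep new operators small and verifiable.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction -------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    # -- arithmetic ----------------------------------------------------------

    def __add__(self, other):
        a, b = self, Tensor._lift(other)
        data = a.data + b.data

        def backward(g):
            return _unbroadcast(g, a.shape), _unbroadcast(g, b.shape)

        return Tensor._make(data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._make(-a.data, (a,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        a, b = self, Tensor._lift(other)
        data = a.data * b.data

        def backward(g):
            return _unbroadcast(g * b.data, a.shape), _unbroadcast(g * a.data, b.shape)

        return Tensor._make(data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, Tensor._lift(other)
        data = a.data / b.data

        def backward(g):
            ga = _unbroadcast(g / b.data, a.shape)
            gb = _unbroadcast(-g * a.data / (b.data**2), b.shape)
            return ga, gb

        return Tensor._make(data, (a, b), backward)

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, exponent: float):
        a = self
        data = a.data**exponent

        def backward(g):
            return (g * exponent * a.data ** (exponent - 1),)

        return Tensor._make(data, (a,), backward)

    def __matmul__(self, other):
        a, b = self, Tensor._lift(other)
        data = a.data @ b.data

        def backward(g):
            ga = g @ np.swapaxes(b.data, -1, -2)
            gb = np.swapaxes(a.data, -1, -2) @ g
            return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)

        return Tensor._make(data, (a, b), backward)

    # -- elementwise nonlinearities ------------------------------------------

    def exp(self):
        a = self
        data = np.exp(a.data)
        return Tensor._make(data, (a,), lambda g: (g * data,))

    def log(self):
        a = self
        return Tensor._make(np.log(a.data), (a,), lambda g: (g / a.data,))

    def sqrt(self):
        a = self
        data = np.sqrt(a.data)
        return Tensor._make(data, (a,), lambda g: (g * 0.5 / data,))

    def sigmoid(self):
        a = self
        data = 1.0 / (1.0 + np.exp(-a.data))
        return Tensor._make(data, (a,), lambda g: (g * data * (1.0 - data),))

    def relu(self):
        a = self
        mask = a.data > 0
        return Tensor._make(a.data * mask, (a,), lambda g: (g * mask,))

    def gelu(self):
        """tanh-approximation GELU."""
        a = self
        c = np.sqrt(2.0 / np.pi)
        inner = c * (a.data + 0.044715 * a.data**3)
        t = np.tanh(inner)
        data = 0.5 * a.data * (1.0 + t)

        def backward(g):
            dinner = c * (1.0 + 3 * 0.044715 * a.data**2)
            dt = (1.0 - t**2) * dinner
            return (g * (0.5 * (1.0 + t) + 0.5 * a.data * dt),)

        return Tensor._make(data, (a,), backward)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes only inside the interval."""
        a = self
        data = np.clip(a.data, lo, hi)
        mask = (a.data > lo) & (a.data < hi)
        return Tensor._make(data, (a,), lambda g: (g * mask,))

    # -- reductions and shape ------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        a = self
        data = a.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, a.shape).copy(),)

        return Tensor._make(data, (a,), backward)

    def mean(self, axis=None, keepdims=False):
        a = self
        n = a.data.size if axis is None else a.data.shape[axis]
        return a.sum(axis=axis, keepdims=keepdims) / n

    def reshape(self, *shape):
        a = self
        data = a.data.reshape(*shape)
        return Tensor._make(data, (a,), lambda g: (g.reshape(a.shape),))

    def transpose(self, *axes):
        a = self
        data = a.data.transpose(*axes)
        inv = np.argsort(axes)
        return Tensor._make(data, (a,), lambda g: (g.transpose(*inv),))

    def __getitem__(self, idx):
        a = self
        data = a.data[idx]

        def backward(g):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            return (full,)

        return Tensor._make(data, (a,), backward)

    def softmax(self, axis: int = -1):
        """Numerically stable softmax along ``axis``."""
        a = self
        shifted = a.data - a.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        s = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            return ((g - dot) * s,)

        return Tensor._make(s, (a,), backward)

    # -- autodiff ------------------------------------------------------------

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
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
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if not parent.requires_grad or g is None:
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad += g

    def zero_grad(self):
        self.grad = None


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    parts = [Tensor._lift(t) for t in tensors]
    data = np.concatenate([p.data for p in parts], axis=axis)
    sizes = [p.data.shape[axis] for p in parts]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        out = []
        for p, lo, hi in zip(parts, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            out.append(g[tuple(sl)])
        return tuple(out)

    return Tensor._make(data, tuple(parts), backward)


def gather_rows(table: Tensor, idx: np.ndarray) -> Tensor:
    """Embedding lookup: rows ``table[idx]`` with scatter-add gradient."""
    idx = np.asarray(idx)
    data = table.data[idx]

    def backward(g):
        full = np.zeros_like(table.data)
        np.add.at(full, idx, g)
        return (full,)

    return Tensor._make(data, (table,), backward)


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis."""
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    return centered / (var + eps).sqrt() * gain + bias


class AdamW:
    """AdamW with decoupled weight decay (default 0: L2 lives in the loss)."""

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
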