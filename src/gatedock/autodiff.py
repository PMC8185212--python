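"""Minimal reverse-mode automatic differentiation on numpy arrays.

The scoring network needs gradients with respect to ordinary dense
parameters *and* the two scalar edge parameters (mu, sigma) that sit
inside the adjacency matrix of the cross-molecular graph, so the edge
weights have to be rebuilt inside the differentiated computation on
every forward pass.  This module provides just enough of a tape-based
autodiff engine to express that computation: broadcast-aware
elementwise arithmetic, (batched) matmul, the nonlinearities the
network uses, reductions, concatenation and masked selection.

Everything is float64.  Gradients are accumulated into ``Tensor.grad``
by :meth:`Tensor.backward`, which walks the tape in reverse
topological order.  The engine is deliberately small; it is validated
against central finite differences in the test-suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "add",
    "sub",
    "mul",
    "div",
    "neg",
    "matmul",
    "transpose_last",
    "exp",
    "log",
    "sigmoid",
    "softplus",
    "relu",
    "clip",
    "square",
    "tsum",
    "mean",
    "concat",
    "split2",
    "where_const",
]


def _to_array(x) -> np.ndarray:
    return np.asarray(x, dtype=np.float64)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away leading dims
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over broadcast (size-1) dims
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus the tape bookkeeping needed for backprop."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _to_array(data)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- misc -----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- operator sugar ---------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return neg(self)

    def __matmul__(self, other):
        return matmul(self, other)

    @property
    def T(self):
        return transpose_last(self)

    # -- backward ---------------------------------------------------------
    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        else:
            grad = _to_array(grad)

        # topological order of the tape reachable from self
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))

        grads: dict[int, np.ndarray] = {id(self): grad}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g.copy() if node.grad is None else node.grad + g
            if node._backward is None:
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if pg is None:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg


def tensor(data, requires_grad: bool = False) -> Tensor:
    return data if isinstance(data, Tensor) else Tensor(data, requires_grad)


def _needs_tape(*ts: Tensor) -> bool:
    return any(t.requires_grad or t._parents for t in ts)


def _make(data: np.ndarray, parents: tuple[Tensor, ...], backward) -> Tensor:
    out = Tensor(data)
    if _needs_tape(*parents):
        out._parents = parents
        out._backward = backward
    return out


# -- arithmetic ------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = tensor(a), tensor(b)
    data = a.data + b.data

    def back(g):
        return _unbroadcast(g, a.shape), _unbroadcast(g, b.shape)

    return _make(data, (a, b), back)


def sub(a, b) -> Tensor:
    a, b = tensor(a), tensor(b)
    data = a.data - b.data

    def back(g):
        return _unbroadcast(g, a.shape), _unbroadcast(-g, b.shape)

    return _make(data, (a, b), back)


def mul(a, b) -> Tensor:
    a, b = tensor(a), tensor(b)
    data = a.data * b.data

    def back(g):
        return (
            _unbroadcast(g * b.data, a.shape),
            _unbroadcast(g * a.data, b.shape),
        )

    return _make(data, (a, b), back)


def div(a, b) -> Tensor:
    a, b = tensor(a), tensor(b)
    data = a.data / b.data

    def back(g):
        return (
            _unbroadcast(g / b.data, a.shape),
            _unbroadcast(-g * a.data / (b.data**2), b.shape),
        )

    return _make(data, (a, b), back)


def neg(a) -> Tensor:
    a = tensor(a)

    def back(g):
        return (-g,)

    return _make(-a.data, (a,), back)


def matmul(a, b) -> Tensor:
    """Matrix product with numpy batching semantics (stacks of matrices)."""
    a, b = tensor(a), tensor(b)
    data = a.data @ b.data

    def back(g):
        ad, bd = a.data, b.data
        if ad.ndim == 1 and bd.ndim == 1:  # inner product
            return g * bd, g * ad
        ga = gb = None
        if ad.ndim == 1:  # (k,) @ (..., k, n)
            ga = _unbroadcast(g[..., None, :] @ bd.swapaxes(-1, -2), ad.shape).reshape(ad.shape)
            gb = _unbroadcast(ad[..., :, None] * g[..., None, :], bd.shape)
        elif bd.ndim == 1:  # (..., m, k) @ (k,)
            ga = _unbroadcast(g[..., :, None] * bd[None, :], ad.shape)
            gb = _unbroadcast((ad * g[..., :, None]).sum(axis=tuple(range(ad.ndim - 1))), bd.shape)
        else:
            ga = _unbroadcast(g @ bd.swapaxes(-1, -2), ad.shape)
            gb = _unbroadcast(ad.swapaxes(-1, -2) @ g, bd.shape)
        return ga, gb

    return _make(data, (a, b), back)


def transpose_last(a) -> Tensor:
    """Swap the last two axes."""
    a = tensor(a)

    def back(g):
        return (g.swapaxes(-1, -2),)

    return _make(a.data.swapaxes(-1, -2), (a,), back)


# -- nonlinearities ----------------------------------------------------------

def exp(a) -> Tensor:
    a = tensor(a)
    data = np.exp(a.data)

    def back(g):
        return (g * data,)

    return _make(data, (a,), back)


def log(a) -> Tensor:
    a = tensor(a)

    def back(g):
        return (g / a.data,)

    return _make(np.log(a.data), (a,), back)


def sigmoid(a) -> Tensor:
    a = tensor(a)
    data = 1.0 / (1.0 + np.exp(-np.clip(a.data, -500, 500)))

    def back(g):
        return (g * data * (1.0 - data),)

    return _make(data, (a,), back)


def softplus(a) -> Tensor:
    """log(1 + e^x), computed stably; gradient is the logistic function."""
    a = tensor(a)
    data = np.logaddexp(0.0, a.data)

    def back(g):
        return (g / (1.0 + np.exp(-np.clip(a.data, -500, 500))),)

    return _make(data, (a,), back)


def relu(a) -> Tensor:
    a = tensor(a)
    mask = a.data > 0

    def back(g):
        return (g * mask,)

    return _make(a.data * mask, (a,), back)


def clip(a, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient passes through only inside the bounds."""
    a = tensor(a)
    mask = (a.data >= lo) & (a.data <= hi)

    def back(g):
        return (g * mask,)

    return _make(np.clip(a.data, lo, hi), (a,), back)


def square(a) -> Tensor:
    a = tensor(a)

    def back(g):
        return (2.0 * g * a.data,)

    return _make(a.data**2, (a,), back)


# -- reductions, shape ops ----------------------------------------------------

def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def back(g):
        if axis is None:
            return (np.broadcast_to(g, a.shape).astype(np.float64),)
        g2 = g if keepdims else np.expand_dims(g, axis)
        return (np.broadcast_to(g2, a.shape).astype(np.float64),)

    return _make(data, (a,), back)


def mean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = tensor(a)
    n = a.data.size if axis is None else a.data.shape[axis]
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def concat(tensors, axis: int = -1) -> Tensor:
    ts = [tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        return tuple(np.split(g, splits, axis=axis))

    return _make(data, tuple(ts), back)


def split2(a, k: int) -> tuple[Tensor, Tensor]:
    """Split the leading axis at k into two views (differentiable)."""
    a = tensor(a)
    first, second = a.data[:k], a.data[k:]

    def back_first(g):
        full = np.zeros_like(a.data)
        full[:k] = g
        return (full,)

    def back_second(g):
        full = np.zeros_like(a.data)
        full[k:] = g
        return (full,)

    return (_make(first, (a,), back_first), _make(second, (a,), back_second))


def where_const(mask: np.ndarray, a, fill: float) -> Tensor:
    """``mask ? a : fill`` with a constant fill; grads flow only through ``a``."""
    a = tensor(a)
    mask = np.asarray(mask, dtype=bool)
    data = np.where(mask, a.data, fill)

    def back(g):
        return (_unbroadcast(g * mask, a.shape),)

    return _make(data, (a,), back)


# -- optimizer ----------------------------------------------------------------

class Adam:
    """Adam with optional L2 weight decay folded into the gradient."""

    def __init__(self, params: list[Tensor], lr: float = 0.002,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = float(weight_decay)
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
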