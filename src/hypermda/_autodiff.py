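"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the association model needs: broadcast
arithmetic, matrix products, row gathering/concatenation, reductions,
`exp`/`log`/`sqrt`, rectifier and logistic nonlinearities, and softmax.
Gradients are accumulated into ``Tensor.grad`` by :meth:`Tensor.backward`
via a topological sweep of the recorded tape.

The engine is deliberately small; anything expressible through these
primitives differentiates correctly, which the finite-difference tests
assert.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "relu", "sigmoid", "softmax", "concat_rows", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum out prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, n in enumerate(shape):
        if n == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """An array node in the differentiation tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    # make numpy defer binary operations to this class's reflected methods
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _make(self, data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)

        def backward(g, out):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, out):
            if self.requires_grad:
                self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)

        def backward(g, out):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)

        def backward(g, out):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return self._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")

        def backward(g, out):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1))

        return self._make(self.data**exponent, (self,), backward)

    def __matmul__(self, other):
        other = as_tensor(other)

        def backward(g, out):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), backward)

    def __rmatmul__(self, other):
        return as_tensor(other) @ self

    @property
    def T(self):
        def backward(g, out):
            if self.requires_grad:
                self._accum(g.T)

        return self._make(self.data.T, (self,), backward)

    # -- reductions and elementwise maps --------------------------------------
    def sum(self, axis=None, keepdims=False):
        def backward(g, out):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                ge = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(ge, self.data.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    def exp(self):
        value = np.exp(self.data)

        def backward(g, out):
            if self.requires_grad:
                self._accum(g * value)

        return self._make(value, (self,), backward)

    def log(self):
        def backward(g, out):
            if self.requires_grad:
                self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        value = np.sqrt(self.data)

        def backward(g, out):
            if self.requires_grad:
                self._accum(g * 0.5 / value)

        return self._make(value, (self,), backward)

    def abs(self):
        sign = np.sign(self.data)

        def backward(g, out):
            if self.requires_grad:
                self._accum(g * sign)

        return self._make(np.abs(self.data), (self,), backward)

    def clip_min(self, lo: float):
        """max(x, lo); subgradient 0 where clipped."""
        mask = self.data > lo

        def backward(g, out):
            if self.requires_grad:
                self._accum(g * mask)

        return self._make(np.maximum(self.data, lo), (self,), backward)

    def rows(self, index):
        """Gather rows by integer index (pair lookup in the scorer)."""
        index = np.asarray(index, dtype=np.intp)

        def backward(g, out):
            if self.requires_grad:
                acc = np.zeros_like(self.data)
                np.add.at(acc, index, g)
                self._accum(acc)

        return self._make(self.data[index], (self,), backward)

    def reshape(self, *shape):
        def backward(g, out):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))

        return self._make(self.data.reshape(*shape), (self,), backward)

    # -- autodiff machinery ----------------------------------------------------
    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(node: Tensor):
            if id(node) in seen or not node.requires_grad:
                return
            seen.add(id(node))
            for parent in node._parents:
                visit(parent)
            topo.append(node)

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad, node)

    def item(self) -> float:
        return float(self.data.reshape(()))


def as_tensor(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)


def _stable_sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g, out):
        if x.requires_grad:
            x._accum(g * mask)

    return x._make(np.maximum(x.data, 0.0), (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    value = _stable_sigmoid(x.data)

    def backward(g, out):
        if x.requires_grad:
            x._accum(g * value * (1.0 - value))

    return x._make(value, (x,), backward)


def softmax(x: Tensor) -> Tensor:
    """Softmax over the last axis, computed via stable primitives."""
    shifted = x - float(x.data.max())
    e = shifted.exp()
    return e / e.sum(axis=-1, keepdims=True)


def concat_rows(parts: list[Tensor]) -> Tensor:
    parts = [as_tensor(p) for p in parts]
    sizes = [p.data.shape[0] for p in parts]
    offsets = np.cumsum([0] + sizes)

    out = Tensor(np.concatenate([p.data for p in parts], axis=0))
    if any(p.requires_grad for p in parts):
        out.requires_grad = True
        out._parents = tuple(parts)

        def backward(g, _):
            for p, lo, hi in zip(parts, offsets[:-1], offsets[1:]):
                if p.requires_grad:
                    p._accum(g[lo:hi])

        out._backward = backward
    return out


class Adam:
    """Adaptive-moment gradient descent over a list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self._m[i] = self.b1 * self._m[i] + (1 - self.b1) * g
            self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * g * g
            m_hat = self._m[i] / (1 - self.b1**self.t)
            v_hat = self._v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
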