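"""Reverse-mode automatic differentiation over NumPy arrays.

The engine records an acyclic computation graph eagerly: every operation
returns a :class:`Tensor` holding its value and, for each differentiable
parent, a vector-Jacobian-product (VJP) closure.  Calling
:meth:`Tensor.backward` on a scalar output propagates cotangents to every
leaf created with ``requires_grad=True``.

All arithmetic is double precision by default.  Complex quantities are
carried as explicit real/imaginary pairs ("duplets") by the operator layer,
so differentiation of complex-valued models reduces to ordinary real
differentiation of the paired coordinates (Wirtinger-style derivatives).

Only the primitives needed by the imaging forward models are provided; this
is not a general deep-learning framework.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "astensor", "constant"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were 1 in the original shape
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node of the computation graph wrapping a ``float64`` ndarray."""

    __slots__ = ("value", "grad", "requires_grad", "_parents")

    def __init__(self, value, requires_grad: bool = False,
                 _parents: Sequence[tuple] = ()):  # (Tensor, vjp) pairs
        self.value = np.asarray(value, dtype=np.float64)
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p, _ in _parents)
        self.grad = None
        self._parents = tuple(_parents) if self.requires_grad else ()

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def _op(value, parents):
        parents = [(p, v) for p, v in parents if p.requires_grad]
        return Tensor(value, _parents=parents)

    @property
    def shape(self):
        return self.value.shape

    @property
    def ndim(self):
        return self.value.ndim

    @property
    def size(self):
        return self.value.size

    def __repr__(self):
        return f"Tensor(shape={self.value.shape}, requires_grad={self.requires_grad})"

    # -- autodiff ------------------------------------------------------------
    def backward(self, grad=None):
        """Accumulate gradients of ``self`` (a scalar unless ``grad`` given)
        into every reachable leaf with ``requires_grad=True``."""
        if grad is None:
            if self.value.size != 1:
                raise ValueError("backward() without an explicit cotangent "
                                 "requires a scalar output")
            grad = np.ones_like(self.value)
        grad = np.asarray(grad, dtype=np.float64)

        # topological order (iterative, graph may be deep)
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
            for parent, _ in node._parents:
                if id(parent) not in seen:
                    stack.append((parent, False))

        grads: dict[int, np.ndarray] = {id(self): grad}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if not node._parents:  # leaf
                if node.requires_grad:
                    node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, vjp in node._parents:
                pg = vjp(g)
                pg = _unbroadcast(np.asarray(pg, dtype=np.float64), parent.value.shape)
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg

    def zero_grad(self):
        self.grad = None

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = astensor(other)
        return Tensor._op(self.value + other.value,
                          [(self, lambda g: g), (other, lambda g: g)])

    __radd__ = __add__

    def __sub__(self, other):
        other = astensor(other)
        return Tensor._op(self.value - other.value,
                          [(self, lambda g: g), (other, lambda g: -g)])

    def __rsub__(self, other):
        return astensor(other) - self

    def __mul__(self, other):
        other = astensor(other)
        a, b = self.value, other.value
        return Tensor._op(a * b,
                          [(self, lambda g: g * b), (other, lambda g: g * a)])

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = astensor(other)
        a, b = self.value, other.value
        return Tensor._op(a / b,
                          [(self, lambda g: g / b),
                           (other, lambda g: -g * a / (b * b))])

    def __rtruediv__(self, other):
        return astensor(other) / self

    def __neg__(self):
        return Tensor._op(-self.value, [(self, lambda g: -g)])

    def __pow__(self, p):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")
        a = self.value
        return Tensor._op(a ** p, [(self, lambda g: g * p * a ** (p - 1))])

    def __getitem__(self, idx):
        a = self.value

        def vjp(g):
            out = np.zeros_like(a)
            np.add.at(out, idx, g)
            return out

        return Tensor._op(a[idx], [(self, vjp)])

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.value.shape
        return Tensor._op(self.value.reshape(shape),
                          [(self, lambda g: g.reshape(old))])

    def ravel(self):
        return self.reshape(-1)

    def sum(self, axis=None, keepdims=False):
        a_shape = self.value.shape

        def vjp(g):
            if axis is None:
                return np.broadcast_to(g, a_shape).copy()
            g2 = g if keepdims else np.expand_dims(g, axis)
            return np.broadcast_to(g2, a_shape).copy()

        return Tensor._op(self.value.sum(axis=axis, keepdims=keepdims),
                          [(self, vjp)])

    def item(self) -> float:
        return float(self.value)


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def constant(x) -> Tensor:
    """A graph leaf that never receives gradients."""
    return Tensor(x, requires_grad=False)


# -- elementwise functions ----------------------------------------------------

def sqrt(x: Tensor) -> Tensor:
    x = astensor(x)
    val = np.sqrt(x.value)
    return Tensor._op(val, [(x, lambda g: g * 0.5 / val)])


def exp(x: Tensor) -> Tensor:
    x = astensor(x)
    val = np.exp(x.value)
    return Tensor._op(val, [(x, lambda g: g * val)])


def log(x: Tensor) -> Tensor:
    x = astensor(x)
    return Tensor._op(np.log(x.value), [(x, lambda g: g / x.value)])


def sin(x: Tensor) -> Tensor:
    x = astensor(x)
    return Tensor._op(np.sin(x.value), [(x, lambda g: g * np.cos(x.value))])


def cos(x: Tensor) -> Tensor:
    x = astensor(x)
    return Tensor._op(np.cos(x.value), [(x, lambda g: -g * np.sin(x.value))])


def absolute(x: Tensor) -> Tensor:
    """|x| with the subgradient convention sign(0) = 0."""
    x = astensor(x)
    s = np.sign(x.value)
    return Tensor._op(np.abs(x.value), [(x, lambda g: g * s)])


def clip(x: Tensor, lo, hi) -> Tensor:
    """Clamp to [lo, hi]; gradient passes through where unclamped."""
    x = astensor(x)
    val = np.clip(x.value, lo, hi)
    inside = ((x.value >= lo) & (x.value <= hi)).astype(np.float64)
    return Tensor._op(val, [(x, lambda g: g * inside)])


def softplus(x: Tensor) -> Tensor:
    """log(1 + exp(x)), computed stably; derivative is the logistic."""
    x = astensor(x)
    v = x.value
    val = np.maximum(v, 0.0) + np.log1p(np.exp(-np.abs(v)))
    sig = 1.0 / (1.0 + np.exp(-v))
    return Tensor._op(val, [(x, lambda g: g * sig)])


def where(cond, a, b) -> Tensor:
    """Elementwise select with a *constant* (non-differentiable) condition."""
    cond = np.asarray(cond, dtype=bool)
    a, b = astensor(a), astensor(b)
    return Tensor._op(np.where(cond, a.value, b.value),
                      [(a, lambda g: np.where(cond, g, 0.0)),
                       (b, lambda g: np.where(cond, 0.0, g))])


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = astensor(a), astensor(b)
    av, bv = a.value, b.value
    if av.ndim == 1 and bv.ndim == 1:
        return Tensor._op(av @ bv, [(a, lambda g: g * bv), (b, lambda g: g * av)])
    if av.ndim == 2 and bv.ndim == 1:
        return Tensor._op(av @ bv, [(a, lambda g: np.outer(g, bv)),
                                    (b, lambda g: av.T @ g)])
    if av.ndim == 1 and bv.ndim == 2:
        return Tensor._op(av @ bv, [(a, lambda g: bv @ g),
                                    (b, lambda g: np.outer(av, g))])
    return Tensor._op(av @ bv, [(a, lambda g: g @ bv.T),
                                (b, lambda g: av.T @ g)])


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    val = np.stack([t.value for t in tensors], axis=axis)
    parents = []
    for i, t in enumerate(tensors):
        def vjp(g, i=i):
            return np.take(g, i, axis=axis)
        parents.append((t, vjp))
    return Tensor._op(val, parents)


def concatenate(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    val = np.concatenate([t.value for t in tensors], axis=axis)
    sizes = [t.value.shape[axis] for t in tensors]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    parents = []
    for i, t in enumerate(tensors):
        lo, hi = int(offsets[i]), int(offsets[i + 1])

        def vjp(g, lo=lo, hi=hi):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            return g[tuple(sl)]
        parents.append((t, vjp))
    return Tensor._op(val, parents)


def linear_map(x: Tensor, fwd: Callable[[np.ndarray], np.ndarray],
               adj: Callable[[np.ndarray], np.ndarray]) -> Tensor:
    """Apply a linear map with a known adjoint; VJP is the adjoint.

    The caller is responsible for ``adj`` truly being the transpose of
    ``fwd`` — the operator test-suite asserts this with dot-product tests.
    """
    x = astensor(x)
    return Tensor._op(fwd(x.value), [(x, lambda g: adj(g))])


def custom(value: np.ndarray, parents: Sequence[tuple]) -> Tensor:
    """Escape hatch for hand-written primitives: ``parents`` is a sequence of
    ``(Tensor, vjp)`` pairs."""
    return Tensor._op(value, parents)
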