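"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations the model stack needs: broadcasting
arithmetic, matmul, elementwise transcendentals (exp, log, softplus,
sigmoid, relu, lgamma), axis reductions, and an Adam optimizer. Values
are float64 throughout; gradients accumulate in float64, which keeps
seeded runs bit-reproducible on a single thread.
"""

from __future__ import annotations

import numpy as np
from scipy import special

__all__ = ["Tensor", "as_tensor", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach its shape."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """Node in the computation graph.

    Leaf tensors (parameters, constants) have no parents. ``grad`` is
    populated by :meth:`backward` for every node reachable from the loss.
    """

    __slots__ = ("value", "grad", "_parents", "_vjps")

    # make `ndarray <op> Tensor` defer to the reflected Tensor operator
    __array_ufunc__ = None

    def __init__(self, value, parents=(), vjps=()):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = None
        self._parents = parents
        self._vjps = vjps

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.value.shape

    @property
    def ndim(self):
        return self.value.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.value.shape})"

    def detach(self) -> "Tensor":
        return Tensor(self.value)

    # -- graph construction --------------------------------------------
    def __add__(self, other):
        o = as_tensor(other)
        return Tensor(
            self.value + o.value,
            parents=(self, o),
            vjps=(
                lambda g: _unbroadcast(g, self.value.shape),
                lambda g: _unbroadcast(g, o.value.shape),
            ),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.value, parents=(self,), vjps=(lambda g: -g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        o = as_tensor(other)
        return Tensor(
            self.value * o.value,
            parents=(self, o),
            vjps=(
                lambda g: _unbroadcast(g * o.value, self.value.shape),
                lambda g: _unbroadcast(g * self.value, o.value.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = as_tensor(other)
        return Tensor(
            self.value / o.value,
            parents=(self, o),
            vjps=(
                lambda g: _unbroadcast(g / o.value, self.value.shape),
                lambda g: _unbroadcast(-g * self.value / o.value**2, o.value.shape),
            ),
        )

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        return Tensor(
            self.value**exponent,
            parents=(self,),
            vjps=(lambda g: g * exponent * self.value ** (exponent - 1),),
        )

    def __matmul__(self, other):
        o = as_tensor(other)
        if self.value.ndim != 2 or o.value.ndim != 2:
            raise ValueError("matmul expects 2-D operands")
        return Tensor(
            self.value @ o.value,
            parents=(self, o),
            vjps=(lambda g: g @ o.value.T, lambda g: self.value.T @ g),
        )

    # -- reductions -----------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        val = self.value.sum(axis=axis, keepdims=keepdims)

        def vjp(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return np.broadcast_to(g, self.value.shape).copy()

        return Tensor(val, parents=(self,), vjps=(vjp,))

    def mean(self, axis=None, keepdims=False):
        n = self.value.size if axis is None else self.value.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # -- autodiff -------------------------------------------------------
    def backward(self):
        if self.value.size != 1:
            raise ValueError("backward() requires a scalar loss")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS topological sort
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
        for node in order:
            node.grad = None
        self.grad = np.ones_like(self.value)
        for node in reversed(order):
            if node.grad is None or not node._parents:
                continue
            for parent, vjp in zip(node._parents, node._vjps):
                contrib = vjp(node.grad)
                if parent.grad is None:
                    parent.grad = contrib
                else:
                    parent.grad = parent.grad + contrib


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- elementwise functions ---------------------------------------------

def exp(x: Tensor) -> Tensor:
    x = as_tensor(x)
    val = np.exp(x.value)
    return Tensor(val, parents=(x,), vjps=(lambda g: g * val,))


def log(x: Tensor) -> Tensor:
    x = as_tensor(x)
    return Tensor(np.log(x.value), parents=(x,), vjps=(lambda g: g / x.value,))


def softplus(x: Tensor) -> Tensor:
    x = as_tensor(x)
    return Tensor(
        np.logaddexp(0.0, x.value),
        parents=(x,),
        vjps=(lambda g: g * special.expit(x.value),),
    )


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    s = special.expit(x.value)
    return Tensor(s, parents=(x,), vjps=(lambda g: g * s * (1.0 - s),))


def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    mask = x.value > 0
    return Tensor(np.where(mask, x.value, 0.0), parents=(x,), vjps=(lambda g: g * mask,))


def lgamma(x: Tensor) -> Tensor:
    x = as_tensor(x)
    return Tensor(
        special.gammaln(x.value),
        parents=(x,),
        vjps=(lambda g: g * special.digamma(x.value),),
    )


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    # subtracting the detached row max is exact for the gradient
    m = np.max(x.value, axis=axis, keepdims=True)
    shifted = x - m
    lse = log(exp(shifted).sum(axis=axis, keepdims=True)) + m
    return x - lse


def logsumexp(x: Tensor, axis: int = -1, keepdims: bool = False) -> Tensor:
    m = np.max(x.value, axis=axis, keepdims=True)
    out = log(exp(x - m).sum(axis=axis, keepdims=True)) + m
    if not keepdims:
        out = Tensor(
            np.squeeze(out.value, axis=axis),
            parents=(out,),
            vjps=(lambda g: np.expand_dims(g, axis),),
        )
    return out


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
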