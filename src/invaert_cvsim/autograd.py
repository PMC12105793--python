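"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the network components need: broadcasted
arithmetic, matrix products, elementwise nonlinearities, reductions and
concatenation.  Gradients are accumulated by a topological-order sweep from a
scalar loss.  An Adam optimizer with optional l2 weight decay and step decay
is included.

Gradient correctness is property-tested against central finite differences.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes that were size 1
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with a gradient tape entry."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, value, requires_grad: bool = False,
                 _parents=(), _backward=None):
        self.value = np.asarray(value, dtype=float)
        self.grad = None
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    # -- construction helpers ----------------------------------------------
    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.value.shape

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other):
        other = Tensor.as_tensor(other)

        def bwd(g):
            return (_unbroadcast(g, self.shape),
                    _unbroadcast(g, other.shape))

        return Tensor(self.value + other.value, _parents=(self, other),
                      _backward=bwd)

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.value, _parents=(self,),
                      _backward=lambda g: (-g,))

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        other = Tensor.as_tensor(other)

        def bwd(g):
            return (_unbroadcast(g * other.value, self.shape),
                    _unbroadcast(g * self.value, other.shape))

        return Tensor(self.value * other.value, _parents=(self, other),
                      _backward=bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor.as_tensor(other)

        def bwd(g):
            return (_unbroadcast(g / other.value, self.shape),
                    _unbroadcast(-g * self.value / other.value ** 2,
                                 other.shape))

        return Tensor(self.value / other.value, _parents=(self, other),
                      _backward=bwd)

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")

        def bwd(g):
            return (g * exponent * self.value ** (exponent - 1),)

        return Tensor(self.value ** exponent, _parents=(self,), _backward=bwd)

    def __matmul__(self, other):
        other = Tensor.as_tensor(other)

        def bwd(g):
            return (g @ other.value.T, self.value.T @ g)

        return Tensor(self.value @ other.value, _parents=(self, other),
                      _backward=bwd)

    # -- elementwise nonlinearities ----------------------------------------
    def exp(self):
        out_val = np.exp(self.value)
        return Tensor(out_val, _parents=(self,),
                      _backward=lambda g: (g * out_val,))

    def log(self):
        return Tensor(np.log(self.value), _parents=(self,),
                      _backward=lambda g: (g / self.value,))

    def tanh(self):
        out_val = np.tanh(self.value)
        return Tensor(out_val, _parents=(self,),
                      _backward=lambda g: (g * (1.0 - out_val ** 2),))

    def relu(self):
        mask = self.value > 0

        def bwd(g):
            return (g * mask,)

        return Tensor(np.where(mask, self.value, 0.0), _parents=(self,),
                      _backward=bwd)

    # -- reductions ---------------------------------------------------------
    def sum(self, axis=None):
        def bwd(g):
            g = np.asarray(g)
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            return (np.broadcast_to(np.expand_dims(g, axis), self.shape)
                    .copy(),)

        return Tensor(self.value.sum(axis=axis), _parents=(self,),
                      _backward=bwd)

    def mean(self, axis=None):
        n = (self.value.size if axis is None else self.value.shape[axis])
        return self.sum(axis=axis) * (1.0 / n)

    # -- autodiff -----------------------------------------------------------
    def backward(self):
        if self.value.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(node: "Tensor"):
            stack = [(node, iter(node._parents))]
            seen.add(id(node))
            while stack:
                cur, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen and p.requires_grad:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(cur)
                    stack.pop()

        visit(self)
        for node in topo:
            node.grad = np.zeros_like(node.value)
        self.grad = np.ones_like(self.value)
        for node in reversed(topo):
            if node._backward is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if parent.requires_grad:
                    if parent.grad is None:
                        parent.grad = np.zeros_like(parent.value)
                    parent.grad = parent.grad + g

    def detach(self) -> "Tensor":
        return Tensor(self.value.copy())


def cat(tensors, axis: int = 1) -> Tensor:
    """Concatenate tensors along ``axis`` (differentiable)."""
    tensors = [Tensor.as_tensor(t) for t in tensors]
    sizes = [t.value.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(np.concatenate([t.value for t in tensors], axis=axis),
                  _parents=tuple(tensors), _backward=bwd)


def parameter(value) -> Tensor:
    return Tensor(np.asarray(value, dtype=float), requires_grad=True)


class Adam:
    """Adam with optional (coupled) l2 weight decay and multiplicative
    learning-rate step decay."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g ** 2
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.value = p.value - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def decay_lr(self, factor: float):
        self.lr *= factor
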