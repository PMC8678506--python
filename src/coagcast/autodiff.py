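"""Compact reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for small recurrent and continuous-time models trained
on a desk-scale CPU: a ``Tensor`` wrapping an ndarray with a gradient slot,
the elementwise/matrix operations the models need (with full broadcasting),
topological-order backpropagation, and SGD/Adam optimizers with global-norm
gradient clipping.  Constants (inputs, masks, step sizes) participate as
plain numpy arrays and never allocate gradient state.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "param", "constant", "Adam", "SGD", "clip_grad_norm"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum out broadcast axes so grad matches the original operand shape."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _coerce(other):
    return other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=float))


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=()):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self._parents = parents
        self._backward = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        other = _coerce(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))
        out._backward = back
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = _coerce(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))
        out._backward = back
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-_coerce(other))

    def __rsub__(self, other):
        return _coerce(other) + (-self)

    def __truediv__(self, other):
        other = _coerce(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data ** 2,
                                          other.data.shape))
        out._backward = back
        return out

    def __matmul__(self, other):
        other = _coerce(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def back(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)
        out._backward = back
        return out

    # -- nonlinearities -----------------------------------------------------

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: self._accum(g * (1.0 - y ** 2))
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: self._accum(g * y * (1.0 - y))
        return out

    def exp(self):
        y = np.exp(np.clip(self.data, -60, 60))
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: self._accum(g * y)
        return out

    def relu(self):
        pos = self.data > 0
        out = Tensor(np.where(pos, self.data, 0.0), parents=(self,))
        out._backward = lambda g: self._accum(g * pos)
        return out

    def softplus(self):
        # numerically stable log(1 + exp(x)); derivative is sigmoid(x)
        y = np.maximum(self.data, 0.0) + np.log1p(np.exp(-np.abs(self.data)))
        out = Tensor(y, parents=(self,))
        sig = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out._backward = lambda g: self._accum(g * sig)
        return out

    # -- reductions ---------------------------------------------------------

    def sum(self):
        out = Tensor(self.data.sum(), parents=(self,))
        out._backward = lambda g: self._accum(np.broadcast_to(g, self.data.shape).copy())
        return out

    def mean(self):
        n = self.data.size
        out = Tensor(self.data.mean(), parents=(self,))
        out._backward = lambda g: self._accum(
            np.broadcast_to(g / n, self.data.shape).copy())
        return out

    # -- autodiff driver ----------------------------------------------------

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=float)
        else:
            self.grad = self.grad + g

    def backward(self):
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen or not node.requires_grad:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)
        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def concat(tensors, axis: int = -1) -> Tensor:
    """Concatenate tensors along an axis, routing gradients back by slice."""
    tensors = [_coerce(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def back(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])
    out._backward = back
    return out


Tensor.concat = staticmethod(concat)


def param(data) -> Tensor:
    return Tensor(np.array(data, dtype=float), requires_grad=True)


def constant(data) -> Tensor:
    return Tensor(np.asarray(data, dtype=float))


def clip_grad_norm(params, max_norm: float) -> float:
    total = np.sqrt(sum(float((p.grad ** 2).sum()) for p in params if p.grad is not None))
    if max_norm and total > max_norm:
        scale = max_norm / (total + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad = p.grad * scale
    return total


class SGD:
    def __init__(self, params, lr: float = 0.1):
        self.params = list(params)
        self.lr = lr

    def step(self) -> None:
        for p in self.params:
            if p.grad is not None:
                p.data -= self.lr * p.grad

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class Adam:
    def __init__(self, params, lr: float = 1e-2, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.eps = lr, eps
        self.b1, self.b2 = betas
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g ** 2
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
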