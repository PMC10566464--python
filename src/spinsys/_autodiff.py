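"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations the spin-system network needs: broadcasted
arithmetic, batched matrix products, the usual pointwise nonlinearities,
axis reductions, concatenation and a fused layer-norm primitive.  Gradients
are accumulated through a topologically sorted tape.  Everything is
gradient-checked against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "stack",
    "relu",
    "sigmoid",
    "tanh",
    "layer_norm",
    "slice_last",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A NumPy array with a gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = Tensor._lift(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        a, b = self.data, other.data

        def backward(g):
            return (_unbroadcast(g * b, self.shape), _unbroadcast(g * a, other.shape))

        return self._make(a * b, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        a, b = self.data, other.data

        def backward(g):
            return (
                _unbroadcast(g / b, self.shape),
                _unbroadcast(-g * a / (b * b), other.shape),
            )

        return self._make(a / b, (self, other), backward)

    def __matmul__(self, other):
        other = Tensor._lift(other)
        a, b = self.data, other.data
        out = a @ b

        def backward(g):
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            return (_unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape))

        return self._make(out, (self, other), backward)

    # -- pointwise ------------------------------------------------------------
    def abs(self):
        s = np.sign(self.data)
        return self._make(np.abs(self.data), (self,), lambda g: (g * s,))

    def exp(self):
        out = np.exp(self.data)
        return self._make(out, (self,), lambda g: (g * out,))

    # -- reductions & shaping -------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return self._make(out, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int):
        out = self.data.max(axis=axis)
        argmax = np.expand_dims(self.data.argmax(axis=axis), axis)

        def backward(g):
            full = np.zeros_like(self.data)
            np.put_along_axis(full, argmax, np.expand_dims(g, axis), axis=axis)
            return (full,)

        return self._make(out, (self,), backward)

    def reshape(self, *shape):
        old = self.shape
        return self._make(
            self.data.reshape(*shape), (self,), lambda g: (g.reshape(old),)
        )

    def swapaxes(self, a, b):
        return self._make(
            np.swapaxes(self.data, a, b), (self,), lambda g: (np.swapaxes(g, a, b),)
        )

    def __getitem__(self, idx):
        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        return self._make(self.data[idx], (self,), backward)

    # -- autodiff driver ------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t._backward is None:  # leaf
                t.grad = g if t.grad is None else t.grad + g
                continue
            for parent, pg in zip(t._parents, t._backward(g)):
                if not parent.requires_grad:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg
            if t.requires_grad and not t._parents:  # pragma: no cover
                t.grad = g


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    res = Tensor(out)
    if any(t.requires_grad for t in tensors):
        res.requires_grad = True
        res._parents = tuple(tensors)
        res._backward = backward
    return res


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        return tuple(np.moveaxis(g, axis, 0))

    res = Tensor(out)
    if any(t.requires_grad for t in tensors):
        res.requires_grad = True
        res._parents = tuple(tensors)
        res._backward = backward
    return res


def slice_last(t: Tensor, start: int, stop: int) -> Tensor:
    """Basic slice along the last axis (cheap backward via zero-padding)."""
    t = Tensor._lift(t)
    idx = (Ellipsis, slice(start, stop))

    def backward(g):
        full = np.zeros_like(t.data)
        full[idx] = g
        return (full,)

    return t._make(t.data[idx], (t,), backward)


def relu(t: Tensor) -> Tensor:
    t = Tensor._lift(t)
    mask = t.data > 0
    return t._make(t.data * mask, (t,), lambda g: (g * mask,))


def sigmoid(t: Tensor) -> Tensor:
    t = Tensor._lift(t)
    out = 1.0 / (1.0 + np.exp(-t.data))
    return t._make(out, (t,), lambda g: (g * out * (1.0 - out),))


def tanh(t: Tensor) -> Tensor:
    t = Tensor._lift(t)
    out = np.tanh(t.data)
    return t._make(out, (t,), lambda g: (g * (1.0 - out * out),))


def layer_norm(t: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize over the last axis; `gain`/`bias` have that axis's length."""
    t, gain, bias = Tensor._lift(t), Tensor._lift(gain), Tensor._lift(bias)
    x = t.data
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x - mu) * inv
    out = xhat * gain.data + bias.data
    n = x.shape[-1]

    def backward(g):
        gg = g * gain.data
        # d xhat / d x backprop (standard fused layernorm gradient)
        gx = inv * (
            gg
            - gg.mean(axis=-1, keepdims=True)
            - xhat * (gg * xhat).mean(axis=-1, keepdims=True)
        )
        ggain = _unbroadcast(g * xhat, gain.shape)
        gbias = _unbroadcast(g, bias.shape)
        return (gx, ggain, gbias)

    out_t = Tensor(out)
    if t.requires_grad or gain.requires_grad or bias.requires_grad:
        out_t.requires_grad = True
        out_t._parents = (t, gain, bias)
        out_t._backward = backward
    del n
    return out_t


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
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
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
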