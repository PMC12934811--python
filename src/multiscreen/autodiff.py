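"""Minimal reverse-mode automatic differentiation on numpy arrays.

Provides exactly the operations needed by the gradient-trained models in this
package (the variational dose-response factorization and the few-shot
transformer): broadcasting arithmetic, batched matmul, the usual nonlinearities,
reductions, cumulative sums, gather/scatter indexing, softmax and concatenation,
plus an Adam optimizer over leaf tensors.

Gradients are accumulated by a topological backward sweep. All shapes follow
numpy broadcasting; the backward of a broadcast op sums the upstream gradient
over the broadcast axes (``_unbroadcast``).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "concat", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- graph plumbing ----------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        # topological order
        order, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            order.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for t in reversed(order):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t._backward is None:  # leaf
                t.grad = g if t.grad is None else t.grad + g
                continue
            for parent, pg in zip(t._parents, t._backward(g)):
                if not parent.requires_grad or pg is None:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg
            if not t._parents:  # leaf with closure? not expected
                t.grad = g if t.grad is None else t.grad + g

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        a, b = self, _as_tensor(other)
        out = Tensor._make(
            a.data + b.data,
            (a, b),
            lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)),
        )
        return out

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        a, b = self, _as_tensor(other)
        return Tensor._make(
            a.data * b.data,
            (a, b),
            lambda g: (
                _unbroadcast(g * b.data, a.shape),
                _unbroadcast(g * a.data, b.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, _as_tensor(other)
        return Tensor._make(
            a.data / b.data,
            (a, b),
            lambda g: (
                _unbroadcast(g / b.data, a.shape),
                _unbroadcast(-g * a.data / (b.data ** 2), b.shape),
            ),
        )

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, p: float):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")
        a = self
        return Tensor._make(
            a.data ** p, (a,), lambda g: (g * p * a.data ** (p - 1),)
        )

    def __matmul__(self, other):
        a, b = self, _as_tensor(other)

        def backward(g):
            ga = g @ np.swapaxes(b.data, -1, -2)
            gb = np.swapaxes(a.data, -1, -2) @ g
            return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)

        return Tensor._make(a.data @ b.data, (a, b), backward)

    # -- elementwise nonlinearities ----------------------------------------
    def exp(self):
        y = np.exp(self.data)
        return Tensor._make(y, (self,), lambda g: (g * y,))

    def log(self):
        return Tensor._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sqrt(self):
        y = np.sqrt(self.data)
        return Tensor._make(y, (self,), lambda g: (g * 0.5 / y,))

    def tanh(self):
        y = np.tanh(self.data)
        return Tensor._make(y, (self,), lambda g: (g * (1.0 - y * y),))

    def sigmoid(self):
        # numerically stable logistic
        y = np.where(
            self.data >= 0,
            1.0 / (1.0 + np.exp(-np.clip(self.data, None, 500))),
            np.exp(np.clip(self.data, -500, None))
            / (1.0 + np.exp(np.clip(self.data, -500, None))),
        )
        return Tensor._make(y, (self,), lambda g: (g * y * (1.0 - y),))

    def softplus(self):
        # log(1 + e^x), stable: max(x,0) + log1p(exp(-|x|))
        x = self.data
        y = np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))
        sig = 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))
        return Tensor._make(y, (self,), lambda g: (g * sig,))

    def relu(self):
        m = self.data > 0
        return Tensor._make(self.data * m, (self,), lambda g: (g * m,))

    def gelu(self):
        # tanh approximation
        x = self.data
        c = np.sqrt(2.0 / np.pi)
        inner = c * (x + 0.044715 * x ** 3)
        t = np.tanh(inner)
        y = 0.5 * x * (1.0 + t)

        def backward(g):
            dinner = c * (1.0 + 3 * 0.044715 * x ** 2)
            dy = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t * t) * dinner
            return (g * dy,)

        return Tensor._make(y, (self,), backward)

    # -- reductions & shape ops --------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, a.shape).copy(),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g2, a.shape).copy(),)

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def cumsum(self, axis: int):
        a = self

        def backward(g):
            rev = np.flip(np.cumsum(np.flip(g, axis=axis), axis=axis), axis=axis)
            return (rev,)

        return Tensor._make(np.cumsum(a.data, axis=axis), (a,), backward)

    def reshape(self, *shape):
        a = self
        return Tensor._make(
            a.data.reshape(*shape), (a,), lambda g: (g.reshape(a.shape),)
        )

    def transpose(self, *axes):
        a = self
        axes = axes or tuple(reversed(range(a.ndim)))
        inv = np.argsort(axes)
        return Tensor._make(
            a.data.transpose(axes), (a,), lambda g: (g.transpose(inv),)
        )

    def swapaxes(self, ax1: int, ax2: int):
        a = self
        return Tensor._make(
            np.swapaxes(a.data, ax1, ax2),
            (a,),
            lambda g: (np.swapaxes(g, ax1, ax2),),
        )

    def __getitem__(self, idx):
        a = self

        def backward(g):
            out = np.zeros_like(a.data)
            np.add.at(out, idx, g)
            return (out,)

        return Tensor._make(a.data[idx], (a,), backward)

    def gather(self, indices: np.ndarray):
        """Rows of self at integer `indices` (along axis 0)."""
        return self[np.asarray(indices, dtype=np.intp)]

    def softmax(self, axis: int = -1):
        x = self.data
        m = x.max(axis=axis, keepdims=True)
        e = np.exp(x - m)
        y = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * y).sum(axis=axis, keepdims=True)
            return (y * (g - dot),)

        return Tensor._make(y, (self,), backward)

    def clip_min(self, lo: float):
        m = self.data > lo
        return Tensor._make(np.maximum(self.data, lo), (self,), lambda g: (g * m,))


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
    )


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]

    def backward(g):
        return tuple(np.take(g, i, axis=axis) for i in range(len(tensors)))

    return Tensor._make(
        np.stack([t.data for t in tensors], axis=axis), tensors, backward
    )


class Adam:
    """Adam over a list of leaf Tensors."""

    def __init__(self, params, lr=1e-2, betas=(0.9, 0.999), eps=1e-8):
        self.params = [p for p in params if p.requires_grad]
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
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
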