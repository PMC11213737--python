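"""Minimal vectorized reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations needed by the contrastive encoder and the
affine-coupling normalizing flow: elementwise arithmetic, matmul, relu/tanh,
exp/log/sqrt, axis reductions, reshape/transpose, a flat ``take`` gather
(used to express 3D convolution via im2col), and broadcasting with correct
gradient accumulation. Gradients are checked against finite differences in
the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape``, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- housekeeping ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        out._backward = backward if out.requires_grad else None
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = (lambda g: (-g,)) if out.requires_grad else None
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        out._backward = backward if out.requires_grad else None
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        out._backward = backward if out.requires_grad else None
        return out

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data**p, parents=(self,))
        out._backward = (
            (lambda g: (g * p * self.data ** (p - 1),)) if out.requires_grad else None
        )
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def backward(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            # sum over broadcast batch axes (e.g. batched @ shared-weight)
            while ga.ndim > len(self.shape):
                ga = ga.sum(axis=0)
            while gb.ndim > len(other.shape):
                gb = gb.sum(axis=0)
            return (ga, gb)

        out._backward = backward if out.requires_grad else None
        return out

    # -- nonlinearities ----------------------------------------------------
    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))
        out._backward = (
            (lambda g: (g * (self.data > 0),)) if out.requires_grad else None
        )
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = Tensor(t, parents=(self,))
        out._backward = (lambda g: (g * (1.0 - t**2),)) if out.requires_grad else None
        return out

    def exp(self):
        e = np.exp(self.data)
        out = Tensor(e, parents=(self,))
        out._backward = (lambda g: (g * e,)) if out.requires_grad else None
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = (lambda g: (g / self.data,)) if out.requires_grad else None
        return out

    def sqrt(self):
        s = np.sqrt(self.data)
        out = Tensor(s, parents=(self,))
        out._backward = (lambda g: (g / (2.0 * s),)) if out.requires_grad else None
        return out

    # -- reductions & shaping ---------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        out._backward = backward if out.requires_grad else None
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = (
            (lambda g: (g.reshape(self.shape),)) if out.requires_grad else None
        )
        return out

    def transpose(self, *axes):
        ax = axes if axes else None
        out = Tensor(self.data.transpose(ax), parents=(self,))
        inv = np.argsort(ax) if ax else None
        out._backward = (
            (lambda g: (g.transpose(inv),)) if out.requires_grad else None
        )
        return out

    @property
    def T(self):
        return self.transpose()

    def take_flat(self, idx: np.ndarray):
        """Gather from the flattened array; backward scatter-adds."""
        out = Tensor(self.data.reshape(-1)[idx], parents=(self,))

        def backward(g):
            gx = np.zeros(self.data.size)
            np.add.at(gx, idx.reshape(-1), np.asarray(g).reshape(-1))
            return (gx.reshape(self.shape),)

        out._backward = backward if out.requires_grad else None
        return out

    # -- backprop ----------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is None:
                continue
            grads = node._backward(node.grad)
            for p, g in zip(node._parents, grads):
                if not p.requires_grad:
                    continue
                if p.grad is None:
                    p.grad = np.zeros_like(p.data)
                p.grad += g

    def zero_grad(self):
        self.grad = None


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    out._backward = backward if out.requires_grad else None
    return out


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
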