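"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations needed by the model zoo in this package
(dense nets, encoder-only transformers, random-Fourier-feature heads):
broadcasting arithmetic, matmul (incl. batched), relu/sigmoid/softplus,
cos/exp/log, reductions, reshape/transpose, softmax and layer norm.
Gradient correctness is enforced by numerical-gradient tests.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach `grad.shape` from `shape`."""
    if grad.shape == shape:
        return grad
    # sum over leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array node in a dynamically built computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return self._make(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bw(g):
            a._accum(-g)

        return self._make(-a.data, (a,), bw)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return self._make(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * as_tensor(other) ** -1.0

    def __rtruediv__(self, other):
        return as_tensor(other) * self ** -1.0

    def __pow__(self, exponent: float):
        a = self
        out_data = a.data ** exponent

        def bw(g):
            a._accum(g * exponent * a.data ** (exponent - 1.0))

        return self._make(out_data, (a,), bw)

    def __matmul__(self, other):
        other = as_tensor(other)
        a, b = self, other
        ad, bd = a.data, b.data

        def bw(g):
            # promote 1-D operands to matrices so one code path covers all cases
            a2 = ad[None, :] if ad.ndim == 1 else ad
            b2 = bd[:, None] if bd.ndim == 1 else bd
            g2 = g
            if ad.ndim == 1:
                g2 = np.expand_dims(g2, -2)
            if bd.ndim == 1:
                g2 = np.expand_dims(g2, -1)
            if a.requires_grad:
                ga = g2 @ np.swapaxes(b2, -1, -2)
                if ad.ndim == 1:
                    ga = ga.reshape(ga.shape[:-2] + (ga.shape[-1],))
                a._accum(_unbroadcast(ga, a.shape))
            if b.requires_grad:
                gb = np.swapaxes(a2, -1, -2) @ g2
                if bd.ndim == 1:
                    gb = gb.reshape(gb.shape[:-1])
                b._accum(_unbroadcast(gb, b.shape))

        return self._make(ad @ bd, (a, b), bw)

    # -- elementwise nonlinearities ----------------------------------------
    def relu(self):
        a = self
        mask = a.data > 0

        def bw(g):
            a._accum(g * mask)

        return self._make(a.data * mask, (a,), bw)

    def sigmoid(self):
        a = self
        s = 0.5 * (np.tanh(0.5 * a.data) + 1.0)  # numerically stable

        def bw(g):
            a._accum(g * s * (1.0 - s))

        return self._make(s, (a,), bw)

    def softplus(self):
        a = self
        out = np.logaddexp(0.0, a.data)
        s = 0.5 * (np.tanh(0.5 * a.data) + 1.0)

        def bw(g):
            a._accum(g * s)

        return self._make(out, (a,), bw)

    def cos(self):
        a = self

        def bw(g):
            a._accum(-g * np.sin(a.data))

        return self._make(np.cos(a.data), (a,), bw)

    def exp(self):
        a = self
        out = np.exp(a.data)

        def bw(g):
            a._accum(g * out)

        return self._make(out, (a,), bw)

    def log(self):
        a = self

        def bw(g):
            a._accum(g / a.data)

        return self._make(np.log(a.data), (a,), bw)

    # -- reductions & shape ------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self

        def bw(g):
            if axis is None:
                a._accum(np.broadcast_to(g, a.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                a._accum(np.broadcast_to(gg, a.shape).copy())

        return self._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        a = self
        old = a.shape

        def bw(g):
            a._accum(g.reshape(old))

        return self._make(a.data.reshape(*shape), (a,), bw)

    def transpose(self, *axes):
        a = self
        inv = np.argsort(axes)

        def bw(g):
            a._accum(g.transpose(*inv))

        return self._make(a.data.transpose(*axes), (a,), bw)

    def softmax(self):
        """Softmax along the last axis."""
        a = self
        z = a.data - a.data.max(axis=-1, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=-1, keepdims=True)

        def bw(g):
            a._accum(y * (g - (g * y).sum(axis=-1, keepdims=True)))

        return self._make(y, (a,), bw)

    def layer_norm(self, eps: float = 1e-5):
        """Zero-mean unit-variance normalization along the last axis (no affine)."""
        a = self
        mu = a.data.mean(axis=-1, keepdims=True)
        var = a.data.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        y = (a.data - mu) * inv
        d = a.data.shape[-1]

        def bw(g):
            gm = g.mean(axis=-1, keepdims=True)
            gym = (g * y).mean(axis=-1, keepdims=True)
            a._accum(inv * (g - gm - y * gym))

        return self._make(y, (a,), bw)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)
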