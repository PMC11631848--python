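"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery for the inverse-operator networks in this package:
broadcast arithmetic, (batched) matmul, the activations used by the
architectures, slicing/concat/reshape for sequence models, reductions,
and an Adam optimizer with optional global-norm gradient clipping.
Gradients flow through a dynamically built graph freed after each
backward pass.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "Adam", "clip_global_norm"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "_parents", "_bwd", "requires_grad")

    def __init__(self, data, parents=(), bwd=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64) if not isinstance(
            data, np.ndarray) else data
        self.grad = None
        self._parents = parents
        self._bwd = bwd
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in parents)

    # -- graph ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def backward(self):
        # iterative topological sort (graphs from long sequences run deep)
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            t, done = stack.pop()
            if not t.requires_grad:
                continue
            if done:
                topo.append(t)
                continue
            if id(t) in seen:
                continue
            seen.add(id(t))
            stack.append((t, True))
            for p in t._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._bwd is not None and t.grad is not None:
                t._bwd(t.grad)
            if t._parents:  # free non-leaf grads lazily
                t._bwd = None
        # detach graph references so memory is reclaimed
        for t in topo:
            if t._parents:
                t._parents = ()

    def _accum(self, p, g):
        if not p.requires_grad:
            return
        g = _unbroadcast(g, p.data.shape)
        p.grad = g if p.grad is None else p.grad + g

    # -- ops -----------------------------------------------------------
    @staticmethod
    def _wrap(x):
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))

    def __add__(self, other):
        other = Tensor._wrap(other)
        out = Tensor(self.data + other.data, (self, other))
        out._bwd = lambda g: (out._accum(self, g), out._accum(other, g))
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))
        out._bwd = lambda g: out._accum(self, -g)
        return out

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __mul__(self, other):
        other = Tensor._wrap(other)
        out = Tensor(self.data * other.data, (self, other))
        out._bwd = lambda g: (out._accum(self, g * other.data),
                              out._accum(other, g * self.data))
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._wrap(other)
        out = Tensor(self.data / other.data, (self, other))

        def bwd(g):
            out._accum(self, g / other.data)
            out._accum(other, -g * self.data / other.data ** 2)
        out._bwd = bwd
        return out

    def matmul(self, other):
        other = Tensor._wrap(other)
        out = Tensor(np.matmul(self.data, other.data), (self, other))

        def bwd(g):
            a, b = self.data, other.data
            ga = np.matmul(g, np.swapaxes(b, -1, -2))
            gb = np.matmul(np.swapaxes(a, -1, -2), g)
            out._accum(self, _unbroadcast(ga, a.shape))
            out._accum(other, _unbroadcast(gb, b.shape))
        out._bwd = bwd
        return out

    __matmul__ = matmul

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, (self,))
        out._bwd = lambda g: out._accum(self, g * mask)
        return out

    def elu(self, alpha: float = 1.0):
        neg = self.data <= 0
        e = alpha * (np.exp(np.minimum(self.data, 0.0)) - 1.0)
        out = Tensor(np.where(neg, e, self.data), (self,))
        out._bwd = lambda g: out._accum(self, g * np.where(neg, e + alpha, 1.0))
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, (self,))
        out._bwd = lambda g: out._accum(self, g * s * (1 - s))
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = Tensor(t, (self,))
        out._bwd = lambda g: out._accum(self, g * (1 - t * t))
        return out

    def sqrt(self):
        s = np.sqrt(self.data)
        out = Tensor(s, (self,))
        out._bwd = lambda g: out._accum(self, g * 0.5 / np.maximum(s, 1e-300))
        return out

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bwd(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            out._accum(self, np.broadcast_to(g, self.data.shape).copy())
        out._bwd = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), (self,))
        out._bwd = lambda g: out._accum(self, g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(*axes), (self,))
        inv = np.argsort(axes)
        out._bwd = lambda g: out._accum(self, g.transpose(*inv))
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], (self,))

        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            out._accum(self, full)
        out._bwd = bwd
        return out

    def unfold_last(self, window: int):
        """Sliding windows over the last axis: (..., C, T) -> (..., C*window, T-window+1).

        Channel-major layout: row c*window + k holds channel c shifted by k,
        so a dense weight (F, C*window) applied to the result is a full-height
        temporal convolution.
        """
        x = self.data
        T = x.shape[-1]
        v = np.lib.stride_tricks.sliding_window_view(x, window, axis=-1)
        # v: (..., C, T-window+1, window) -> (..., C, window, T-window+1)
        v = np.swapaxes(v, -1, -2)
        new_shape = x.shape[:-2] + (x.shape[-2] * window, T - window + 1)
        out = Tensor(np.ascontiguousarray(v).reshape(new_shape), (self,))

        def bwd(g):
            gv = g.reshape(x.shape[:-2] + (x.shape[-2], window, T - window + 1))
            gx = np.zeros_like(x)
            for k in range(window):
                gx[..., k:k + T - window + 1] += gv[..., k, :]
            out._accum(self, gx)
        out._bwd = bwd
        return out

    def pad_last(self, before: int, after: int):
        """Zero-pad the last axis (for same-padded temporal convolution)."""
        width = [(0, 0)] * (self.data.ndim - 1) + [(before, after)]
        out = Tensor(np.pad(self.data, width), (self,))
        sl = (Ellipsis, slice(before, before + self.data.shape[-1]))
        out._bwd = lambda g: out._accum(self, g[sl])
        return out


def concat(tensors, axis: int) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, o, s in zip(tensors, offsets, sizes):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(o, o + s)
            out._accum(t, g[tuple(sl)])
    out._bwd = bwd
    return out


def clip_global_norm(params, max_norm: float) -> float:
    """Scale all gradients so their joint L2 norm is at most ``max_norm``."""
    total = np.sqrt(sum(float(np.sum(p.grad ** 2)) for p in params
                        if p.grad is not None))
    if total > max_norm and total > 0:
        scale = max_norm / total
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return total


class Adam:
    """Adam with the usual defaults (lr 1e-3, betas 0.9/0.999, eps 1e-8)."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
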