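"""A small reverse-mode automatic-differentiation engine on numpy arrays.

Supports exactly the operations the pointwise sequence regressor needs:
broadcasting arithmetic, batched matmul, reshape/transpose, concatenation,
1D convolution building blocks (pad + slice), ReLU/GELU/sigmoid, softmax,
layer normalization and reductions.  Gradients flow through a topologically
sorted tape; everything is float64 for reproducibility.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- graph bookkeeping ------------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
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
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))
        return Tensor._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))
        return Tensor._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def matmul(self, other: "Tensor") -> "Tensor":
        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.data.shape))
        return Tensor._make(self.data @ other.data, (self, other), bw)

    __matmul__ = matmul

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape):
        src = self.data.shape
        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(src))
        return Tensor._make(self.data.reshape(*shape), (self,), bw)

    def transpose(self, *axes):
        inv = np.argsort(axes)
        def bw(g):
            if self.requires_grad:
                self._accum(g.transpose(*inv))
        return Tensor._make(self.data.transpose(*axes), (self,), bw)

    def pad_axis1(self, before: int, after: int):
        """Zero-pad along axis 1 of a (B, L, C) tensor."""
        def bw(g):
            if self.requires_grad:
                L = self.data.shape[1]
                self._accum(g[:, before:before + L, :])
        padded = np.pad(self.data, ((0, 0), (before, after), (0, 0)))
        return Tensor._make(padded, (self,), bw)

    def slice_axis1(self, start: int, stop: int):
        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[:, start:stop, :] = g
                self._accum(full)
        return Tensor._make(self.data[:, start:stop, :], (self,), bw)

    # -- nonlinearities ---------------------------------------------------
    def relu(self):
        mask = self.data > 0
        def bw(g):
            if self.requires_grad:
                self._accum(g * mask)
        return Tensor._make(self.data * mask, (self,), bw)

    def gelu(self):
        # tanh approximation of the Gaussian error linear unit
        x = self.data
        c = np.sqrt(2.0 / np.pi)
        inner = c * (x + 0.044715 * x ** 3)
        t = np.tanh(inner)
        out = 0.5 * x * (1.0 + t)
        def bw(g):
            if self.requires_grad:
                d_inner = c * (1.0 + 3 * 0.044715 * x ** 2)
                grad = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t ** 2) * d_inner
                self._accum(g * grad)
        return Tensor._make(out, (self,), bw)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        def bw(g):
            if self.requires_grad:
                self._accum(g * s * (1.0 - s))
        return Tensor._make(s, (self,), bw)

    def softmax_lastaxis(self):
        z = self.data - self.data.max(axis=-1, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=-1, keepdims=True)
        def bw(g):
            if self.requires_grad:
                dot = np.sum(g * s, axis=-1, keepdims=True)
                self._accum(s * (g - dot))
        return Tensor._make(s, (self,), bw)

    def layernorm_lastaxis(self, eps: float = 1e-5):
        x = self.data
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc ** 2).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        y = xc * inv
        n = x.shape[-1]
        def bw(g):
            if self.requires_grad:
                gm = g.mean(axis=-1, keepdims=True)
                gy = (g * y).mean(axis=-1, keepdims=True)
                self._accum(inv * (g - gm - y * gy))
        return Tensor._make(y, (self,), bw)

    # -- reductions -------------------------------------------------------
    def mean(self):
        n = self.data.size
        def bw(g):
            if self.requires_grad:
                self._accum(np.full_like(self.data, g / n))
        return Tensor._make(np.array(self.data.mean()), (self,), bw)

    def abs(self):
        sign = np.sign(self.data)
        def bw(g):
            if self.requires_grad:
                self._accum(g * sign)
        return Tensor._make(np.abs(self.data), (self,), bw)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(a, b)
                t._accum(g[tuple(idx)])
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    return Tensor._make(out_data, tuple(tensors), bw)
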