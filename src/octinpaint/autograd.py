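"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The engine provides exactly the operations the dual-GAN needs: elementwise
arithmetic, activations, reductions, 2-D (transposed) convolution via
``numpy.lib.stride_tricks.sliding_window_view``, channel concatenation for
skip connections, and an FFT-domain L1 distance with an analytic adjoint.

A :class:`Tensor` wraps an ``ndarray`` and records its parents together with
a closure that accumulates gradients into them; ``Tensor.backward`` walks the
graph in reverse topological order.  Gradients are plain ``ndarray``s stored
on ``.grad``.  Dtype follows the data (float32 for training speed, float64
for finite-difference checks).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "conv2d",
    "conv_transpose2d",
    "spectral_l1",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An ndarray node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph bookkeeping -------------------------------------------------
    @classmethod
    def _make(cls, data, parents, backward):
        out = cls(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
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
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(np.asarray(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free interior grads/graph to bound memory over long chains
                if node is not self:
                    node.grad = None
                node._backward = None
                node._parents = ()

    # -- elementwise arithmetic -------------------------------------------
    def __add__(self, other):
        other = as_tensor(other, self.dtype)

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accumulate(-g)

        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-as_tensor(other, self.dtype))

    def __rsub__(self, other):
        return as_tensor(other, self.dtype) + (-self)

    def __mul__(self, other):
        other = as_tensor(other, self.dtype)

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other, self.dtype)

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.shape)
                )

        return Tensor._make(self.data / other.data, (self, other), bw)

    def __rtruediv__(self, other):
        return as_tensor(other, self.dtype) / self

    def __pow__(self, exponent: float):
        def bw(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1))

        return Tensor._make(self.data**exponent, (self,), bw)

    # -- elementwise nonlinearities ---------------------------------------
    def abs(self):
        def bw(g):
            self._accumulate(g * np.sign(self.data))

        return Tensor._make(np.abs(self.data), (self,), bw)

    def log(self):
        def bw(g):
            self._accumulate(g / self.data)

        return Tensor._make(np.log(self.data), (self,), bw)

    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            self._accumulate(g * out_data)

        return Tensor._make(out_data, (self,), bw)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bw(g):
            self._accumulate(g * 0.5 / out_data)

        return Tensor._make(out_data, (self,), bw)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bw(g):
            self._accumulate(g * (1.0 - out_data**2))

        return Tensor._make(out_data, (self,), bw)

    def sigmoid(self):
        out_data = 0.5 * (1.0 + np.tanh(0.5 * self.data))

        def bw(g):
            self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), bw)

    def relu(self):
        mask = self.data > 0

        def bw(g):
            self._accumulate(g * mask)

        return Tensor._make(self.data * mask, (self,), bw)

    def leaky_relu(self, slope: float = 0.2):
        pos = self.data > 0
        scale = np.where(pos, 1.0, slope)

        def bw(g):
            self._accumulate(g * scale)

        return Tensor._make(self.data * scale, (self,), bw)

    def clamp(self, lo: float, hi: float):
        """Clip values; gradient is passed through inside [lo, hi] only."""
        inside = (self.data >= lo) & (self.data <= hi)

        def bw(g):
            self._accumulate(g * inside)

        return Tensor._make(np.clip(self.data, lo, hi), (self,), bw)

    # -- reductions / shaping ---------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def bw(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accumulate(np.broadcast_to(gg, self.shape).copy())

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.shape[a] for a in axes]))
        # true division keeps mean-of-ones exactly 1
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        def bw(g):
            self._accumulate(g.reshape(self.shape))

        return Tensor._make(self.data.reshape(*shape), (self,), bw)

    def __float__(self) -> float:
        return float(self.data)

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.shape}, dtype={self.dtype}, grad={self.requires_grad})"


def as_tensor(x, dtype=None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    arr = np.asarray(x)
    if dtype is not None and arr.dtype != dtype and arr.dtype.kind == "f":
        arr = arr.astype(dtype)
    elif dtype is not None and arr.dtype.kind in "iub":
        arr = arr.astype(dtype)
    return Tensor(arr)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(a, b)
                t._accumulate(g[tuple(idx)])

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bw
    )


# ---------------------------------------------------------------------------
# 2-D convolution.  Layout: x (N, C, H, W); weight (O, C, kh, kw) for conv2d
# and (C, O, kh, kw) for conv_transpose2d (input channels first, as usual).
# ---------------------------------------------------------------------------


def _pad_hw(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))


def _windows(xp: np.ndarray, k: int, s: int) -> np.ndarray:
    """(N, C, Ho, Wo, k, k) strided view of padded input."""
    v = sliding_window_view(xp, (k, k), axis=(2, 3))
    return v[:, :, ::s, ::s]


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int, padding: int) -> Tensor:
    k = w.shape[2]
    s, p = stride, padding
    xp = _pad_hw(x.data, p)
    win = _windows(xp, k, s)
    out = np.einsum("nchwij,ocij->nohw", win, w.data, optimize=True)
    if b is not None:
        out = out + b.data[None, :, None, None]
    n_out, ho, wo = out.shape[0], out.shape[2], out.shape[3]

    def bw(g):
        if w.requires_grad:
            w._accumulate(np.einsum("nchwij,nohw->ocij", win, g, optimize=True))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for di in range(k):
                for dj in range(k):
                    tmp = np.einsum("nohw,oc->nchw", g, w.data[:, :, di, dj], optimize=True)
                    gxp[:, :, di : di + s * ho : s, dj : dj + s * wo : s] += tmp
            if p:
                gxp = gxp[:, :, p:-p, p:-p]
            x._accumulate(gxp)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out, parents, bw)


def conv_transpose2d(
    x: Tensor, w: Tensor, b: Tensor | None, stride: int, padding: int
) -> Tensor:
    n, c, h, wdt = x.shape
    k = w.shape[2]
    o = w.shape[1]
    s, p = stride, padding
    ho = (h - 1) * s + k - 2 * p
    wo = (wdt - 1) * s + k - 2 * p
    full = np.zeros((n, o, ho + 2 * p, wo + 2 * p), dtype=x.dtype)
    for di in range(k):
        for dj in range(k):
            tmp = np.einsum("nchw,co->nohw", x.data, w.data[:, :, di, dj], optimize=True)
            full[:, :, di : di + s * h : s, dj : dj + s * wdt : s] += tmp
    out = full[:, :, p : p + ho, p : p + wo]
    if b is not None:
        out = out + b.data[None, :, None, None]

    def bw(g):
        gp = _pad_hw(g, p)
        win = _windows(gp, k, s)  # (N, O, H, W, k, k)
        if x.requires_grad:
            x._accumulate(np.einsum("nohwij,coij->nchw", win, w.data, optimize=True))
        if w.requires_grad:
            w._accumulate(np.einsum("nohwij,nchw->coij", win, x.data, optimize=True))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out, parents, bw)


# ---------------------------------------------------------------------------
# FFT-domain L1 distance with analytic adjoint.
# ---------------------------------------------------------------------------


def spectral_l1(x: Tensor, y: Tensor) -> Tensor:
    """Mean over frequency bins (and batch) of |FFT2(x) - FFT2(y)|.

    The 2-D transform is the unnormalized forward DFT over the last two axes.
    For real input the adjoint of the DFT is ``H*W * ifft2``, so the gradient
    of the complex modulus propagates as the real part of the inverse
    transform of ``D / |D|``.
    """
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    diff = np.fft.fft2(x.data) - np.fft.fft2(y.data)
    mod = np.abs(diff)
    out = mod.mean()
    hw = x.shape[-1] * x.shape[-2]

    def bw(g):
        with np.errstate(invalid="ignore", divide="ignore"):
            phase = np.where(mod > 0, diff / np.where(mod > 0, mod, 1.0), 0.0)
        gx = np.real(np.fft.ifft2(phase)) * (hw / mod.size) * g
        if x.requires_grad:
            x._accumulate(gx.astype(x.dtype))
        if y.requires_grad:
            y._accumulate((-gx).astype(y.dtype))

    return Tensor._make(np.asarray(out, dtype=x.dtype), (x, y), bw)
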