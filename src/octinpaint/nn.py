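"""Neural-network layers, parameter handling and RMSprop on the autodiff engine.

Conventions follow the common deep-learning ones: tensors are (N, C, H, W),
convolution weights are Gaussian-initialized with std 0.02, batch norm keeps
exponential running statistics for inference, and ``Module.train``/``eval``
toggles dropout and the batch-norm statistics source.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

from .autograd import Tensor, conv2d, conv_transpose2d

INIT_STD = 0.02  # weight init: zero-mean Gaussian, standard for this GAN family


class Module:
    """Base class: parameter registry, train/eval mode, state dicts."""

    def __init__(self):
        self._params: OrderedDict[str, Tensor] = OrderedDict()
        self._buffers: OrderedDict[str, np.ndarray] = OrderedDict()
        self._modules: OrderedDict[str, Module] = OrderedDict()
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", OrderedDict())[name] = value
        object.__setattr__(self, name, value)

    def register_parameter(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(value, requires_grad=True)
        self._params[name] = t
        object.__setattr__(self, name, t)
        return t

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_state(self, prefix: str = "") -> OrderedDict[str, np.ndarray]:
        out: OrderedDict[str, np.ndarray] = OrderedDict()
        for k, t in self._params.items():
            out[prefix + k] = t.data
        for k, b in self._buffers.items():
            out[prefix + k] = b
        for mk, m in self._modules.items():
            out.update(m.named_state(prefix + mk + "."))
        return out

    def load_state(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for k, t in self._params.items():
            src = state[prefix + k]
            if src.shape != t.data.shape:
                raise ValueError(f"shape mismatch for {prefix + k}")
            t.data = src.astype(t.data.dtype, copy=True)
        for k in self._buffers:
            arr = state[prefix + k].copy()
            self._buffers[k] = arr
            object.__setattr__(self, k, arr)
        for mk, m in self._modules.items():
            m.load_state(state, prefix + mk + ".")

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(self, c_in, c_out, kernel, stride, padding, rng, dtype=np.float32):
        super().__init__()
        self.stride, self.padding = stride, padding
        w = rng.normal(0.0, INIT_STD, size=(c_out, c_in, kernel, kernel))
        self.register_parameter("weight", w.astype(dtype))
        self.register_parameter("bias", np.zeros(c_out, dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class ConvTranspose2d(Module):
    def __init__(self, c_in, c_out, kernel, stride, padding, rng, dtype=np.float32):
        super().__init__()
        self.stride, self.padding = stride, padding
        w = rng.normal(0.0, INIT_STD, size=(c_in, c_out, kernel, kernel))
        self.register_parameter("weight", w.astype(dtype))
        self.register_parameter("bias", np.zeros(c_out, dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose2d(x, self.weight, self.bias, self.stride, self.padding)


class BatchNorm2d(Module):
    """Per-channel normalization over (N, H, W); running stats for eval."""

    def __init__(self, channels, momentum=0.1, eps=1e-5, dtype=np.float32):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.register_parameter("gamma", np.ones(channels, dtype=dtype))
        self.register_parameter("beta", np.zeros(channels, dtype=dtype))
        self.register_buffer("running_mean", np.zeros(channels, dtype=np.float64))
        self.register_buffer("running_var", np.ones(channels, dtype=np.float64))

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            centered = x - mu
            var = (centered**2.0).mean(axis=(0, 2, 3), keepdims=True)
            rm = self._buffers["running_mean"]
            rv = self._buffers["running_var"]
            rm += self.momentum * (mu.data.reshape(-1) - rm)
            rv += self.momentum * (var.data.reshape(-1) - rv)
            xhat = centered * ((var + self.eps) ** -0.5)
        else:
            rm = self._buffers["running_mean"].astype(x.dtype)[None, :, None, None]
            rv = self._buffers["running_var"].astype(x.dtype)[None, :, None, None]
            xhat = (x - Tensor(rm)) * Tensor(1.0 / np.sqrt(rv + self.eps))
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return xhat * g + b


class LayerNorm2d(Module):
    """Per-sample normalization over all of (C, H, W), per-channel affine."""

    def __init__(self, channels, eps=1e-5, dtype=np.float32):
        super().__init__()
        self.eps = eps
        self.register_parameter("gamma", np.ones(channels, dtype=dtype))
        self.register_parameter("beta", np.zeros(channels, dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(1, 2, 3), keepdims=True)
        centered = x - mu
        var = (centered**2.0).mean(axis=(1, 2, 3), keepdims=True)
        xhat = centered * ((var + self.eps) ** -0.5)
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return xhat * g + b


class Dropout(Module):
    """Inverted dropout; the mask is drawn from the module's own generator."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * Tensor(mask)


class RMSprop:
    """RMSprop: v <- alpha*v + (1-alpha)*g^2; p <- p - lr*g/(sqrt(v)+eps)."""

    def __init__(self, params: list[Tensor], lr: float, alpha: float = 0.99, eps: float = 1e-8):
        self.params = params
        self.lr, self.alpha, self.eps = lr, alpha, eps
        self.sq = [np.zeros_like(p.data, dtype=np.float64) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self.sq):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float64)
            v *= self.alpha
            v += (1.0 - self.alpha) * g * g
            p.data -= (self.lr * g / (np.sqrt(v) + self.eps)).astype(p.data.dtype)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def state(self) -> list[np.ndarray]:
        return self.sq

    def load(self, sq: list[np.ndarray]) -> None:
        if len(sq) != len(self.sq):
            raise ValueError("optimizer state length mismatch")
        self.sq = [a.copy() for a in sq]
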