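"""Generator / discriminator architectures and the mask-composite operation.

Two U-Net generators translate between the artifact domain and the clean
domain; two PatchGAN discriminators score local patches of their inputs.
The generator encoder is a plain convolution followed by ReLU-Conv-LayerNorm
blocks and a ReLU-Conv bottleneck; the decoder is ReLU-ConvTranspose-
BatchNorm-Dropout blocks with a final ReLU-ConvTranspose-Tanh, with skip
connections concatenating mirrored encoder features.  All sampling layers
are 4x4 convolutions with stride 2 and padding 1, so each encoder stage
halves the spatial size and a 2^d-sided image bottoms out at 1x1 with
depth d.

The discriminator is five 4x4 convolutions with strides (2, 2, 2, 1, 1) and
padding 1 — the standard schedule whose receptive field is 70x70 — ending in
a sigmoid patch-score map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, concat
from .nn import (
    BatchNorm2d,
    Conv2d,
    ConvTranspose2d,
    Dropout,
    LayerNorm2d,
    Module,
)

__all__ = [
    "GeneratorSpec",
    "DiscriminatorSpec",
    "UNetGenerator",
    "PatchDiscriminator",
    "build_generator",
    "build_discriminator",
    "receptive_field",
    "composite",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """U-Net hyperparameters.

    ``depth`` encoder (and decoder) stages; channel width at stage i is
    ``min(base_channels * 2**i, channel_cap)``.  ``depth=None`` selects
    log2(image side) so the bottleneck is 1x1 ("small-image mode" for test
    images below the nominal 256).
    """

    image_size: int = 256
    depth: int | None = None
    base_channels: int = 64
    channel_cap: int = 512
    dropout: float = 0.5

    def resolved_depth(self) -> int:
        d = int(np.log2(self.image_size))
        if 2**d != self.image_size or self.image_size < 32:
            raise ValueError(
                f"image_size must be a power of two >= 32, got {self.image_size}"
            )
        if self.depth is None:
            return d
        if self.depth > d:
            raise ValueError(
                f"depth {self.depth} needs image side >= {2**self.depth}, "
                f"got {self.image_size}"
            )
        return self.depth

    def channels(self) -> list[int]:
        d = self.resolved_depth()
        return [min(self.base_channels * 2**i, self.channel_cap) for i in range(d)]


@dataclass(frozen=True)
class DiscriminatorSpec:
    """PatchGAN hyperparameters: per-layer kernel/stride/padding schedule."""

    base_channels: int = 64
    kernels: tuple[int, ...] = (4, 4, 4, 4, 4)
    strides: tuple[int, ...] = (2, 2, 2, 1, 1)
    paddings: tuple[int, ...] = (1, 1, 1, 1, 1)
    leaky_slope: float = 0.2

    def __post_init__(self):
        if not len(self.kernels) == len(self.strides) == len(self.paddings):
            raise ValueError("kernel/stride/padding schedules differ in length")


class UNetGenerator(Module):
    """Maps a [-1, 1] image grid to a [-1, 1] grid of the same shape."""

    def __init__(self, spec: GeneratorSpec, seed: int, dtype=np.float32):
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.dropout_rng = np.random.default_rng(
            np.random.SeedSequence(seed).spawn(1)[0]
        )
        ch = spec.channels()
        depth = len(ch)
        # encoder: Conv, then (depth-2) x [ReLU-Conv-LayerNorm], then ReLU-Conv
        enc_in = [1] + ch[:-1]
        for i in range(depth):
            conv = Conv2d(enc_in[i], ch[i], 4, 2, 1, rng, dtype)
            setattr(self, f"enc{i}", conv)
            if 0 < i < depth - 1:
                setattr(self, f"enc_norm{i}", LayerNorm2d(ch[i], dtype=dtype))
        # decoder: (depth-1) x [ReLU-ConvT-BatchNorm-Dropout], then ReLU-ConvT-Tanh
        for i in range(depth):
            c_in = ch[depth - 1 - i] if i == 0 else 2 * ch[depth - 1 - i]
            c_out = 1 if i == depth - 1 else ch[depth - 2 - i]
            deconv = ConvTranspose2d(c_in, c_out, 4, 2, 1, rng, dtype)
            setattr(self, f"dec{i}", deconv)
            if i < depth - 1:
                setattr(self, f"dec_norm{i}", BatchNorm2d(c_out, dtype=dtype))
                setattr(self, f"dec_drop{i}", Dropout(spec.dropout, self.dropout_rng))

    def forward(self, x: Tensor) -> Tensor:
        depth = len(self.spec.channels())
        skips: list[Tensor] = []
        h = x
        for i in range(depth):
            if i > 0:
                h = h.relu()
            h = getattr(self, f"enc{i}")(h)
            if 0 < i < depth - 1:
                h = getattr(self, f"enc_norm{i}")(h)
            skips.append(h)
        for i in range(depth):
            if i > 0:
                h = concat([h, skips[depth - 1 - i]], axis=1)
            h = h.relu()
            h = getattr(self, f"dec{i}")(h)
            if i < depth - 1:
                h = getattr(self, f"dec_norm{i}")(h)
                h = getattr(self, f"dec_drop{i}")(h)
        return h.tanh()


class PatchDiscriminator(Module):
    """Sigmoid patch-score map over local receptive fields."""

    def __init__(self, spec: DiscriminatorSpec, seed: int, dtype=np.float32):
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng(seed)
        n = len(spec.kernels)
        c_prev = 1
        for i, (k, s, p) in enumerate(zip(spec.kernels, spec.strides, spec.paddings)):
            c_out = 1 if i == n - 1 else min(spec.base_channels * 2**i, 8 * spec.base_channels)
            setattr(self, f"conv{i}", Conv2d(c_prev, c_out, k, s, p, rng, dtype))
            if 0 < i < n - 1:
                setattr(self, f"norm{i}", BatchNorm2d(c_out, dtype=dtype))
            c_prev = c_out

    def forward(self, x: Tensor) -> Tensor:
        n = len(self.spec.kernels)
        h = x
        for i in range(n):
            h = getattr(self, f"conv{i}")(h)
            if 0 < i < n - 1:
                h = getattr(self, f"norm{i}")(h)
            if i < n - 1:
                h = h.leaky_relu(self.spec.leaky_slope)
        return h.sigmoid()


def build_generator(spec: GeneratorSpec, seed: int, dtype=np.float32) -> UNetGenerator:
    """Seeded construction; identical (spec, seed) gives identical weights."""
    return UNetGenerator(spec, seed, dtype)


def build_discriminator(
    spec: DiscriminatorSpec, seed: int, dtype=np.float32
) -> PatchDiscriminator:
    return PatchDiscriminator(spec, seed, dtype)


def receptive_field(spec: DiscriminatorSpec) -> int:
    """Side length of the input region seen by one output unit.

    Standard recursion: r_k = r_{k-1} + (kernel_k - 1) * prod(strides before k).
    """
    r, jump = 1, 1
    for k, s in zip(spec.kernels, spec.strides):
        r += (k - 1) * jump
        jump *= s
    return r


def patch_map_size(spec: DiscriminatorSpec, side: int) -> int:
    """Spatial side of the score map: per-layer floor((n + 2p - k)/s) + 1."""
    n = side
    for k, s, p in zip(spec.kernels, spec.strides, spec.paddings):
        n = (n + 2 * p - k) // s + 1
    return n


def composite(s: np.ndarray, m: np.ndarray, s_hat: np.ndarray) -> np.ndarray:
    """Replace the masked region of ``s`` by ``s_hat``: s*(1-m) + s_hat*m.

    Pixels where m == 0 are returned bit-exactly from ``s``.
    """
    s = np.asarray(s)
    m = np.asarray(m)
    s_hat = np.asarray(s_hat)
    if not (s.shape == m.shape == s_hat.shape):
        raise ValueError(
            f"shape mismatch: s {s.shape}, m {m.shape}, s_hat {s_hat.shape}"
        )
    return np.where(m.astype(bool), s_hat, s)


def composite_tensor(s: Tensor, m: np.ndarray, s_hat: Tensor) -> Tensor:
    """Differentiable composite for training; the mask is a constant."""
    mt = Tensor(m.astype(s.dtype))
    return s * (1.0 - mt) + s_hat * mt
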