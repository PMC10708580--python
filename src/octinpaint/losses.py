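"""The five training objectives and their weighted total.

The generator pair is trained with a structural-similarity term, an
FFT-domain L1 term, a pixel L1 term, the adversarial log-likelihood, and a
cycle-reconstruction L1 term:

    L_total = lambda_ssim * L_SSIM + lambda_f * L_F + lambda_1 * L_1
              + lambda_adv * L_adv + lambda_recon * L_recon

with default weights (50, 1, 100, 1, 1).  Every term is reduced by means
(over pixels, frequency bins, patch scores and batch), so the weights stay
scale-comparable across image sizes.  Setting a weight to zero removes that
term (the ablation configurations) with no other code change.

All functions accept NumPy arrays or autodiff Tensors with shapes (H, W),
(N, H, W) or (N, 1, H, W) and return a scalar Tensor (``float()`` it for a
plain number).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, as_tensor, conv2d, spectral_l1

__all__ = [
    "SSIMParams",
    "LossWeights",
    "LossReport",
    "ssim",
    "ssim_loss",
    "fft2",
    "frequency_loss",
    "l1_loss",
    "adversarial_loss",
    "reconstruction_loss",
    "total_loss",
]


@dataclass(frozen=True)
class SSIMParams:
    """Stabilizers and window of the structural-similarity index.

    ``dynamic_range`` is the intensity span L; C1 = (0.01 L)^2 and
    C2 = (0.03 L)^2.  ``window='gaussian'`` uses the conventional 11x11
    Gaussian weighting (sigma 1.5) with valid-mode convolution;
    ``window='global'`` uses whole-image statistics (a single window).
    """

    dynamic_range: float = 1.0
    window: str = "gaussian"
    window_size: int = 11
    sigma: float = 1.5

    def __post_init__(self):
        if self.window not in ("gaussian", "global"):
            raise ValueError(f"unknown window mode {self.window!r}")
        if self.window_size % 2 == 0 or self.window_size < 3:
            raise ValueError("window_size must be odd and >= 3")
        if self.dynamic_range <= 0:
            raise ValueError("dynamic_range must be positive")

    @property
    def c1(self) -> float:
        return (0.01 * self.dynamic_range) ** 2

    @property
    def c2(self) -> float:
        return (0.03 * self.dynamic_range) ** 2


@dataclass(frozen=True)
class LossWeights:
    lambda_ssim: float = 50.0
    lambda_f: float = 1.0
    lambda_l1: float = 100.0
    lambda_adv: float = 1.0
    lambda_recon: float = 1.0

    def __post_init__(self):
        for name, v in self.__dict__.items():
            if v < 0:
                raise ValueError(f"{name} must be nonnegative, got {v}")


@dataclass(frozen=True)
class LossReport:
    l_ssim: float
    l_f: float
    l_1: float
    l_adv: float
    l_recon: float
    total: float

    def as_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


def _nchw(x) -> Tensor:
    t = as_tensor(x, np.float64)
    if t.data.ndim == 2:
        t = t.reshape(1, 1, *t.shape)
    elif t.data.ndim == 3:
        t = t.reshape(t.shape[0], 1, t.shape[1], t.shape[2])
    elif t.data.ndim != 4:
        raise ValueError(f"expected 2-4 dims, got shape {t.shape}")
    return t


def _check_same_shape(x: Tensor, y: Tensor) -> None:
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")


def gaussian_window(size: int, sigma: float, dtype=np.float64) -> np.ndarray:
    ax = np.arange(size, dtype=np.float64) - (size - 1) / 2.0
    g = np.exp(-(ax**2) / (2.0 * sigma**2))
    w2 = np.outer(g, g)
    return (w2 / w2.sum()).astype(dtype)[None, None]


def ssim_map(x, y, params: SSIMParams = SSIMParams()) -> Tensor:
    """Per-window SSIM values (local mode) or per-sample values (global)."""
    x, y = _nchw(x), _nchw(y)
    _check_same_shape(x, y)
    c1, c2 = params.c1, params.c2
    if params.window == "global":
        axes = (1, 2, 3)
        mx = x.mean(axis=axes, keepdims=True)
        my = y.mean(axis=axes, keepdims=True)
        vx = ((x - mx) ** 2.0).mean(axis=axes, keepdims=True)
        vy = ((y - my) ** 2.0).mean(axis=axes, keepdims=True)
        cov = ((x - mx) * (y - my)).mean(axis=axes, keepdims=True)
    else:
        h, w = x.shape[2], x.shape[3]
        if h < params.window_size or w < params.window_size:
            raise ValueError(
                f"image {h}x{w} smaller than the {params.window_size}-pixel SSIM "
                "window; use window='global' for tiny regions"
            )
        win = Tensor(gaussian_window(params.window_size, params.sigma, x.dtype))
        mx = conv2d(x, win, None, 1, 0)
        my = conv2d(y, win, None, 1, 0)
        vx = conv2d(x * x, win, None, 1, 0) - mx * mx
        vy = conv2d(y * y, win, None, 1, 0) - my * my
        cov = conv2d(x * y, win, None, 1, 0) - mx * my
    num = (2.0 * mx * my + c1) * (2.0 * cov + c2)
    den = (mx * mx + my * my + c1) * (vx + vy + c2)
    return num / den


def ssim(x, y, params: SSIMParams = SSIMParams()) -> Tensor:
    """Mean structural similarity; 1 exactly iff the images are identical."""
    return ssim_map(x, y, params).mean()


def ssim_loss(w, ga_s, s, gb_w, params: SSIMParams = SSIMParams()) -> Tensor:
    """(1 - SSIM) in both translation directions, batch-averaged."""
    a = ssim_map(w, ga_s, params).mean(axis=(1, 2, 3)).mean()
    b = ssim_map(s, gb_w, params).mean(axis=(1, 2, 3)).mean()
    return (1.0 - a) + (1.0 - b)


def fft2(x: np.ndarray) -> np.ndarray:
    """Unnormalized 2-D discrete Fourier transform over the last two axes."""
    return np.fft.fft2(np.asarray(x, dtype=np.float64))


def frequency_loss(w, ga_s, s, gb_w) -> Tensor:
    """Mean complex-modulus L1 distance between spectra, both directions."""
    w, ga_s, s, gb_w = _nchw(w), _nchw(ga_s), _nchw(s), _nchw(gb_w)
    _check_same_shape(w, ga_s)
    _check_same_shape(s, gb_w)
    return spectral_l1(ga_s, w) + spectral_l1(gb_w, s)


def l1_loss(w, ga_s, s, gb_w) -> Tensor:
    """Mean absolute pixel difference, both directions."""
    w, ga_s, s, gb_w = _nchw(w), _nchw(ga_s), _nchw(s), _nchw(gb_w)
    _check_same_shape(w, ga_s)
    _check_same_shape(s, gb_w)
    return (ga_s - w).abs().mean() + (gb_w - s).abs().mean()


def _check_scores(name: str, t: Tensor) -> None:
    if t.data.size == 0:
        raise ValueError(f"{name}: empty score map")
    if (t.data <= 0).any() or (t.data >= 1).any():
        raise ValueError(
            f"{name}: discriminator scores must lie strictly in (0, 1) "
            "(is the final sigmoid missing?)"
        )


def adversarial_loss(da_real, da_fake, db_real, db_fake) -> Tensor:
    """GAN value function over patch-score maps (mean-reduced logs).

    E[log D_A(w)] + E[log(1 - D_A(G_A(s)))] + E[log D_B(s)]
    + E[log(1 - D_B(G_B(w)))].  Discriminators ascend this; generators use
    the non-saturating surrogate during training.
    """
    terms = {
        "da_real": as_tensor(da_real, np.float64),
        "da_fake": as_tensor(da_fake, np.float64),
        "db_real": as_tensor(db_real, np.float64),
        "db_fake": as_tensor(db_fake, np.float64),
    }
    for name, t in terms.items():
        _check_scores(name, t)
    return (
        terms["da_real"].log().mean()
        + (1.0 - terms["da_fake"]).log().mean()
        + terms["db_real"].log().mean()
        + (1.0 - terms["db_fake"]).log().mean()
    )


def reconstruction_loss(s, gb_ga_s, w, ga_gb_w) -> Tensor:
    """Cycle-consistency L1: ||G_B(G_A(s)) - s|| and ||G_A(G_B(w)) - w||."""
    s, gb_ga_s = _nchw(s), _nchw(gb_ga_s)
    w, ga_gb_w = _nchw(w), _nchw(ga_gb_w)
    _check_same_shape(s, gb_ga_s)
    _check_same_shape(w, ga_gb_w)
    return (gb_ga_s - s).abs().mean() + (ga_gb_w - w).abs().mean()


def total_loss(
    l_ssim, l_f, l_1, l_adv, l_recon, weights: LossWeights = LossWeights()
) -> LossReport:
    """Weighted sum of the five terms, with every term kept for logging."""
    vals = {
        "l_ssim": float(l_ssim),
        "l_f": float(l_f),
        "l_1": float(l_1),
        "l_adv": float(l_adv),
        "l_recon": float(l_recon),
    }
    for name, v in vals.items():
        if not np.isfinite(v):
            raise ValueError(f"non-finite loss term {name}: {v}")
    total = (
        weights.lambda_ssim * vals["l_ssim"]
        + weights.lambda_f * vals["l_f"]
        + weights.lambda_l1 * vals["l_1"]
        + weights.lambda_adv * vals["l_adv"]
        + weights.lambda_recon * vals["l_recon"]
    )
    return LossReport(total=total, **vals)
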