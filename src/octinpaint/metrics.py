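"""Inpainting quality and segmentation overlap metrics.

PSNR and SSIM are reported "for the repaired region": PSNR over exactly the
masked pixels, SSIM over the bounding box of the mask (SSIM needs a 2-D
neighborhood); full-image mode is also available.  Segmentation quality is
scored with the Dice similarity coefficient, pixel accuracy, F1 and Jaccard
computed from exact pixel counts; DSC and F1 are algebraically identical and
DSC = 2J / (1 + J).

A deliberately simple threshold-based corneal segmenter
(:func:`segment_cornea`) recovers the outer corneal surfaces (EP and EN) and
the filled corneal region from intensities alone, standing in for a trained
segmentation network when scoring how much inpainting helps downstream
boundary recovery.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation

from .losses import SSIMParams, ssim

__all__ = [
    "RegionSpec",
    "ConfusionCounts",
    "psnr",
    "ssim_metric",
    "confusion",
    "dsc",
    "pixel_accuracy",
    "f1",
    "jaccard",
    "segment_cornea",
    "boundary_overlap",
    "evaluate",
    "MetricsReport",
    "PSNR_CAP",
]

PSNR_CAP = 100.0  # sentinel for MSE == 0


@dataclass(frozen=True)
class RegionSpec:
    """Where a fidelity metric is evaluated.

    mode: 'masked' (exact masked pixels), 'bbox' (bounding box of the mask)
    or 'full'.  The mask uses the 1 = repaired convention.
    """

    mode: str = "masked"
    mask: np.ndarray | None = None

    def __post_init__(self):
        if self.mode not in ("masked", "bbox", "full"):
            raise ValueError(f"unknown region mode {self.mode!r}")
        if self.mode != "full":
            if self.mask is None or not np.asarray(self.mask).any():
                raise ValueError(f"region mode {self.mode!r} needs a nonempty mask")

    def bbox(self) -> tuple[slice, slice]:
        rows = np.flatnonzero(self.mask.any(axis=1))
        cols = np.flatnonzero(self.mask.any(axis=0))
        return (
            slice(rows[0], rows[-1] + 1),
            slice(cols[0], cols[-1] + 1),
        )


def psnr(
    x: np.ndarray, y: np.ndarray, region: RegionSpec = RegionSpec(mode="full"),
    dynamic_range: float = 1.0,
) -> float:
    """10 log10(L^2 / MSE) over the region; capped at 100 dB when MSE = 0."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if region.mode == "masked":
        sel = np.asarray(region.mask).astype(bool)
        diff = x[sel] - y[sel]
    elif region.mode == "bbox":
        r, c = region.bbox()
        diff = x[r, c] - y[r, c]
    else:
        diff = x - y
    mse = float(np.mean(diff**2))
    if mse == 0.0:
        return PSNR_CAP
    return min(10.0 * np.log10(dynamic_range**2 / mse), PSNR_CAP)


def ssim_metric(
    x: np.ndarray,
    y: np.ndarray,
    region: RegionSpec = RegionSpec(mode="full"),
    params: SSIMParams = SSIMParams(),
) -> float:
    """SSIM over the region crop, sharing the loss-term implementation.

    'masked' mode falls back to the mask bounding box, since SSIM is
    windowed and needs rectangular support.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if region.mode in ("masked", "bbox"):
        r, c = region.bbox()
        x, y = x[r, c], y[r, c]
    if params.window == "gaussian" and min(x.shape) < params.window_size:
        raise ValueError(
            f"region {x.shape} smaller than the {params.window_size}-pixel SSIM "
            "window; pass SSIMParams(window='global') for narrow stripes"
        )
    return float(ssim(x, y, params))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _check_binary(a: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(a)
    if not np.isin(a, (0, 1)).all():
        raise ValueError(f"{name} must be binary {{0, 1}}")
    return a.astype(bool)


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Exact TP/TN/FP/FN pixel counts of a binary prediction."""
    pred = _check_binary(pred, "pred")
    truth = _check_binary(truth, "truth")
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    return ConfusionCounts(
        tp=int((pred & truth).sum()),
        tn=int((~pred & ~truth).sum()),
        fp=int((pred & ~truth).sum()),
        fn=int((~pred & truth).sum()),
    )


def dsc(pred: np.ndarray, truth: np.ndarray) -> float:
    """Dice similarity 2|X∩Y| / (|X|+|Y|); 1 when both masks are empty."""
    pred = _check_binary(pred, "pred")
    truth = _check_binary(truth, "truth")
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    denom = int(pred.sum()) + int(truth.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((pred & truth).sum()) / denom


def pixel_accuracy(c: ConfusionCounts) -> float:
    if c.total == 0:
        raise ValueError("empty confusion counts")
    return (c.tp + c.tn) / c.total


def f1(c: ConfusionCounts) -> float:
    denom = 2 * c.tp + c.fn + c.fp
    if denom == 0:
        return 1.0
    return 2.0 * c.tp / denom


def jaccard(pred: np.ndarray, truth: np.ndarray) -> float:
    pred = _check_binary(pred, "pred")
    truth = _check_binary(truth, "truth")
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    union = int((pred | truth).sum())
    if union == 0:
        return 1.0
    return int((pred & truth).sum()) / union


# ---------------------------------------------------------------------------
# Threshold-based corneal boundary recovery.
# ---------------------------------------------------------------------------


def segment_cornea(image: np.ndarray, threshold: float = 0.2) -> dict[str, np.ndarray]:
    """Recover outer corneal surfaces per column by intensity thresholding.

    Returns 'EP' and 'EN' one-pixel boundary-curve masks (first and last
    bright pixel per column) and 'region', the filled band between them.
    Saturated stripes pull EP to the top row and EN to the bottom, which is
    exactly why inpainting improves the recovered segmentation.
    """
    img = np.asarray(image, dtype=np.float64)
    bright = img >= threshold
    h, w = img.shape
    ep = np.zeros((h, w), dtype=np.uint8)
    en = np.zeros((h, w), dtype=np.uint8)
    any_col = bright.any(axis=0)
    first = np.argmax(bright, axis=0)
    last = h - 1 - np.argmax(bright[::-1], axis=0)
    cols = np.nonzero(any_col)[0]
    ep[first[cols], cols] = 1
    en[last[cols], cols] = 1
    rr = np.arange(h)[:, None]
    region = (
        (rr >= first[None, :]) & (rr <= last[None, :]) & any_col[None, :]
    ).astype(np.uint8)
    return {"EP": ep, "EN": en, "region": region}


def boundary_overlap(
    pred_curve: np.ndarray, truth_curve: np.ndarray, tolerance: int = 0
) -> float:
    """DSC of two 1-pixel boundary curves, each dilated by ``tolerance``."""
    pred = _check_binary(pred_curve, "pred")
    truth = _check_binary(truth_curve, "truth")
    if tolerance > 0:
        footprint = np.ones((2 * tolerance + 1, 2 * tolerance + 1), dtype=bool)
        pred = binary_dilation(pred, footprint)
        truth = binary_dilation(truth, footprint)
    return dsc(pred.astype(np.uint8), truth.astype(np.uint8))


# ---------------------------------------------------------------------------
# Dataset-level evaluation.
# ---------------------------------------------------------------------------


@dataclass
class MetricsReport:
    per_image: pd.DataFrame
    means: dict[str, float]
    missing: list[str]
    region_mode: str

    @property
    def partial(self) -> bool:
        return bool(self.missing)


def evaluate(
    manifest_path,
    checkpoint,
    region_mode: str = "masked",
    split: str = "test",
    seg_threshold: float = 0.2,
    out_csv=None,
) -> MetricsReport:
    """Inpaint every ``split`` sample of a dataset and score the repairs.

    ``checkpoint`` may be a checkpoint path, a fitted estimator, or any
    callable ``f(image, mask) -> image`` (e.g. an oracle or the identity,
    for before-inpainting baselines).  PSNR uses the masked pixels, SSIM the
    mask bounding box (global window when the stripe is narrower than the
    local window), and segmentation metrics compare threshold-recovered
    corneal regions of the repaired vs. the clean image.
    """
    from . import cli_io, training

    manifest = cli_io.read_manifest(manifest_path)
    base = Path(manifest_path).parent
    rows = manifest[manifest["split"] == split]
    if rows.empty:
        raise ValueError(f"manifest has no '{split}' rows")
    if callable(checkpoint) and not isinstance(checkpoint, training.DualGANInpainter):
        repair = checkpoint
    else:
        est = checkpoint
        if not isinstance(est, training.DualGANInpainter):
            est = training.load_checkpoint(checkpoint)
        repair = lambda img, m: est.transform(img, masks=m)  # noqa: E731

    records, missing = [], []
    for _, r in rows.iterrows():
        paths = [base / r["path_artifact"], base / r["path_clean"], base / r["path_mask"]]
        if not all(p.exists() for p in paths):
            missing.extend(str(p) for p in paths if not p.exists())
            continue
        s = cli_io.load_image(paths[0])
        w = cli_io.load_image(paths[1])
        m = cli_io.load_mask(paths[2])
        repaired = repair(s, m)
        region = RegionSpec(mode=region_mode, mask=m if region_mode != "full" else None)
        rec = {"path": r["path_artifact"]}
        rec["psnr"] = psnr(repaired, w, region)
        bbox_w = int(m.any(axis=0).sum()) if region_mode != "full" else min(w.shape)
        sp = SSIMParams() if bbox_w >= 11 else SSIMParams(window="global")
        rec["ssim"] = ssim_metric(repaired, w, region, sp)
        seg_p = segment_cornea(repaired, seg_threshold)["region"]
        seg_t = segment_cornea(w, seg_threshold)["region"]
        c = confusion(seg_p, seg_t)
        rec["dsc"] = dsc(seg_p, seg_t)
        rec["pa"] = pixel_accuracy(c)
        rec["f1"] = f1(c)
        rec["jaccard"] = jaccard(seg_p, seg_t)
        records.append(rec)
    per_image = pd.DataFrame(records)
    metric_cols = ["psnr", "ssim", "dsc", "pa", "f1", "jaccard"]
    means = {k: float(per_image[k].mean()) for k in metric_cols} if records else {}
    report = MetricsReport(
        per_image=per_image, means=means, missing=missing, region_mode=region_mode
    )
    if out_csv is not None:
        summary = per_image.copy()
        mean_row = {"path": "MEAN", **means}
        summary = pd.concat([summary, pd.DataFrame([mean_row])], ignore_index=True)
        cli_io.atomic_write_bytes(out_csv, summary.to_csv(index=False).encode())
    return report
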