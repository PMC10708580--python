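"""Synthetic anterior-segment corneal phantoms and stripe-artifact corruption.

Real AS-OCT B-scans of the cornea show a bright, gently curved multilayer
arc over a dark background, degraded by multiplicative speckle, and — when
the beam hits the apex perpendicularly — a vertical saturation stripe.  The
phantom reproduces exactly that statistical structure with known geometry:

* the anterior epithelium surface (EP) is a circular arc;
* below it lie three intensity bands (epithelium, Bowman's layer, stroma
  down to the endothelium), whose lower edges give the BL and EN boundary
  curves;
* the whole geometry can be tilted by rotating the arc's center about the
  image center, emulating scans acquired at different inclinations;
* speckle is multiplicative: image *= 1 + strength * g, g ~ N(0, 1).

Corruption replaces a single vertical stripe of pixels by a constant fill
(default 1.0 — a saturated white stripe), yielding a paired sample
(artifact image, clean image, mask) with the mask convention 1 = repair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "PhantomParams",
    "PhantomScene",
    "MaskParams",
    "PairedSample",
    "GeometryError",
    "default_params",
    "generate_phantom",
    "sample_mask",
    "corrupt",
    "build_dataset",
]


class GeometryError(ValueError):
    """The corneal arc does not intersect the image frame."""


@dataclass(frozen=True)
class PhantomParams:
    height: int = 256
    width: int = 256
    tilt_deg: float = 0.0
    arc_radius: float = 320.0
    apex_row: float = 48.0
    layer_thicknesses: tuple[float, float, float] = (10.0, 6.0, 44.0)
    layer_intensities: tuple[float, float, float] = (0.9, 0.55, 0.35)
    background_level: float = 0.05
    speckle_strength: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("height and width must be positive")
        vals = (*self.layer_intensities, self.background_level)
        if any(not 0.0 <= v <= 1.0 for v in vals):
            raise ValueError("intensities must lie in [0, 1]")
        if any(t <= 0 for t in self.layer_thicknesses):
            raise ValueError("layer thicknesses must be positive")
        if sum(self.layer_thicknesses) >= self.height:
            raise ValueError("layer thicknesses must sum to less than the height")
        if self.arc_radius <= 0:
            raise ValueError("arc_radius must be positive")
        if self.speckle_strength < 0:
            raise ValueError("speckle_strength must be nonnegative")


@dataclass(frozen=True)
class PhantomScene:
    image: np.ndarray  # float64 in [0, 1], shape (H, W)
    boundary_labels: dict[str, np.ndarray]  # 'EP'/'BL'/'EN' -> binary (H, W)
    boundary_rows: dict[str, np.ndarray]  # per-column row index, -1 off-cornea


def default_params(size: int = 256, **overrides) -> PhantomParams:
    """Defaults scaled from the nominal 256-pixel frame to ``size``."""
    f = size / 256.0
    p = PhantomParams(
        height=size,
        width=size,
        arc_radius=320.0 * f,
        apex_row=48.0 * f,
        layer_thicknesses=(max(10.0 * f, 2.0), max(6.0 * f, 1.0), max(44.0 * f, 4.0)),
    )
    return replace(p, **overrides)


def _boundary_row_curves(params: PhantomParams) -> dict[str, np.ndarray]:
    """Continuous row coordinate of each boundary per column; NaN off-arc.

    The arc is the upper half of a circle whose center sits ``arc_radius``
    below the apex; tilt rotates that center about the image center, so
    opposite tilts give exactly mirrored geometry when the arc is centered.
    """
    h, w = params.height, params.width
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    # untilted circle center
    row0 = params.apex_row + params.arc_radius
    col0 = cx
    th = math.radians(params.tilt_deg)
    dr, dc = row0 - cy, col0 - cx
    crow = cy + dr * math.cos(th) - dc * math.sin(th)
    ccol = cx + dr * math.sin(th) + dc * math.cos(th)

    cols = np.arange(w, dtype=np.float64)
    under = params.arc_radius**2 - (cols - ccol) ** 2
    ep = np.full(w, np.nan)
    ok = under > 0
    ep[ok] = crow - np.sqrt(under[ok])
    t1, t2, t3 = params.layer_thicknesses
    return {"EP": ep, "BL": ep + t1 + t2, "EN": ep + t1 + t2 + t3}


def generate_phantom(params: PhantomParams) -> PhantomScene:
    """Render a phantom scene; deterministic given (params, seed)."""
    params.validate()
    h, w = params.height, params.width
    curves = _boundary_row_curves(params)
    rows = np.arange(h, dtype=np.float64)[:, None]
    ep, bl, en = curves["EP"], curves["BL"], curves["EN"]
    t1 = params.layer_thicknesses[0]

    # cornea present where all three boundaries land inside the frame
    present = (
        np.isfinite(ep) & (ep >= 0) & (ep < h - 0.5) & (en >= 0) & (en < h - 0.5)
    )
    if not present.any():
        raise GeometryError(
            "corneal arc does not intersect the image frame for these parameters"
        )

    img = np.full((h, w), params.background_level)
    i1, i2, i3 = params.layer_intensities
    band1 = (rows >= ep) & (rows < ep + t1) & present
    band2 = (rows >= ep + t1) & (rows < bl) & present
    band3 = (rows >= bl) & (rows < en) & present
    img[band1] = i1
    img[band2] = i2
    img[band3] = i3

    if params.speckle_strength > 0:
        rng = np.random.default_rng(params.seed)
        g = rng.standard_normal((h, w))
        img = img * (1.0 + params.speckle_strength * g)
    img = np.clip(img, 0.0, 1.0)

    labels: dict[str, np.ndarray] = {}
    row_idx: dict[str, np.ndarray] = {}
    for name in ("EP", "BL", "EN"):
        r = np.where(present, np.rint(curves[name]), -1).astype(int)
        r[(r < 0) | (r >= h)] = -1
        grid = np.zeros((h, w), dtype=np.uint8)
        cols_on = np.nonzero(r >= 0)[0]
        grid[r[cols_on], cols_on] = 1
        labels[name] = grid
        row_idx[name] = r
    return PhantomScene(image=img, boundary_labels=labels, boundary_rows=row_idx)


@dataclass(frozen=True)
class MaskParams:
    width_range: tuple[int, int] = (8, 24)
    center_range: tuple[int, int] | None = None  # None -> widest valid range
    seed: int = 0

    def validate(self, shape: tuple[int, int]) -> tuple[int, int]:
        _, w = shape
        wmin, wmax = self.width_range
        if not 1 <= wmin <= wmax < w:
            raise ValueError(f"width_range {self.width_range} invalid for width {w}")
        if self.center_range is None:
            # worst case: width wmax, start = c - wmax//2 must be >= 0 and
            # start + wmax <= w
            lo, hi = wmax // 2, w - (wmax - wmax // 2)
        else:
            lo, hi = self.center_range
        if not 0 <= lo <= hi < w:
            raise ValueError(f"center_range ({lo}, {hi}) outside image width {w}")
        if lo - wmax // 2 < 0 or hi - wmax // 2 + wmax > w:
            raise ValueError("a stripe of maximal width would leave the image")
        return lo, hi


@dataclass(frozen=True)
class ArtifactMaskInfo:
    grid: np.ndarray  # uint8 {0,1}, shape (H, W)
    col_start: int
    col_stop: int  # half-open [start, stop)


def sample_mask(mask_params: MaskParams, shape: tuple[int, int]) -> ArtifactMaskInfo:
    """Draw one vertical stripe mask, uniform in width and center column."""
    lo, hi = mask_params.validate(shape)
    h, w = shape
    rng = np.random.default_rng(mask_params.seed)
    wmin, wmax = mask_params.width_range
    width = int(rng.integers(wmin, wmax + 1))
    center = int(rng.integers(lo, hi + 1))
    start = center - width // 2
    grid = np.zeros((h, w), dtype=np.uint8)
    grid[:, start : start + width] = 1
    return ArtifactMaskInfo(grid=grid, col_start=start, col_stop=start + width)


@dataclass(frozen=True)
class PairedSample:
    artifact_image: np.ndarray  # s
    clean_image: np.ndarray  # w = I
    mask: np.ndarray  # m, uint8 {0,1}


def corrupt(clean: np.ndarray, mask: np.ndarray, fill: float = 1.0) -> PairedSample:
    """Overwrite the masked stripe with a constant fill intensity."""
    clean = np.asarray(clean)
    grid = mask.grid if isinstance(mask, ArtifactMaskInfo) else np.asarray(mask)
    if clean.shape != grid.shape:
        raise ValueError(f"shape mismatch: image {clean.shape}, mask {grid.shape}")
    if not 0.0 <= fill <= 1.0:
        raise ValueError("fill must lie in [0, 1]")
    artifact = np.where(grid.astype(bool), np.asarray(fill, dtype=clean.dtype), clean)
    return PairedSample(
        artifact_image=artifact, clean_image=clean, mask=grid.astype(np.uint8)
    )


def build_dataset(
    n_train: int,
    n_test: int,
    phantom_params: PhantomParams,
    train_mask_params: MaskParams,
    test_mask_params: MaskParams,
    out_dir,
    fill: float = 1.0,
    tilt_range_deg: tuple[float, float] = (-15.0, 15.0),
    seed: int = 0,
):
    """Write clean/artifact/mask PNG triplets plus a manifest.

    Each sample gets its own tilt (uniform in ``tilt_range_deg``) and its own
    speckle/mask seeds spawned from ``seed``, so the whole dataset is a pure
    function of the arguments.  Test masks come from ``test_mask_params``
    (conventionally wider than the training stripes).
    """
    from . import cli_io  # local import: cli_io imports nothing from here

    import pandas as pd
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(seed)
    rows = []
    specs = [("train", i, train_mask_params) for i in range(n_train)]
    specs += [("test", i, test_mask_params) for i in range(n_test)]
    child_seeds = master.generate_state(2 * len(specs) + 1)
    tilt_rng = np.random.default_rng(int(child_seeds[-1]) % 2**31)
    for j, (split, i, mp) in enumerate(specs):
        sseed = int(child_seeds[2 * j]) % 2**31
        mseed = int(child_seeds[2 * j + 1]) % 2**31
        tilt = float(tilt_rng.uniform(*tilt_range_deg))
        pp = replace(phantom_params, tilt_deg=tilt, seed=sseed)
        scene = generate_phantom(pp)
        mask = sample_mask(replace(mp, seed=mseed), scene.image.shape)
        # quantize clean to its on-disk 8-bit values before corruption so the
        # paired-sample identity survives the PNG round trip
        clean_q = np.round(scene.image * 255.0) / 255.0
        pair = corrupt(clean_q, mask, fill=fill)
        stem = f"{split}_{i:05d}"
        p_clean = out_dir / f"{stem}_clean.png"
        p_art = out_dir / f"{stem}_artifact.png"
        p_mask = out_dir / f"{stem}_mask.png"
        cli_io.save_image(p_clean, pair.clean_image)
        cli_io.save_image(p_art, pair.artifact_image)
        cli_io.save_mask(p_mask, pair.mask)
        rows.append(
            {
                "path_clean": p_clean.name,
                "path_artifact": p_art.name,
                "path_mask": p_mask.name,
                "seed": sseed,
                "mask_seed": mseed,
                "tilt_deg": tilt,
                "mask_width": mask.col_stop - mask.col_start,
                "split": split,
            }
        )
    manifest = pd.DataFrame(rows)
    cli_io.write_manifest(out_dir / "manifest.tsv", manifest)
    return manifest
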