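"""Dual-GAN optimization loop and the user-facing estimator.

:class:`DualGANInpainter` is a scikit-learn style estimator: ``fit`` trains
the two generator / two discriminator networks on paired (artifact, clean,
mask) batches; ``transform`` repairs images by running the artifact-removal
generator and splicing its output into the masked stripe only, so pixels
outside the mask are returned bit-identical to the input whatever the
training state.

Per step the discriminators take one ascent step on the adversarial
log-likelihood, then the generators take one descent step on the weighted
total objective (with the non-saturating adversarial surrogate).  Images
live in [0, 1] on disk and in [-1, 1] inside the networks; compositing and
all reconstruction losses are evaluated in [0, 1] storage space.

Value-of-default choices: RMSprop with generator lr 5e-4, discriminator lr
1e-4, batch size 4.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import cli_io
from .autograd import Tensor
from .losses import (
    LossReport,
    LossWeights,
    SSIMParams,
    adversarial_loss,
    frequency_loss,
    l1_loss,
    reconstruction_loss,
    ssim_loss,
    total_loss,
)
from .networks import (
    DiscriminatorSpec,
    GeneratorSpec,
    build_discriminator,
    build_generator,
    composite,
    composite_tensor,
)
from .nn import RMSprop

__all__ = [
    "DualGANInpainter",
    "TrainConfig",
    "TrainRecord",
    "TrainingDiverged",
    "train",
    "train_step",
    "inpaint",
    "save_checkpoint",
    "load_checkpoint",
]

_SCORE_EPS = 1e-6


class TrainingDiverged(RuntimeError):
    def __init__(self, message: str, last_record: "TrainRecord | None"):
        super().__init__(message)
        self.last_record = last_record


@dataclass(frozen=True)
class TrainRecord:
    step: int
    report: LossReport
    d_a_real: float
    d_a_fake: float
    d_b_real: float
    d_b_fake: float

    def as_dict(self) -> dict[str, float]:
        d = {"step": self.step}
        d.update(self.report.as_dict())
        d.update(
            d_a_real=self.d_a_real,
            d_a_fake=self.d_a_fake,
            d_b_real=self.d_b_real,
            d_b_fake=self.d_b_fake,
        )
        return d


def _to_net(x01):
    return 2.0 * x01 - 1.0


def _to_storage(xn):
    return 0.5 * (xn + 1.0)


class DualGANInpainter(BaseEstimator, TransformerMixin):
    """Adversarial stripe-artifact inpainter for grayscale images.

    Parameters mirror the training setup: U-Net generator geometry
    (``image_size``, ``depth``, ``base_channels``), PatchGAN width
    (``disc_base_channels``), the five loss weights (defaults
    50, 1, 100, 1, 1), RMSprop learning rates and the batch size.

    Fitted attributes (trailing underscore): ``gen_a_`` (artifact -> clean),
    ``gen_b_`` (clean -> artifact), ``disc_a_``, ``disc_b_``, ``history_``
    (list of :class:`TrainRecord`), ``n_steps_``.
    """

    def __init__(
        self,
        image_size: int = 256,
        depth: int | None = None,
        base_channels: int = 64,
        channel_cap: int = 512,
        disc_base_channels: int = 64,
        dropout: float = 0.5,
        lr_g: float = 5e-4,
        lr_d: float = 1e-4,
        batch_size: int = 4,
        n_steps: int = 200,
        lambda_ssim: float = 50.0,
        lambda_f: float = 1.0,
        lambda_l1: float = 100.0,
        lambda_adv: float = 1.0,
        lambda_recon: float = 1.0,
        ssim_window: str = "gaussian",
        dtype: str = "float32",
        random_state: int = 0,
    ):
        self.image_size = image_size
        self.depth = depth
        self.base_channels = base_channels
        self.channel_cap = channel_cap
        self.disc_base_channels = disc_base_channels
        self.dropout = dropout
        self.lr_g = lr_g
        self.lr_d = lr_d
        self.batch_size = batch_size
        self.n_steps = n_steps
        self.lambda_ssim = lambda_ssim
        self.lambda_f = lambda_f
        self.lambda_l1 = lambda_l1
        self.lambda_adv = lambda_adv
        self.lambda_recon = lambda_recon
        self.ssim_window = ssim_window
        self.dtype = dtype
        self.random_state = random_state

    # -- construction ------------------------------------------------------
    def _weights(self) -> LossWeights:
        return LossWeights(
            lambda_ssim=self.lambda_ssim,
            lambda_f=self.lambda_f,
            lambda_l1=self.lambda_l1,
            lambda_adv=self.lambda_adv,
            lambda_recon=self.lambda_recon,
        )

    def _ssim_params(self) -> SSIMParams:
        # losses are evaluated in [0, 1] storage space, so L = 1
        size = min(11, self.image_size)
        if size % 2 == 0:
            size -= 1
        return SSIMParams(dynamic_range=1.0, window=self.ssim_window, window_size=size)

    def _np_dtype(self):
        return np.dtype(self.dtype)

    def _init_models(self) -> None:
        ss = np.random.SeedSequence(self.random_state)
        seeds = [int(s) % 2**31 for s in ss.generate_state(5)]
        gspec = GeneratorSpec(
            image_size=self.image_size,
            depth=self.depth,
            base_channels=self.base_channels,
            channel_cap=self.channel_cap,
            dropout=self.dropout,
        )
        dspec = DiscriminatorSpec(base_channels=self.disc_base_channels)
        dt = self._np_dtype()
        self.gen_a_ = build_generator(gspec, seeds[0], dt)
        self.gen_b_ = build_generator(gspec, seeds[1], dt)
        self.disc_a_ = build_discriminator(dspec, seeds[2], dt)
        self.disc_b_ = build_discriminator(dspec, seeds[3], dt)
        self.shuffle_rng_ = np.random.default_rng(seeds[4])
        self.opt_g_ = RMSprop(
            self.gen_a_.parameters() + self.gen_b_.parameters(), lr=self.lr_g
        )
        self.opt_d_ = RMSprop(
            self.disc_a_.parameters() + self.disc_b_.parameters(), lr=self.lr_d
        )
        self.history_: list[TrainRecord] = []
        self.n_steps_ = 0

    # -- one optimization step --------------------------------------------
    def _apply_gen_a(self, s01: Tensor, m: np.ndarray) -> Tensor:
        """G_A with its output spliced into the masked region of its input."""
        raw = self.gen_a_(_to_net(s01))
        return composite_tensor(s01, m, _to_storage(raw))

    def _apply_gen_b(self, w01: Tensor) -> Tensor:
        return _to_storage(self.gen_b_(_to_net(w01)))

    def partial_fit_batch(
        self, s01: np.ndarray, w01: np.ndarray, m: np.ndarray
    ) -> TrainRecord:
        """One discriminator ascent step, then one generator descent step."""
        dt = self._np_dtype()
        s_t = Tensor(s01.astype(dt)[:, None])
        w_t = Tensor(w01.astype(dt)[:, None])
        m4 = m.astype(dt)[:, None]
        weights = self._weights()
        sp = self._ssim_params()

        # generator forwards (train mode: dropout + batch statistics)
        ga_s = self._apply_gen_a(s_t, m4)
        gb_w = self._apply_gen_b(w_t)

        # --- discriminator update (fakes detached) ---
        da_real = self.disc_a_(_to_net(w_t))
        da_fake = self.disc_a_(_to_net(ga_s.detach()))
        db_real = self.disc_b_(_to_net(s_t))
        db_fake = self.disc_b_(_to_net(gb_w.detach()))
        eps = _SCORE_EPS
        d_value = (
            da_real.clamp(eps, 1 - eps).log().mean()
            + (1.0 - da_fake.clamp(eps, 1 - eps)).log().mean()
            + db_real.clamp(eps, 1 - eps).log().mean()
            + (1.0 - db_fake.clamp(eps, 1 - eps)).log().mean()
        )
        self.opt_d_.zero_grad()
        (-d_value).backward()
        self.opt_d_.step()

        # Eq-8 value reported from the pre-update scores
        def _c(t):
            return np.clip(t.data, eps, 1 - eps)

        l_adv_value = float(
            adversarial_loss(_c(da_real), _c(da_fake), _c(db_real), _c(db_fake))
        )

        # --- generator update ---
        zero = Tensor(np.asarray(0.0, dtype=dt))
        l_ssim = ssim_loss(w_t, ga_s, s_t, gb_w, sp) if weights.lambda_ssim else zero
        l_f = frequency_loss(w_t, ga_s, s_t, gb_w) if weights.lambda_f else zero
        l_1 = l1_loss(w_t, ga_s, s_t, gb_w) if weights.lambda_l1 else zero
        if weights.lambda_recon:
            gb_ga_s = self._apply_gen_b(ga_s)
            ga_gb_w = self._apply_gen_a(gb_w, m4)
            l_recon = reconstruction_loss(s_t, gb_ga_s, w_t, ga_gb_w)
        else:
            l_recon = zero
        if weights.lambda_adv:
            da_fake_g = self.disc_a_(_to_net(ga_s)).clamp(eps, 1 - eps)
            db_fake_g = self.disc_b_(_to_net(gb_w)).clamp(eps, 1 - eps)
            # non-saturating surrogate: maximize log D(fake)
            g_adv = -(da_fake_g.log().mean()) - db_fake_g.log().mean()
        else:
            g_adv = zero
        g_objective = (
            weights.lambda_ssim * l_ssim
            + weights.lambda_f * l_f
            + weights.lambda_l1 * l_1
            + weights.lambda_adv * g_adv
            + weights.lambda_recon * l_recon
        )
        self.opt_g_.zero_grad()
        g_objective.backward()
        self.opt_g_.step()

        try:
            report = total_loss(
                float(l_ssim), float(l_f), float(l_1), l_adv_value, float(l_recon), weights
            )
        except ValueError as exc:
            last = self.history_[-1] if self.history_ else None
            raise TrainingDiverged(str(exc), last) from exc
        record = TrainRecord(
            step=self.n_steps_,
            report=report,
            d_a_real=float(da_real.data.mean()),
            d_a_fake=float(da_fake.data.mean()),
            d_b_real=float(db_real.data.mean()),
            d_b_fake=float(db_fake.data.mean()),
        )
        self.history_.append(record)
        self.n_steps_ += 1
        return record

    # -- sklearn surface ---------------------------------------------------
    def _validate_arrays(self, X, y, masks):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        masks = np.asarray(masks)
        if X.ndim == 2:
            X, y, masks = X[None], y[None], masks[None]
        if not (X.shape == y.shape == masks.shape) or X.ndim != 3:
            raise ValueError(
                f"X, y, masks must share shape (n, h, w); got {X.shape}, "
                f"{y.shape}, {masks.shape}"
            )
        if X.min() < 0 or X.max() > 1 or y.min() < 0 or y.max() > 1:
            raise ValueError("images must lie in [0, 1]")
        if not np.isin(masks, (0, 1)).all():
            raise ValueError("masks must be binary {0, 1}")
        return X, y, masks.astype(np.uint8)

    def fit(self, X, y=None, masks=None):
        """Train on artifact images ``X`` with clean targets ``y``.

        X, y : arrays (n, h, w) in [0, 1]; masks : binary arrays (n, h, w),
        1 marking the stripe to repair.
        """
        if y is None or masks is None:
            raise ValueError("fit requires clean targets y and binary masks")
        X, y, masks = self._validate_arrays(X, y, masks)
        if X.shape[1] != self.image_size or X.shape[2] != self.image_size:
            raise ValueError(
                f"images are {X.shape[1]}x{X.shape[2]} but image_size="
                f"{self.image_size}"
            )
        self._init_models()
        self._run_steps(X, y, masks, self.n_steps)
        return self

    def _run_steps(self, X, y, masks, until: int) -> None:
        n = X.shape[0]
        self.gen_a_.train()
        self.gen_b_.train()
        self.disc_a_.train()
        self.disc_b_.train()
        order: list[int] = []
        while self.n_steps_ < until:
            if len(order) < self.batch_size:
                order = list(self.shuffle_rng_.permutation(n))
            idx = [order.pop() for _ in range(min(self.batch_size, n))]
            self.partial_fit_batch(X[idx], y[idx], masks[idx])

    def transform(self, X, masks=None):
        """Inpaint the masked stripes; identity outside every mask."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "gen_a_")
        if masks is None:
            raise ValueError("transform requires binary masks")
        single = np.asarray(X).ndim == 2
        X, _, masks = self._validate_arrays(X, X, masks)
        d = len(self.gen_a_.spec.channels())
        if X.shape[1] % 2**d or X.shape[2] % 2**d:
            raise ValueError(
                f"image sides must be divisible by 2^{d} for this checkpoint"
            )
        self.gen_a_.eval()
        out = np.empty_like(X)
        for i in range(0, X.shape[0], self.batch_size):
            xb = X[i : i + self.batch_size]
            raw = self.gen_a_(Tensor(_to_net(xb.astype(self._np_dtype()))[:, None]))
            s_hat01 = np.clip(_to_storage(raw.data[:, 0]).astype(np.float64), 0.0, 1.0)
            for j in range(xb.shape[0]):
                out[i + j] = composite(xb[j], masks[i + j], s_hat01[j])
        self.gen_a_.train()
        return out[0] if single else out

    def __sklearn_is_fitted__(self) -> bool:
        return hasattr(self, "gen_a_")


# ---------------------------------------------------------------------------
# Checkpointing: a single .npz holding every parameter/buffer array, the
# optimizer state, the RNG states and the estimator config (JSON strings).
# ---------------------------------------------------------------------------


def save_checkpoint(path, est: DualGANInpainter) -> None:
    arrays: dict[str, np.ndarray] = {}
    for name, model in (
        ("gen_a", est.gen_a_),
        ("gen_b", est.gen_b_),
        ("disc_a", est.disc_a_),
        ("disc_b", est.disc_b_),
    ):
        for k, v in model.named_state(name + ".").items():
            arrays[k] = v
    for tag, opt in (("opt_g", est.opt_g_), ("opt_d", est.opt_d_)):
        for i, v in enumerate(opt.state()):
            arrays[f"{tag}.{i}"] = v
    meta = {
        "config": est.get_params(),
        "n_steps_": est.n_steps_,
        "rng": {
            "shuffle": est.shuffle_rng_.bit_generator.state,
            "dropout_a": est.gen_a_.dropout_rng.bit_generator.state,
            "dropout_b": est.gen_b_.dropout_rng.bit_generator.state,
        },
    }
    arrays["__meta__"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8
    ).copy()
    import io as _io

    buf = _io.BytesIO()
    np.savez(buf, **arrays)
    cli_io.atomic_write_bytes(path, buf.getvalue())


def load_checkpoint(path) -> DualGANInpainter:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such checkpoint: {path}")
    with np.load(path) as z:
        arrays = {k: z[k] for k in z.files}
    meta = json.loads(arrays.pop("__meta__").tobytes().decode())
    est = DualGANInpainter(**meta["config"])
    est._init_models()
    for name, model in (
        ("gen_a", est.gen_a_),
        ("gen_b", est.gen_b_),
        ("disc_a", est.disc_a_),
        ("disc_b", est.disc_b_),
    ):
        model.load_state(arrays, name + ".")
    for tag, opt in (("opt_g", est.opt_g_), ("opt_d", est.opt_d_)):
        opt.load([arrays[f"{tag}.{i}"] for i in range(len(opt.state()))])
    est.n_steps_ = int(meta["n_steps_"])
    est.shuffle_rng_.bit_generator.state = meta["rng"]["shuffle"]
    est.gen_a_.dropout_rng.bit_generator.state = meta["rng"]["dropout_a"]
    est.gen_b_.dropout_rng.bit_generator.state = meta["rng"]["dropout_b"]
    return est


# ---------------------------------------------------------------------------
# Config-driven training over an on-disk dataset manifest.
# ---------------------------------------------------------------------------


@dataclass
class TrainConfig:
    manifest: str = "data/manifest.tsv"
    out_dir: str = "runs/default"
    image_size: int = 256
    depth: int | None = None
    base_channels: int = 64
    channel_cap: int = 512
    disc_base_channels: int = 64
    dropout: float = 0.5
    lr_g: float = 5e-4
    lr_d: float = 1e-4
    batch_size: int = 4
    n_steps: int = 200
    lambda_ssim: float = 50.0
    lambda_f: float = 1.0
    lambda_l1: float = 100.0
    lambda_adv: float = 1.0
    lambda_recon: float = 1.0
    ssim_window: str = "gaussian"
    dtype: str = "float32"
    seed: int = 0
    checkpoint_every: int = 100
    log_every: int = 1

    def __post_init__(self):
        if self.lr_g <= 0 or self.lr_d <= 0:
            raise ValueError("learning rates must be positive")
        if self.batch_size <= 0 or self.n_steps <= 0:
            raise ValueError("batch_size and n_steps must be positive")

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        keys = set(cls.__dataclass_fields__)
        return cls(**cli_io.load_config(path, known_keys=keys))

    def to_yaml(self, path) -> None:
        cli_io.dump_config(path, asdict(self))

    def estimator_params(self) -> dict:
        skip = {"manifest", "out_dir", "seed", "checkpoint_every", "log_every"}
        d = {k: v for k, v in asdict(self).items() if k not in skip}
        d["random_state"] = self.seed
        return d


def _load_split(manifest_path, split: str):
    manifest = cli_io.read_manifest(manifest_path)
    base = Path(manifest_path).parent
    rows = manifest[manifest["split"] == split]
    if rows.empty:
        raise ValueError(f"manifest has no '{split}' rows")
    s, w, m = [], [], []
    for _, r in rows.iterrows():
        s.append(cli_io.load_image(base / r["path_artifact"]))
        w.append(cli_io.load_image(base / r["path_clean"]))
        m.append(cli_io.load_mask(base / r["path_mask"]))
    return np.stack(s), np.stack(w), np.stack(m)


def train(config: TrainConfig, resume=None) -> Path:
    """Run the training loop over a dataset manifest; returns the final
    checkpoint path.  ``resume`` continues from a saved checkpoint with the
    identical record stream an uninterrupted run would produce."""
    s, w, m = _load_split(config.manifest, "train")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out_dir / "config.yaml")
    if resume is not None:
        est = load_checkpoint(resume)
    else:
        est = DualGANInpainter(**config.estimator_params())
        est._init_models()
    log_path = out_dir / "train_log.tsv"
    records: list[dict] = []
    n_start = est.n_steps_
    while est.n_steps_ < config.n_steps:
        upto = min(
            config.n_steps,
            est.n_steps_ + config.checkpoint_every,
        )
        est._run_steps(s, w, m, upto)
        save_checkpoint(out_dir / f"checkpoint_{est.n_steps_:06d}.npz", est)
    final = out_dir / "checkpoint_final.npz"
    save_checkpoint(final, est)
    records = [r.as_dict() for r in est.history_[:: config.log_every]]
    import pandas as pd

    cli_io.atomic_write_bytes(
        log_path, pd.DataFrame(records).to_csv(sep="\t", index=False).encode()
    )
    return final


def train_step(
    est: DualGANInpainter, s01: np.ndarray, w01: np.ndarray, m: np.ndarray
) -> TrainRecord:
    """One optimization step on a paired batch (thin wrapper over the
    estimator's :meth:`DualGANInpainter.partial_fit_batch`)."""
    return est.partial_fit_batch(s01, w01, m)


def inpaint(image: np.ndarray, mask: np.ndarray, checkpoint) -> np.ndarray:
    """Repair one image with a trained (or freshly built) model.

    ``checkpoint`` may be a fitted :class:`DualGANInpainter` or a checkpoint
    path.  Pixels where the mask is 0 are bit-identical to the input.
    """
    est = checkpoint
    if not isinstance(est, DualGANInpainter):
        est = load_checkpoint(checkpoint)
    return est.transform(np.asarray(image, dtype=np.float64), masks=np.asarray(mask))
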