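import numpy as np
import pytest

import octinpaint as oi


def make_paired_arrays(
    n_train: int,
    n_test: int,
    size: int,
    seed: int,
    train_widths: tuple[int, int] = (6, 12),
    test_widths: tuple[int, int] = (12, 16),
    tilt_range: tuple[float, float] = (-15.0, 15.0),
    fill: float = 1.0,
):
    """In-memory paired dataset: clean W, masks M, artifact S (train+test).

    Clean images are quantized to 8-bit values as the on-disk pipeline
    would, so all identities that hold for PNG data hold here too.
    """
    n = n_train + n_test
    ss = np.random.SeedSequence(seed).generate_state(2 * n + 1)
    tilt_rng = np.random.default_rng(int(ss[-1]) % 2**31)
    W, M, S = [], [], []
    for i in range(n):
        widths = train_widths if i < n_train else test_widths
        scene = oi.generate_phantom(
            oi.default_params(
                size,
                seed=int(ss[2 * i]) % 2**31,
                tilt_deg=float(tilt_rng.uniform(*tilt_range)),
            )
        )
        w = np.round(scene.image * 255) / 255
        m = oi.sample_mask(
            oi.MaskParams(width_range=widths, seed=int(ss[2 * i + 1]) % 2**31),
            (size, size),
        ).grid
        W.append(w)
        M.append(m)
        S.append(oi.corrupt(w, m, fill=fill).artifact_image)
    return np.stack(W), np.stack(M), np.stack(S)


def tiny_estimator(size=32, n_steps=4, seed=0, **overrides):
    """A fast throwaway model for plumbing tests."""
    kwargs = dict(
        image_size=size,
        base_channels=4,
        channel_cap=16,
        disc_base_channels=8,
        n_steps=n_steps,
        batch_size=2,
        random_state=seed,
    )
    kwargs.update(overrides)
    return oi.DualGANInpainter(**kwargs)


@pytest.fixture(scope="session")
def phantom_scene_64():
    return oi.generate_phantom(oi.default_params(64, seed=0))


@pytest.fixture(scope="session")
def paired_32():
    return make_paired_arrays(4, 2, 32, seed=7, train_widths=(4, 6), test_widths=(6, 8))
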