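"""Loss-term analytics: closed forms, independent oracles, invariances."""

import numpy as np
import pytest
from skimage.metrics import structural_similarity as skimage_ssim

import octinpaint as oi
from octinpaint.losses import SSIMParams, ssim_map

RNG = np.random.default_rng(31)
GLOBAL = SSIMParams(window="global")


def naive_dft2(img: np.ndarray) -> np.ndarray:
    """O(N^4) direct double-sum DFT, the oracle for fft2."""
    h, w = img.shape
    out = np.zeros((h, w), dtype=complex)
    for u in range(h):
        for v in range(w):
            for r in range(h):
                for c in range(w):
                    out[u, v] += img[r, c] * np.exp(-2j * np.pi * (u * r / h + v * c / w))
    return out


class TestSSIM:
    def test_identical_images_give_exactly_one(self, phantom_scene_64):
        x = phantom_scene_64.image
        assert float(oi.ssim(x, x)) == 1.0
        assert float(oi.ssim(x, x, GLOBAL)) == 1.0

    def test_constant_images_match_closed_form(self):
        # mu_x=0, mu_y=1, all sigma=0: SSIM = C1 / (1 + C1), C1 = 1e-4
        v = float(oi.ssim(np.zeros((8, 8)), np.ones((8, 8)), GLOBAL))
        assert v == pytest.approx(1e-4 / (1 + 1e-4), rel=1e-12)

    @pytest.mark.parametrize("params", [SSIMParams(), GLOBAL])
    def test_symmetry_in_arguments(self, params):
        x, y = RNG.random((16, 16)), RNG.random((16, 16))
        assert float(oi.ssim(x, y, params)) == pytest.approx(
            float(oi.ssim(y, x, params)), rel=1e-12
        )

    def test_agrees_with_skimage_reference_implementation(self):
        x = RNG.random((32, 32))
        y = np.clip(x + 0.1 * RNG.standard_normal((32, 32)), 0, 1)
        ref = skimage_ssim(
            x, y, data_range=1.0, gaussian_weights=True, sigma=1.5,
            use_sample_covariance=False, win_size=11,
        )
        assert float(oi.ssim(x, y)) == pytest.approx(ref, abs=1e-12)

    def test_rescaling_image_and_dynamic_range_together_is_invariant(self):
        x, y = RNG.random((16, 16)), RNG.random((16, 16))
        base = float(oi.ssim(x, y, SSIMParams(dynamic_range=1.0)))
        scaled = float(oi.ssim(3 * x, 3 * y, SSIMParams(dynamic_range=3.0)))
        assert scaled == pytest.approx(base, rel=1e-10)

    def test_window_smaller_than_image_required(self):
        with pytest.raises(ValueError, match="global"):
            oi.ssim(np.zeros((8, 8)), np.zeros((8, 8)), SSIMParams())

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            oi.ssim(np.zeros((16, 16)), np.zeros((16, 17)), GLOBAL)


class TestSSIMLoss:
    def test_perfect_generators_give_zero(self):
        w, s = RNG.random((2, 16, 16)), RNG.random((2, 16, 16))
        assert float(oi.ssim_loss(w, w, s, s, GLOBAL)) == 0.0

    def test_equals_sum_of_directionwise_terms(self):
        w, ga, s, gb = (RNG.random((2, 16, 16)) for _ in range(4))
        loss = float(oi.ssim_loss(w, ga, s, gb, GLOBAL))
        d1 = 1 - float(ssim_map(w, ga, GLOBAL).mean())
        d2 = 1 - float(ssim_map(s, gb, GLOBAL).mean())
        assert loss == pytest.approx(d1 + d2, rel=1e-12)

    def test_one_perfect_direction_leaves_the_other(self):
        w = RNG.random((1, 16, 16))
        s, gb = RNG.random((1, 16, 16)), RNG.random((1, 16, 16))
        expected = 1 - float(oi.ssim(s[0], gb[0], GLOBAL))
        assert float(oi.ssim_loss(w, w, s, gb, GLOBAL)) == pytest.approx(expected, rel=1e-12)

    def test_nonnegative_on_random_batches(self):
        for _ in range(5):
            args = [RNG.random((2, 16, 16)) for _ in range(4)]
            assert float(oi.ssim_loss(*args, GLOBAL)) >= 0.0


class TestFFT:
    def test_matches_naive_double_sum_dft(self):
        img = RNG.random((8, 8))
        assert np.abs(oi.fft2(img) - naive_dft2(img)).max() < 1e-10

    def test_constant_image_concentrates_at_zero_frequency(self):
        c, n = 0.7, 8
        spec = oi.fft2(np.full((n, n), c))
        assert spec[0, 0] == pytest.approx(c * n * n)
        rest = spec.copy()
        rest[0, 0] = 0
        assert np.abs(rest).max() < 1e-10

    def test_real_input_yields_hermitian_spectrum(self):
        spec = oi.fft2(RNG.random((8, 8)))
        flipped = np.conj(spec[(-np.arange(8)) % 8][:, (-np.arange(8)) % 8])
        assert np.allclose(spec, flipped)


class TestFrequencyLoss:
    def test_zero_on_identical_pairs(self):
        w, s = RNG.random((2, 8, 8)), RNG.random((2, 8, 8))
        assert float(oi.frequency_loss(w, w, s, s)) == 0.0

    def test_scaling_the_perturbation_scales_the_term_linearly(self):
        w = RNG.random((1, 8, 8))
        delta = RNG.standard_normal((1, 8, 8))
        s = RNG.random((1, 8, 8))
        l1 = float(oi.frequency_loss(w, w + delta, s, s))
        l2 = float(oi.frequency_loss(w, w + 2 * delta, s, s))
        assert l2 == pytest.approx(2 * l1, rel=1e-10)

    def test_matches_from_scratch_reimplementation(self):
        w, ga, s, gb = (RNG.random((2, 8, 8)) for _ in range(4))

        def naive_term(a, b):
            vals = []
            for i in range(a.shape[0]):
                vals.append(np.abs(naive_dft2(a[i]) - naive_dft2(b[i])).mean())
            return float(np.mean(vals))

        expected = naive_term(ga, w) + naive_term(gb, s)
        assert float(oi.frequency_loss(w, ga, s, gb)) == pytest.approx(expected, abs=1e-8)

    def test_zero_frequency_loss_iff_zero_l1_loss(self):
        w, s = RNG.random((1, 8, 8)), RNG.random((1, 8, 8))
        ga = w + 1e-3
        assert float(oi.frequency_loss(w, ga, s, s)) > 0
        assert float(oi.l1_loss(w, ga, s, s)) > 0
        assert float(oi.frequency_loss(w, w, s, s)) == float(oi.l1_loss(w, w, s, s)) == 0.0


class TestL1Loss:
    def test_uniform_offset_gives_the_offset(self):
        w, s = RNG.random((2, 8, 8)), RNG.random((2, 8, 8))
        assert float(oi.l1_loss(w, w + 0.5, s, s)) == pytest.approx(0.5, rel=1e-12)

    def test_invariant_under_pixel_permutation(self):
        w, ga = RNG.random((1, 8, 8)), RNG.random((1, 8, 8))
        s = np.zeros((1, 8, 8))
        perm = RNG.permutation(64)
        wp = w.reshape(1, -1)[:, perm].reshape(1, 8, 8)
        gap = ga.reshape(1, -1)[:, perm].reshape(1, 8, 8)
        assert float(oi.l1_loss(w, ga, s, s)) == pytest.approx(
            float(oi.l1_loss(wp, gap, s, s)), rel=1e-12
        )


class TestAdversarialLoss:
    def test_uniform_half_scores_give_four_log_half(self):
        maps = [np.full((2, 1, 3, 3), 0.5)] * 4
        assert float(oi.adversarial_loss(*maps)) == pytest.approx(4 * np.log(0.5), rel=1e-12)

    def test_value_invariant_to_patch_map_size_for_constant_scores(self):
        small = [np.full((1, 1, 2, 2), 0.3), np.full((1, 1, 2, 2), 0.6)] * 2
        large = [np.full((1, 1, 30, 30), 0.3), np.full((1, 1, 30, 30), 0.6)] * 2
        assert float(oi.adversarial_loss(*small)) == pytest.approx(
            float(oi.adversarial_loss(*large)), rel=1e-12
        )

    def test_confident_discriminators_approach_zero_from_below(self):
        for eps in (1e-3, 1e-6):
            maps = [np.full((1, 1, 2, 2), v) for v in (1 - eps, eps, 1 - eps, eps)]
            val = float(oi.adversarial_loss(*maps))
            assert -0.01 < val < 0.0 or abs(val) < 4 * 2 * eps

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.3])
    def test_scores_outside_open_unit_interval_rejected(self, bad):
        maps = [np.full((1, 1, 2, 2), 0.5)] * 3 + [np.full((1, 1, 2, 2), bad)]
        with pytest.raises(ValueError, match="sigmoid"):
            oi.adversarial_loss(*maps)


class TestReconstructionLoss:
    def test_identity_cycles_give_zero(self):
        s, w = RNG.random((2, 8, 8)), RNG.random((2, 8, 8))
        assert float(oi.reconstruction_loss(s, s, w, w)) == 0.0

    def test_uniform_cycle_error_gives_the_offset(self):
        s, w = RNG.random((2, 8, 8)), RNG.random((2, 8, 8))
        assert float(oi.reconstruction_loss(s, s + 0.1, w, w)) == pytest.approx(0.1, rel=1e-9)

    def test_symmetric_in_the_two_domain_cycle_pairs(self):
        s, cs, w, cw = (RNG.random((1, 8, 8)) for _ in range(4))
        assert float(oi.reconstruction_loss(s, cs, w, cw)) == pytest.approx(
            float(oi.reconstruction_loss(w, cw, s, cs)), rel=1e-12
        )


class TestTotalLoss:
    def test_zero_terms_give_zero_total(self):
        assert oi.total_loss(0, 0, 0, 0, 0).total == 0.0

    def test_unit_terms_with_default_weights_sum_to_153(self):
        report = oi.total_loss(1, 1, 1, 1, 1)
        assert report.total == 153.0

    def test_total_is_weighted_sum_of_reported_terms(self):
        wts = oi.LossWeights()
        report = oi.total_loss(0.2, 3.0, 0.05, -2.7, 0.4, wts)
        expected = 50 * 0.2 + 1 * 3.0 + 100 * 0.05 + 1 * -2.7 + 1 * 0.4
        assert report.total == pytest.approx(expected, rel=1e-12)

    def test_zeroed_frequency_weight_is_the_ablation_configuration(self):
        wts = oi.LossWeights(lambda_f=0.0)
        report = oi.total_loss(1, 99.0, 1, 1, 1, wts)
        assert report.total == 50 + 100 + 1 + 1  # the frequency term drops out
        assert report.l_f == 99.0  # but stays reported for logging

    def test_non_finite_term_rejected_with_its_name(self):
        with pytest.raises(ValueError, match="l_f"):
            oi.total_loss(0, np.nan, 0, 0, 0)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            oi.LossWeights(lambda_ssim=-1.0)
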