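"""Repair-fidelity and segmentation-overlap metrics."""

import numpy as np
import pytest

import octinpaint as oi
from octinpaint.metrics import (
    PSNR_CAP,
    MetricsReport,
    RegionSpec,
    boundary_overlap,
)

RNG = np.random.default_rng(41)


def stripe_mask(h=64, w=64, start=20, stop=36):
    m = np.zeros((h, w), dtype=np.uint8)
    m[:, start:stop] = 1
    return m


class TestPSNR:
    def test_identical_images_hit_the_cap(self):
        x = RNG.random((16, 16))
        assert oi.psnr(x, x) == PSNR_CAP

    def test_unit_error_gives_zero_decibels(self):
        assert oi.psnr(np.zeros((16, 16)), np.ones((16, 16))) == pytest.approx(0.0)

    def test_halving_mse_raises_psnr_by_three_db(self):
        x = np.zeros((16, 16))
        a = oi.psnr(x, np.full((16, 16), 0.5))
        b = oi.psnr(x, np.full((16, 16), 0.5 / np.sqrt(2)))
        assert b - a == pytest.approx(10 * np.log10(2), rel=1e-9)

    def test_masked_mode_ignores_pixels_outside_the_mask(self):
        m = stripe_mask()
        x = RNG.random((64, 64))
        y = x.copy()
        y[m == 0] += 0.5  # corrupt only the complement
        assert oi.psnr(x, y, RegionSpec(mode="masked", mask=m)) == PSNR_CAP
        assert oi.psnr(x, y, RegionSpec(mode="full")) < PSNR_CAP

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            RegionSpec(mode="masked", mask=np.zeros((4, 4), dtype=np.uint8))


class TestSSIMMetric:
    def test_identical_crops_give_one(self):
        x = RNG.random((64, 64))
        assert oi.ssim_metric(x, x, RegionSpec(mode="bbox", mask=stripe_mask())) == 1.0

    def test_full_mode_equals_the_loss_module_ssim(self):
        x, y = RNG.random((32, 32)), RNG.random((32, 32))
        assert oi.ssim_metric(x, y) == pytest.approx(float(oi.ssim(x, y)), rel=1e-12)

    def test_symmetric_in_arguments(self):
        x, y = RNG.random((64, 64)), RNG.random((64, 64))
        reg = RegionSpec(mode="bbox", mask=stripe_mask())
        assert oi.ssim_metric(x, y, reg) == pytest.approx(oi.ssim_metric(y, x, reg), rel=1e-12)

    def test_narrow_stripe_guides_to_global_window(self):
        x = RNG.random((64, 64))
        narrow = RegionSpec(mode="bbox", mask=stripe_mask(start=20, stop=24))
        with pytest.raises(ValueError, match="global"):
            oi.ssim_metric(x, x, narrow)
        sp = oi.SSIMParams(window="global")
        assert oi.ssim_metric(x, x, narrow, sp) == 1.0


class TestConfusion:
    def test_hand_counted_four_by_four_case(self):
        truth = np.zeros((4, 4), dtype=np.uint8)
        truth[0, :2] = 1
        truth[1, :2] = 1  # |Y| = 4
        pred = np.zeros((4, 4), dtype=np.uint8)
        pred[0, :2] = 1
        pred[2, 2:] = 1  # |X| = 4, overlap 2
        c = oi.confusion(pred, truth)
        assert (c.tp, c.tn, c.fp, c.fn) == (2, 10, 2, 2)
        assert c.total == 16

    def test_perfect_prediction_has_no_errors(self):
        y = RNG.integers(0, 2, (8, 8)).astype(np.uint8)
        c = oi.confusion(y, y)
        assert c.fp == c.fn == 0

    def test_complementary_masks_have_no_agreement(self):
        y = RNG.integers(0, 2, (8, 8)).astype(np.uint8)
        c = oi.confusion(1 - y, y)
        assert c.tp == c.tn == 0

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            oi.confusion(np.full((4, 4), 2), np.zeros((4, 4)))


class TestOverlapScores:
    def test_dice_of_half_overlapping_masks_is_half(self):
        # |X| = 4, |Y| = 4, |X∩Y| = 2 -> 2*2 / 8
        x = np.array([[1, 1, 1, 1], [0, 0, 0, 0]], dtype=np.uint8)
        y = np.array([[1, 1, 0, 0], [1, 1, 0, 0]], dtype=np.uint8)
        assert oi.dsc(x, y) == 0.5

    def test_equal_nonempty_masks_score_one_disjoint_score_zero(self):
        a = np.array([[1, 1, 0, 0]], dtype=np.uint8)
        b = np.array([[0, 0, 1, 1]], dtype=np.uint8)
        assert oi.dsc(a, a) == 1.0
        assert oi.dsc(a, b) == 0.0
        assert oi.jaccard(a, a) == 1.0

    def test_pixel_accuracy_hand_case(self):
        c = oi.ConfusionCounts(tp=2, tn=90, fp=2, fn=2)
        assert oi.pixel_accuracy(c) == pytest.approx(92 / 96)
        assert oi.pixel_accuracy(oi.ConfusionCounts(5, 5, 0, 0)) == 1.0

    def test_f1_hand_case(self):
        assert oi.f1(oi.ConfusionCounts(tp=2, tn=0, fp=2, fn=2)) == 0.5
        assert oi.f1(oi.ConfusionCounts(tp=3, tn=9, fp=0, fn=0)) == 1.0

    def test_jaccard_hand_case_and_dice_identity(self):
        x = np.array([[1, 1, 1, 1, 0, 0]], dtype=np.uint8)
        y = np.array([[0, 0, 1, 1, 1, 1]], dtype=np.uint8)
        j = oi.jaccard(x, y)
        assert j == pytest.approx(1 / 3)
        assert oi.dsc(x, y) == pytest.approx(2 * j / (1 + j))

    def test_dice_equals_f1_and_jaccard_identity_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            x = rng.integers(0, 2, (8, 8)).astype(np.uint8)
            y = rng.integers(0, 2, (8, 8)).astype(np.uint8)
            d = oi.dsc(x, y)
            assert d == pytest.approx(oi.f1(oi.confusion(x, y)), abs=1e-15)
            j = oi.jaccard(x, y)
            assert d == pytest.approx(2 * j / (1 + j), abs=1e-12)

    def test_both_empty_masks_count_as_perfect_agreement(self):
        z = np.zeros((4, 4), dtype=np.uint8)
        assert oi.dsc(z, z) == 1.0
        assert oi.jaccard(z, z) == 1.0
        assert oi.f1(oi.ConfusionCounts(0, 16, 0, 0)) == 1.0


class TestSegmentCornea:
    def test_recovers_outer_surfaces_of_a_clean_phantom(self):
        scene = oi.generate_phantom(oi.default_params(64, speckle_strength=0.0, seed=0))
        seg = oi.segment_cornea(scene.image)
        for key in ("EP", "EN"):
            truth_rows = scene.boundary_rows[key]
            cols = np.nonzero(truth_rows >= 0)[0]
            got_rows = np.argmax(seg[key][:, cols] > 0, axis=0)
            # rasterization can differ by the rounding convention only
            assert np.abs(got_rows - truth_rows[cols]).max() <= 1

    def test_saturated_stripe_inflates_the_recovered_region(self):
        scene = oi.generate_phantom(oi.default_params(64, seed=0))
        mask = oi.sample_mask(oi.MaskParams(width_range=(10, 10), center_range=(32, 32), seed=0), (64, 64))
        corrupted = oi.corrupt(scene.image, mask).artifact_image
        gt = oi.segment_cornea(scene.image)["region"]
        assert oi.dsc(oi.segment_cornea(corrupted)["region"], gt) < oi.dsc(gt, gt)

    def test_strict_boundary_overlap_is_exact_on_identical_curves(self):
        scene = oi.generate_phantom(oi.default_params(64, seed=0))
        ep = scene.boundary_labels["EP"]
        assert boundary_overlap(ep, ep, tolerance=0) == 1.0


class TestEvaluate:
    @pytest.fixture(scope="class")
    @staticmethod
    def dataset(tmp_path_factory):
        out = tmp_path_factory.mktemp("ds")
        oi.build_dataset(
            n_train=2,
            n_test=3,
            phantom_params=oi.default_params(64),
            train_mask_params=oi.MaskParams(width_range=(6, 8)),
            test_mask_params=oi.MaskParams(width_range=(12, 14)),
            out_dir=out,
            seed=1,
        )
        return out / "manifest.tsv"

    @staticmethod
    def oracle(img, mask, manifest_dir):
        # returns the paired clean image (perfect inpainter) — found by
        # matching the artifact image outside the mask
        from octinpaint import cli_io

        man = cli_io.read_manifest(manifest_dir)
        for _, r in man.iterrows():
            clean = cli_io.load_image(manifest_dir.parent / r["path_clean"])
            if np.array_equal(clean[mask == 0], img[mask == 0]):
                return clean
        raise AssertionError("no paired clean image found")

    def test_oracle_inpainter_scores_perfectly(self, dataset):
        report = oi.evaluate(dataset, lambda img, m: self.oracle(img, m, dataset))
        assert (report.per_image["ssim"] == 1.0).all()
        assert (report.per_image["psnr"] == PSNR_CAP).all()
        assert report.means["dsc"] == 1.0

    def test_identity_inpainter_reproduces_the_before_repair_baseline(self, dataset):
        report = oi.evaluate(dataset, lambda img, m: img)
        # saturated stripes: poor fidelity and inflated segmentation
        assert report.means["psnr"] < 20
        assert report.means["dsc"] < 1.0

    def test_oracle_dominates_identity_on_every_image(self, dataset):
        good = oi.evaluate(dataset, lambda img, m: self.oracle(img, m, dataset))
        bad = oi.evaluate(dataset, lambda img, m: img)
        assert (good.per_image["psnr"].values > bad.per_image["psnr"].values).all()
        assert (good.per_image["ssim"].values > bad.per_image["ssim"].values).all()

    def test_reported_means_equal_per_image_means(self, dataset):
        report = oi.evaluate(dataset, lambda img, m: img)
        for k, v in report.means.items():
            assert v == pytest.approx(report.per_image[k].mean(), rel=1e-12)

    def test_missing_files_are_listed_and_evaluation_continues(self, dataset, tmp_path):
        import shutil

        work = tmp_path / "partial"
        shutil.copytree(dataset.parent, work)
        victim = next(work.glob("test_*_artifact.png"))
        victim.unlink()
        report = oi.evaluate(work / "manifest.tsv", lambda img, m: img)
        assert report.partial
        assert len(report.per_image) == 2

    def test_report_csv_written_with_summary_row(self, dataset, tmp_path):
        out = tmp_path / "report.csv"
        oi.evaluate(dataset, lambda img, m: img, out_csv=out)
        import pandas as pd

        df = pd.read_csv(out)
        assert df.iloc[-1]["path"] == "MEAN"
        assert isinstance(oi.evaluate(dataset, lambda img, m: img), MetricsReport)
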