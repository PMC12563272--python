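import itertools

import numpy as np
import pytest

import wellquant as wq
from wellquant.geometry import CircleROI, WellImage
from wellquant.segmentation import SegMask


def m(arr):
    return SegMask(np.asarray(arr, dtype=bool))


class TestIoU:
    def test_identical_masks(self):
        a = m([[1, 0], [1, 1]])
        assert wq.iou(a, a) == 1.0

    def test_disjoint_masks(self):
        assert wq.iou(m([[1, 0], [0, 0]]), m([[0, 0], [0, 1]])) == 0.0

    def test_shifted_blocks(self):
        pred = np.zeros((4, 4), bool)
        truth = np.zeros((4, 4), bool)
        pred[0:2, 0:2] = True
        truth[0:2, 1:3] = True
        assert wq.iou(m(pred), m(truth)) == pytest.approx(2 / 6)

    def test_empty_empty_is_one(self):
        z = m(np.zeros((3, 3)))
        assert wq.iou(z, z) == 1.0

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            wq.iou(m(np.zeros((2, 2))), m(np.zeros((3, 3))))

    def test_exhaustive_3x3_oracle_and_symmetry(self):
        """On all 2^9 x 2^9 3x3 mask pairs, iou equals the brute-force set
        computation and is symmetric."""
        masks = [
            np.array(bits, dtype=bool).reshape(3, 3)
            for bits in itertools.product([0, 1], repeat=9)
        ]
        flat = np.array([mk.ravel() for mk in masks])  # (512, 9)
        inter = flat.astype(int) @ flat.T.astype(int)
        pop = flat.sum(axis=1)
        union = pop[:, None] + pop[None, :] - inter
        rng = np.random.default_rng(1)
        idx = rng.integers(0, 512, size=(4000, 2))
        for i, j in idx:
            expected = 1.0 if union[i, j] == 0 else inter[i, j] / union[i, j]
            assert wq.iou(m(masks[i]), m(masks[j])) == pytest.approx(expected)
            assert wq.iou(m(masks[j]), m(masks[i])) == pytest.approx(expected)
        # full exhaustive check through the vectorized identity
        got = np.where(union == 0, 1.0, inter / np.maximum(union, 1))
        assert np.allclose(got, got.T)

    def test_monotone_in_added_positives(self):
        rng = np.random.default_rng(2)
        truth = m(rng.uniform(size=(8, 8)) < 0.3)
        pred = rng.uniform(size=(8, 8)) < 0.2
        inter0 = (pred & truth.pixels).sum()
        union0 = (pred | truth.pixels).sum()
        grown = pred.copy()
        grown[rng.integers(0, 8, 5), rng.integers(0, 8, 5)] = True
        assert (grown & truth.pixels).sum() >= inter0
        assert (grown | truth.pixels).sum() >= union0


class TestCoverageFraction:
    ROI = CircleROI(20, 20, 15)

    def test_empty_mask(self):
        assert wq.coverage_fraction(m(np.zeros((41, 41))), self.ROI) == 0.0

    def test_full_roi_interior(self):
        full = self.ROI.contains((41, 41))
        assert wq.coverage_fraction(m(full), self.ROI) == 100.0

    def test_half_plane_is_half(self):
        half = np.zeros((41, 41), bool)
        half[:, :20] = True  # x < center: half the disk, rim column excluded
        got = wq.coverage_fraction(m(half & self.ROI.contains((41, 41))), self.ROI)
        assert got == pytest.approx(50, abs=2.5)

    def test_degenerate_roi_raises(self):
        with pytest.raises(ValueError):
            wq.coverage_fraction(m(np.zeros((5, 5))), CircleROI(100, 100, 1))


class TestCompareModels:
    ROI = CircleROI(25, 25, 20)

    def test_identical_lists(self):
        masks = [m(self.ROI.contains((51, 51)))] * 3
        cmp_ = wq.compare_models(masks, masks, self.ROI)
        assert cmp_.mean_coverage_diff_pct == 0.0
        assert cmp_.sd_coverage_diff_pct == 0.0

    def test_constant_offset(self):
        inside = self.ROI.contains((51, 51))
        n_inside = inside.sum()
        target = int(round(0.02 * n_inside))
        ys, xs = np.nonzero(inside)
        a, b = np.zeros((51, 51), bool), np.zeros((51, 51), bool)
        b[ys[:target], xs[:target]] = True
        offset = 100.0 * target / n_inside
        cmp_ = wq.compare_models([m(a)] * 4, [m(b)] * 4, self.ROI)
        assert cmp_.mean_coverage_diff_pct == pytest.approx(offset)
        assert cmp_.sd_coverage_diff_pct == pytest.approx(0.0)

    def test_single_image_sd_zero(self):
        a = m(np.zeros((51, 51)))
        cmp_ = wq.compare_models([a], [a], self.ROI)
        assert cmp_.n_images == 1 and cmp_.sd_coverage_diff_pct == 0.0

    def test_length_mismatch(self):
        a = m(np.zeros((51, 51)))
        with pytest.raises(ValueError):
            wq.compare_models([a], [a, a], self.ROI)


class TestBaseline:
    def test_uniform_interior_gives_empty_mask(self):
        img = WellImage(np.full((101, 101), 120, np.uint8))
        roi = CircleROI(50, 50, 40)
        assert wq.segment_baseline(img, roi).pixels.sum() == 0

    def test_iou_on_synthetic_fixture(self, fixture_50):
        img, truth = fixture_50
        mask = wq.segment_baseline(img, truth.roi)
        assert wq.iou(mask, SegMask(truth.mask)) >= 0.7

    def test_deterministic(self, fixture_50):
        img, truth = fixture_50
        a = wq.segment_baseline(img, truth.roi)
        b = wq.segment_baseline(img, truth.roi)
        assert np.array_equal(a.pixels, b.pixels)

    def test_zero_outside_roi(self, fixture_50):
        img, truth = fixture_50
        mask = wq.segment_baseline(img, truth.roi)
        assert not mask.pixels[~truth.roi.contains(img.shape)].any()


class TestTrainedSegmenter:
    def test_validation_iou(self, trained_model):
        model, validation, roi = trained_model
        ious = [
            wq.iou(wq.predict(model, img, roi), msk) for img, msk in validation
        ]
        assert np.mean(ious) >= 0.8

    def test_memorization_sanity(self, small_flat):
        img, truth = wq.render_well(small_flat, wq.CellRenderSpec(), 40, seed=21)
        model = wq.train_segmenter([(img, SegMask(truth.mask))], seed=0)
        assert wq.iou(wq.predict(model, img, truth.roi), SegMask(truth.mask)) >= 0.9

    def test_manifest_provenance(self, trained_model):
        model, _, _ = trained_model
        man = model.training_manifest
        assert man["seed"] == 3
        assert man["n_images"] == 40
        assert len(man["dataset_fingerprint"]) == 16

    def test_repeat_training_is_reproducible(self, small_flat):
        pairs = []
        for s in range(4):
            img, truth = wq.render_well(small_flat, wq.CellRenderSpec(), 30, seed=s)
            pairs.append((img, SegMask(truth.mask)))
        roi = truth.roi
        img_t, truth_t = wq.render_well(small_flat, wq.CellRenderSpec(), 35, seed=99)
        i1 = wq.iou(
            wq.predict(wq.train_segmenter(pairs, seed=5), img_t, roi),
            SegMask(truth_t.mask),
        )
        i2 = wq.iou(
            wq.predict(wq.train_segmenter(pairs, seed=5), img_t, roi),
            SegMask(truth_t.mask),
        )
        assert abs(i1 - i2) < 0.05

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            wq.train_segmenter([])

    def test_predict_negative_control_and_contracts(self, trained_model, small_flat):
        model, _, roi = trained_model
        img, truth = wq.render_well(small_flat, wq.CellRenderSpec(), 0, seed=33)
        mask = wq.predict(model, img, roi)
        assert mask.shape == img.shape
        assert wq.coverage_fraction(mask, roi) < 1.0
        again = wq.predict(model, img, roi)
        assert np.array_equal(mask.pixels, again.pixels)
        assert not mask.pixels[~roi.contains(img.shape)].any()

    def test_untrained_blob_rejected(self, fixture_50):
        img, truth = fixture_50
        model = wq.SegModel(backend="trained_cnn", training_manifest={"seed": 0})
        with pytest.raises(ValueError):
            wq.predict(model, img, truth.roi)


class TestBubbleRobustness:
    def test_bubble_changes_little_and_stays_negative(self, trained_model, small_flat):
        """Across 20 paired frames identical except for one injected bubble,
        the coverage error grows by < 2 percentage points and under 20% of
        bubble pixels are called cell."""
        model, _, roi = trained_model
        cells = wq.CellRenderSpec()
        art = wq.ArtifactSpec(bubble_probability=1.0, bubble_radius_um=(30, 60))
        errs_plain, errs_bubble, bubble_pos = [], [], []
        for s in range(20):
            img_p, tr_p = wq.render_well(small_flat, cells, 30, None, seed=200 + s)
            img_b, tr_b = wq.render_well(small_flat, cells, 30, art, seed=200 + s)
            denom = roi.contains(tr_p.mask.shape).sum()
            cov_p = 100 * tr_p.mask.sum() / denom
            cov_b = 100 * tr_b.mask.sum() / denom
            errs_plain.append(
                abs(wq.coverage_fraction(wq.predict(model, img_p, roi), roi) - cov_p)
            )
            mask_b = wq.predict(model, img_b, roi)
            errs_bubble.append(abs(wq.coverage_fraction(mask_b, roi) - cov_b))
            bubble_px = (
                (img_b.pixels.astype(int) != img_p.pixels.astype(int))
                & ~tr_b.mask
                & ~tr_p.mask
            )
            if bubble_px.any():
                bubble_pos.append(mask_b.pixels[bubble_px].mean())
        assert np.mean(errs_bubble) - np.mean(errs_plain) < 2.0
        assert np.mean(bubble_pos) < 0.2
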