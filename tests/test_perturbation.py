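"""LIME / Squaregrid / RISE: oracle equivalence, closed forms, convergence."""
import numpy as np
import pytest

from biaslens import (ClassifierContract, ConstantClassifier, RiseConfig,
                      Segmentation, lime_explain, make_region_oracle,
                      rise_explain, rise_masks, slic_segment,
                      square_grid_segmentation, squaregrid_explain)


def checkerboard_segmentation(h, w, n_seg):
    """Equal vertical strips as a simple known segmentation."""
    cols = np.clip(np.arange(w) * n_seg // w, 0, n_seg - 1)
    labels = np.broadcast_to(cols, (h, w)).astype(int)
    return Segmentation(labels=np.array(labels), n_segments=n_seg)


class SegmentIndicatorBox(ClassifierContract):
    """Black box whose class-1 probability is a linear function of which
    segments are 'on' (i.e. unchanged from the reference image)."""

    n_classes = 2

    def __init__(self, reference, labels, intercept, coefs):
        self.reference = reference
        self.labels = labels
        self.intercept = intercept
        self.coefs = np.asarray(coefs, dtype=float)

    def _z(self, image):
        return np.array([
            float(np.array_equal(image[self.labels == k],
                                 self.reference[self.labels == k]))
            for k in range(len(self.coefs))])

    def predict(self, images):
        p1 = np.array([self.intercept + self.coefs @ self._z(im)
                       for im in images])
        return np.stack([1.0 - p1, p1], axis=1)


class TestSlic:
    def test_labels_partition_all_pixels(self, rng):
        img = rng.random((48, 48, 3))
        seg = slic_segment(img, nslic=8)
        present = np.unique(seg.labels)
        np.testing.assert_array_equal(present,
                                      np.arange(seg.n_segments))

    def test_two_tone_image_segments_split_by_side(self):
        img = np.zeros((40, 40, 3))
        img[:, 20:] = 0.9
        seg = slic_segment(img, nslic=4)
        sides = np.arange(40) >= 20
        for k in range(seg.n_segments):
            member_cols = sides[np.where(seg.labels == k)[1]]
            purity = max(member_cols.mean(), 1 - member_cols.mean())
            assert purity >= 0.95

    def test_constant_image_flagged_degenerate(self):
        seg = slic_segment(np.full((32, 32, 3), 0.5))
        assert seg.degenerate and seg.n_segments == 1

    def test_nslic_below_two_rejected(self):
        with pytest.raises(ValueError):
            slic_segment(np.zeros((32, 32, 3)), nslic=1)


class TestLime:
    def test_exhaustive_vanishing_ridge_recovers_linear_black_box(self, rng):
        # independent oracle: exact least squares over all 2^8 patterns
        h = w = 16
        seg = checkerboard_segmentation(h, w, 8)
        ref = rng.random((h, w, 3))
        box = SegmentIndicatorBox(ref, seg.labels, 0.1,
                                  [0, 0, 0, 0.2, 0, 0, 0, 0])
        hm = lime_explain(box, ref, seg, class_index=1, exhaustive=True,
                          ridge_alpha=0.0)
        coefs = np.array([hm.values[seg.labels == k][0] for k in range(8)])
        z = ((np.arange(256)[:, None] >> np.arange(8)) & 1).astype(float)
        y = 0.1 + z @ np.array([0, 0, 0, 0.2, 0, 0, 0, 0])
        design = np.hstack([z, np.ones((256, 1))])
        ols = np.linalg.lstsq(design, y, rcond=None)[0][:8]
        np.testing.assert_allclose(coefs, ols, atol=1e-8)
        np.testing.assert_allclose(coefs,
                                   [0, 0, 0, 0.2, 0, 0, 0, 0], atol=1e-8)

    def test_constant_classifier_gives_zero_coefficients(self, rng):
        seg = checkerboard_segmentation(16, 16, 4)
        hm = lime_explain(ConstantClassifier(), rng.random((16, 16, 3)),
                          seg, n_samples=64, seed=0)
        np.testing.assert_allclose(hm.values, 0.0, atol=1e-8)

    def test_same_seed_reproduces_heatmap(self, rng):
        img = rng.random((16, 16, 3))
        seg = checkerboard_segmentation(16, 16, 4)
        orc = make_region_oracle(seg.labels == 1)
        a = lime_explain(orc, img, seg, n_samples=32, seed=5)
        b = lime_explain(orc, img, seg, n_samples=32, seed=5)
        np.testing.assert_array_equal(a.values, b.values)

    def test_result_invariant_to_classifier_batch_size(self, rng):
        img = rng.random((16, 16, 3))
        seg = checkerboard_segmentation(16, 16, 4)
        orc = make_region_oracle(seg.labels == 2)
        a = lime_explain(orc, img, seg, n_samples=40, seed=3, batch_size=7)
        b = lime_explain(orc, img, seg, n_samples=40, seed=3, batch_size=64)
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_too_few_samples_rejected(self, rng):
        seg = checkerboard_segmentation(16, 16, 8)
        with pytest.raises(ValueError):
            lime_explain(ConstantClassifier(), rng.random((16, 16, 3)),
                         seg, n_samples=4)


class TestSquaregrid:
    def test_grid_cells_equal_size_and_centered(self):
        seg = square_grid_segmentation((70, 70), 2)   # 4x4 grid, 17px cells
        sizes = np.bincount(seg.labels.ravel())
        assert seg.n_segments == 16
        inner = seg.labels[1 + 2:70 - 3, 1 + 2:70 - 3]
        # interior cells are 17x17: check a central cell exactly
        assert (seg.labels == seg.labels[35, 35]).sum() == 17 * 17

    def test_single_level_equals_lime_on_that_grid(self, rng):
        img = rng.random((32, 32, 3))
        seg = square_grid_segmentation((32, 32), 1)
        orc = make_region_oracle(seg.labels == 0)
        hm_grid = squaregrid_explain(orc, img, levels=(1,),
                                     n_samples_per_level=64, seed=4)
        sub_seed = int(np.random.default_rng([4, 1]).integers(2 ** 31))
        hm_lime = lime_explain(orc, img, seg, n_samples=64, seed=sub_seed)
        np.testing.assert_allclose(hm_grid.values, hm_lime.values,
                                   atol=1e-12)

    def test_constant_classifier_gives_zero_map(self, rng):
        hm = squaregrid_explain(ConstantClassifier(), rng.random((32, 32, 3)),
                                levels=(1, 2), n_samples_per_level=32, seed=0)
        np.testing.assert_allclose(hm.values, 0.0, atol=1e-8)

    def test_corner_patch_oracle_localized_by_summed_map(self, rng):
        img = rng.random((64, 64, 3))
        mask = np.zeros((64, 64), dtype=bool)
        mask[:16, :16] = True      # one level-2 cell
        orc = make_region_oracle(mask)
        hm = squaregrid_explain(orc, img, levels=(2, 3, 4),
                                n_samples_per_level=128, seed=2)
        peak = np.unravel_index(np.argmax(hm.values), hm.values.shape)
        assert mask[peak]

    def test_too_fine_level_skipped_with_warning(self, rng):
        img = rng.random((32, 32, 3))
        with pytest.warns(UserWarning, match="skipped"):
            hm = squaregrid_explain(ConstantClassifier(), img,
                                    levels=(1, 6), n_samples_per_level=16,
                                    seed=0)
        assert hm.params["levels"] == [1]


class TestRise:
    def test_keep_prob_one_gives_all_ones_masks(self):
        masks = rise_masks(RiseConfig(n_masks=3, cell_grid=4, keep_prob=1.0,
                                      seed=0), (20, 20))
        np.testing.assert_array_equal(masks, 1.0)

    def test_mask_values_in_unit_interval_and_mean_near_keep_prob(self):
        cfg = RiseConfig(n_masks=100, cell_grid=7, keep_prob=0.5, seed=1)
        masks = rise_masks(cfg, (50, 50))
        assert masks.min() >= 0.0 and masks.max() <= 1.0
        n_cells = 100 * 7 * 7   # independent Bernoulli draws behind the masks
        band = 3 * np.sqrt(0.5 * 0.5 / n_cells)
        assert abs(masks.mean() - 0.5) <= band

    def test_same_seed_reproduces_mask_stack(self):
        cfg = RiseConfig(n_masks=20, cell_grid=5, keep_prob=0.4, seed=9)
        np.testing.assert_array_equal(rise_masks(cfg, (30, 30)),
                                      rise_masks(cfg, (30, 30)))

    def test_single_allon_mask_returns_classifier_probability(self, rng):
        img = rng.random((20, 20, 3))
        orc = make_region_oracle(np.ones((20, 20), dtype=bool))
        cfg = RiseConfig(n_masks=1, cell_grid=4, keep_prob=1.0, seed=0)
        hm = rise_explain(orc, img, 1, cfg)
        expected = orc.predict_one(img)[1]
        np.testing.assert_allclose(hm.values, expected, atol=1e-6)

    def test_constant_classifier_within_monte_carlo_band(self, rng):
        c, p1, n = 0.7, 0.5, 2000
        cfg = RiseConfig(n_masks=n, cell_grid=7, keep_prob=p1, seed=3)
        hm = rise_explain(ConstantClassifier((0.3, c)),
                          rng.random((56, 56, 3)), 1, cfg)
        se = c * np.sqrt((1 - p1) / (n * p1))   # binomial bound per pixel
        assert np.abs(hm.values - c).max() <= 4 * se

    def test_result_invariant_to_batch_size(self, rng):
        img = rng.random((24, 24, 3))
        orc = make_region_oracle(img[:, :, 0] > 0.5)
        a = rise_explain(orc, img, 1, RiseConfig(n_masks=60, seed=2,
                                                 batch_size=7))
        b = rise_explain(orc, img, 1, RiseConfig(n_masks=60, seed=2,
                                                 batch_size=100))
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_patch_oracle_argmax_lands_in_patch(self, seed):
        rng = np.random.default_rng(100 + seed)
        img = np.clip(0.45 + 0.05 * rng.standard_normal((84, 84, 3)), 0, 1)
        mask = np.zeros((84, 84), dtype=bool)
        mask[24:36, 36:48] = True     # one cell-sized patch (84/7 = 12)
        img[mask] = 0.95
        orc = make_region_oracle(mask)
        hm = rise_explain(orc, img, 1, RiseConfig(n_masks=4000, seed=seed))
        peak = np.unravel_index(np.argmax(hm.values), hm.values.shape)
        assert mask[peak]

    def test_monte_carlo_error_shrinks_with_sample_size(self, rng):
        img = rng.random((40, 40, 3))
        devs = {}
        for n in (500, 2000):
            hm = rise_explain(ConstantClassifier((0.4, 0.6)), img, 1,
                              RiseConfig(n_masks=n, seed=11))
            devs[n] = np.sqrt(np.mean((hm.values - 0.6) ** 2))
        # RMS error should fall roughly like 1/sqrt(N): allow generous slack
        assert devs[2000] < devs[500]

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            RiseConfig(n_masks=0)
        with pytest.raises(ValueError):
            RiseConfig(cell_grid=1)
        with pytest.raises(ValueError):
            RiseConfig(keep_prob=0.0)
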