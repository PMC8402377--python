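"""GradCAM and the gradient explainers: closed forms and axioms."""
import numpy as np
import pytest

from biaslens import (DifferentiableClassifierContract,
                      EnsembleClassifier, IgConfig, SmallCnn, SmoothConfig,
                      completeness_gap, gradcam, integrated_gradient,
                      make_region_oracle, smooth_gradient, vanilla_gradient)
from biaslens.contracts import softmax


class LinearLogitModel(DifferentiableClassifierContract):
    """y_1 = sum(w * x); y_0 = 0 — gradients known exactly."""

    n_classes = 2

    def __init__(self, w):
        self.w = np.asarray(w, dtype=float)

    def logits(self, images):
        z1 = np.tensordot(np.asarray(images, dtype=float), self.w, axes=3)
        return np.stack([np.zeros_like(z1), z1], axis=1)

    def predict(self, images):
        return softmax(self.logits(images), axis=1)

    def input_gradient(self, image, class_index):
        return self.w if class_index == 1 else np.zeros_like(self.w)

    def feature_layers(self):
        return []

    def feature_maps(self, image, layer_id):
        raise ValueError("no layers")

    def feature_map_gradient(self, image, class_index, layer_id):
        raise ValueError("no layers")


@pytest.fixture(scope="module")
def linear_model(rng_module=np.random.default_rng(77)):
    return LinearLogitModel(rng_module.normal(size=(12, 12, 3)))


class TestGradCam:
    def test_output_nonnegative_and_unit_normalized(self, rng):
        mask = np.zeros((56, 56), dtype=bool)
        mask[8:24, 8:24] = True
        orc = make_region_oracle(mask)
        hm = gradcam(orc, rng.random((56, 56, 3)))
        assert hm.values.min() >= 0.0
        assert hm.values.max() == pytest.approx(1.0)

    def test_oracle_heatmap_support_confined_to_region(self, rng):
        # region aligned to the oracle's 14x14 pooled cells: support of the
        # upsampled CAM stays within one pooled cell of the region
        mask = np.zeros((56, 56), dtype=bool)
        mask[8:24, 8:24] = True     # cells are 4x4 px here
        orc = make_region_oracle(mask)
        hm = gradcam(orc, rng.random((56, 56, 3)))
        far = np.ones((56, 56), dtype=bool)
        far[4:28, 4:28] = False     # region dilated by one pooled cell
        assert hm.values[far].max() == 0.0

    def test_alpha_weights_match_finite_difference_gradients(self):
        model = SmallCnn((32, 32), (4, 6, 3), seed=1, activation="softplus",
                         pool="mean")
        rng = np.random.default_rng(5)
        for k in ("b1", "b2", "b3", "bd"):
            model.params[k] = rng.normal(0, 0.2, size=model.params[k].shape)
        x = rng.random((32, 32, 3))
        layer = "conv3"   # 3 feature maps
        grads = model.feature_map_gradient(x, 1, layer)
        alphas = grads.mean(axis=(0, 1))
        maps = model.feature_maps(x, layer)
        eps = 1e-4
        fd_alphas = np.empty(3)
        for k in range(3):
            hi, lo = maps.copy(), maps.copy()
            hi[:, :, k] += eps
            lo[:, :, k] -= eps
            # GAP of the per-pixel gradient = uniform-shift sensitivity / Z
            z = maps.shape[0] * maps.shape[1]
            fd_alphas[k] = (model.forward_from(layer, hi)[1]
                            - model.forward_from(layer, lo)[1]) / (2 * eps * z)
        np.testing.assert_allclose(alphas, fd_alphas, atol=1e-4)

    def test_invariant_to_positive_feature_map_rescaling(self, rng):
        mask = np.zeros((28, 28), dtype=bool)
        mask[4:12, 4:12] = True
        img = rng.random((28, 28, 3))
        base = gradcam(make_region_oracle(mask, gain=2.0), img)
        scaled = gradcam(make_region_oracle(mask, gain=8.0), img)
        np.testing.assert_allclose(base.values, scaled.values, atol=1e-9)

    def test_rejected_for_ensembles_with_defining_message(self, rng):
        member = make_region_oracle(np.ones((16, 16), dtype=bool))
        ens = EnsembleClassifier([member, member])
        with pytest.raises(TypeError, match="not defined for ensembles"):
            gradcam(ens, rng.random((16, 16, 3)))


class TestVanillaGradient:
    def test_linear_logit_recovers_channel_max_weight_magnitude(
            self, linear_model, rng):
        hm = vanilla_gradient(linear_model, rng.random((12, 12, 3)), 1)
        np.testing.assert_allclose(hm.values,
                                   np.abs(linear_model.w).max(axis=-1))

    def test_zero_outside_oracle_region(self, corner_oracle, rng):
        orc, mask = corner_oracle
        hm = vanilla_gradient(orc, rng.random((64, 64, 3)), 1)
        assert hm.values[~mask].max() == 0.0
        assert hm.values[mask].min() > 0.0

    def test_matches_finite_differences_on_smooth_cnn(self, rng):
        model = SmallCnn((32, 32), (4, 8, 8), seed=3, activation="softplus",
                         pool="mean")
        x = rng.random((32, 32, 3))
        hm = vanilla_gradient(model, x, 1)
        grad = model.input_gradient(x, 1)
        eps = 1e-5
        for _ in range(10):
            i, j = rng.integers(0, 32), rng.integers(0, 32)
            c = int(np.argmax(np.abs(grad[i, j])))
            hi, lo = x.copy(), x.copy()
            hi[i, j, c] += eps
            lo[i, j, c] -= eps
            fd = (model.logits(hi[None])[0, 1]
                  - model.logits(lo[None])[0, 1]) / (2 * eps)
            assert abs(abs(fd) - hm.values[i, j]) <= 1e-3 * max(abs(fd), 1e-6)


class TestSmoothGradient:
    def test_sigma_zero_equals_vanilla_exactly(self, corner_oracle, rng):
        orc, _ = corner_oracle
        img = rng.random((64, 64, 3))
        sm = smooth_gradient(orc, img, 1, SmoothConfig(n_noisy=7, sigma=0.0))
        va = vanilla_gradient(orc, img, 1)
        np.testing.assert_array_equal(sm.values, va.values)

    def test_linear_logit_mean_within_monte_carlo_band(self, linear_model,
                                                       rng):
        img = rng.random((12, 12, 3))
        hm = smooth_gradient(linear_model, img, 1,
                             SmoothConfig(n_noisy=25, sigma=0.2, seed=0))
        # each draw is exact for a linear logit, so the mean is exact too
        np.testing.assert_allclose(hm.values,
                                   np.abs(linear_model.w).max(axis=-1),
                                   atol=1e-12)

    def test_deterministic_given_seed(self, corner_oracle, rng):
        orc, _ = corner_oracle
        img = rng.random((64, 64, 3))
        cfg = SmoothConfig(n_noisy=5, sigma=0.1, seed=8)
        a = smooth_gradient(orc, img, 1, cfg)
        b = smooth_gradient(orc, img, 1, cfg)
        np.testing.assert_array_equal(a.values, b.values)


class TestIntegratedGradient:
    def test_linear_logit_black_baseline_exact_at_any_steps(self,
                                                            linear_model,
                                                            rng):
        img = rng.random((12, 12, 3))
        for steps in (1, 7):
            hm = integrated_gradient(linear_model, img, 1,
                                     IgConfig(steps=steps))
            np.testing.assert_allclose(hm.values,
                                       (linear_model.w * img).sum(axis=-1),
                                       atol=1e-12)

    def test_image_equal_to_baseline_gives_zero_map(self, corner_oracle):
        orc, _ = corner_oracle
        img = np.full((64, 64, 3), 0.3)
        hm = integrated_gradient(orc, img, 1,
                                 IgConfig(steps=5, baseline=img.copy()))
        np.testing.assert_allclose(hm.values, 0.0, atol=1e-12)

    def test_completeness_on_smooth_cnn(self, rng):
        model = SmallCnn((32, 32), (4, 8, 8), seed=2, activation="softplus",
                         pool="mean")
        for k in ("b1", "b2", "b3", "bd"):
            model.params[k] = rng.normal(0, 0.2, size=model.params[k].shape)
        x = rng.random((32, 32, 3))
        gap300 = completeness_gap(model, x, 1, steps=300)
        gap20 = completeness_gap(model, x, 1, steps=20)
        assert gap300 <= 0.01
        assert gap300 <= gap20 + 1e-12

    def test_baseline_shape_mismatch_rejected(self, corner_oracle):
        orc, _ = corner_oracle
        with pytest.raises(ValueError):
            integrated_gradient(orc, np.zeros((64, 64, 3)), 1,
                                IgConfig(baseline=np.zeros((32, 32, 3))))


def test_all_methods_agree_on_zero_map_for_constant_logits(rng):
    """A model whose logits ignore the input must get zero saliency from
    every gradient-based technique."""
    model = LinearLogitModel(np.zeros((12, 12, 3)))
    img = rng.random((12, 12, 3))
    assert vanilla_gradient(model, img, 1).values.max() == 0.0
    assert smooth_gradient(model, img, 1,
                           SmoothConfig(n_noisy=3)).values.max() == 0.0
    assert integrated_gradient(model, img, 1).values.max() == 0.0
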