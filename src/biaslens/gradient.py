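"""Gradient-based explainers: GradCAM, vanilla, smooth and integrated
gradients.

All four differentiate the pre-softmax logit of the target class.

GradCAM weighs a convolutional layer's feature maps A^k by the global
average pool of their gradients, alpha_c^k = (1/Z) sum d y_c / d A^k,
rectifies the weighted sum, upsamples it bilinearly to image size and
normalizes by the maximum, giving a map on [0, 1].  It is defined for a
single differentiable network only — the averaged prediction of an
ensemble has no shared convolutional layer to draw maps from.

Vanilla gradients take the per-pixel magnitude (channel-max absolute
value) of d y_c / d pixel: the map says *which* pixels matter, not in
which direction.  Smooth gradients average vanilla maps over Gaussian-
noised copies of the input.  Integrated gradients accumulate the input
gradient along the straight path from a baseline (black by default) to
the image and multiply by (image - baseline); the attributions are
signed and, in the exact integral, sum to y_c(image) - y_c(baseline)
(the completeness property the Riemann approximation approaches as the
step count grows).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .contracts import DifferentiableClassifierContract
from .types import Heatmap

ENSEMBLE_GRADCAM_ERROR = "GradCAM is not defined for ensembles of models"


@dataclass
class IgConfig:
    """Integrated-gradients settings: path steps and baseline image."""

    steps: int = 50
    baseline: np.ndarray | None = None   # None -> all-black image

    def __post_init__(self) -> None:
        if self.steps < 1:
            raise ValueError("steps must be >= 1")


@dataclass
class SmoothConfig:
    """Smooth-gradients settings: noisy copies and noise scale (intensity
    units on the [0, 1] pixel range)."""

    n_noisy: int = 25
    sigma: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_noisy < 1:
            raise ValueError("n_noisy must be >= 1")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def _require_differentiable(classifier) -> None:
    from .ensemble import EnsembleClassifier

    if isinstance(classifier, EnsembleClassifier):
        raise TypeError(ENSEMBLE_GRADCAM_ERROR)
    if not isinstance(classifier, DifferentiableClassifierContract):
        raise TypeError("classifier does not satisfy the differentiable "
                        "contract")


def gradcam(classifier: DifferentiableClassifierContract, image: np.ndarray,
            class_index: int = 1, layer_id: str | None = None) -> Heatmap:
    """Class activation map from a spatial layer's gradient-weighted maps.

    ``layer_id`` defaults to the network's last spatial layer (the
    deepest convolution before the classification block).
    """
    _require_differentiable(classifier)
    image = np.asarray(image, dtype=float)
    if layer_id is None:
        layers = classifier.feature_layers()
        if not layers:
            raise ValueError("classifier exposes no spatial layers")
        layer_id = layers[-1]
    maps = classifier.feature_maps(image, layer_id)        # (h, w, K)
    grads = classifier.feature_map_gradient(image, class_index, layer_id)
    if maps.ndim != 3:
        raise ValueError(f"layer {layer_id!r} is not spatial")
    alphas = grads.mean(axis=(0, 1))                       # GAP over h*w
    cam = np.maximum(np.tensordot(maps, alphas, axes=(2, 0)), 0.0)
    cam = resize(cam, image.shape[:2], order=1, anti_aliasing=False)
    cam = np.maximum(cam, 0.0)     # bilinear resize cannot go negative, but be safe
    peak = cam.max()
    if peak > 0:
        cam = cam / peak
    return Heatmap(values=cam, technique="gradcam", scale_convention="unit",
                   params={"layer_id": layer_id, "class_index": class_index,
                           "score": "logit"})


def vanilla_gradient(classifier: DifferentiableClassifierContract,
                     image: np.ndarray, class_index: int = 1) -> Heatmap:
    """Channel-max absolute input gradient of the class logit."""
    _require_differentiable(classifier)
    image = np.asarray(image, dtype=float)
    grad = classifier.input_gradient(image, class_index)
    values = np.abs(grad).max(axis=-1)
    return Heatmap(values=values, technique="vanilla_gradient",
                   scale_convention="magnitude",
                   params={"class_index": class_index, "score": "logit"})


def smooth_gradient(classifier: DifferentiableClassifierContract,
                    image: np.ndarray, class_index: int = 1,
                    config: SmoothConfig | None = None) -> Heatmap:
    """Average of vanilla maps over Gaussian-noised copies of the input.

    Noise is applied in intensity space and the noisy images are *not*
    re-clipped, so ``sigma = 0`` reduces exactly to the vanilla map.
    """
    _require_differentiable(classifier)
    config = config or SmoothConfig()
    image = np.asarray(image, dtype=float)
    rng = np.random.default_rng(config.seed)
    if config.sigma == 0:   # degenerate: every draw is the vanilla map
        values = np.abs(classifier.input_gradient(image,
                                                  class_index)).max(axis=-1)
    else:
        acc = np.zeros(image.shape[:2])
        for _ in range(config.n_noisy):
            noisy = image + rng.normal(0.0, config.sigma, size=image.shape)
            grad = classifier.input_gradient(noisy, class_index)
            acc += np.abs(grad).max(axis=-1)
        values = acc / config.n_noisy
    return Heatmap(values=values, technique="smooth_gradient",
                   scale_convention="magnitude",
                   params={"n_noisy": config.n_noisy, "sigma": config.sigma,
                           "seed": config.seed, "class_index": class_index,
                           "score": "logit"})


def integrated_gradient(classifier: DifferentiableClassifierContract,
                        image: np.ndarray, class_index: int = 1,
                        config: IgConfig | None = None) -> Heatmap:
    """Midpoint Riemann sum of input gradients along the baseline path.

    Attribution per pixel is the path-averaged gradient times
    (image - baseline), summed over channels; the map is signed.
    """
    _require_differentiable(classifier)
    config = config or IgConfig()
    image = np.asarray(image, dtype=float)
    baseline = (np.zeros_like(image) if config.baseline is None
                else np.asarray(config.baseline, dtype=float))
    if baseline.shape != image.shape:
        raise ValueError("baseline must have the same shape as the image")
    diff = image - baseline
    acc = np.zeros_like(image)
    for k in range(config.steps):
        t = (k + 0.5) / config.steps
        acc += classifier.input_gradient(baseline + t * diff, class_index)
    attribution = (acc / config.steps) * diff
    return Heatmap(values=attribution.sum(axis=-1),
                   technique="integrated_gradient",
                   scale_convention="symmetric_signed",
                   params={"steps": config.steps, "class_index": class_index,
                           "baseline": "black" if config.baseline is None
                           else "custom", "score": "logit"})


def completeness_gap(classifier: DifferentiableClassifierContract,
                     image: np.ndarray, class_index: int = 1,
                     steps: int = 50,
                     baseline: np.ndarray | None = None) -> float:
    """Relative gap between the attribution sum and the logit difference.

    Diagnostic for the integrated-gradients step count: the exact path
    integral satisfies sum(attribution) = y_c(image) - y_c(baseline).
    """
    image = np.asarray(image, dtype=float)
    base = np.zeros_like(image) if baseline is None else baseline
    hm = integrated_gradient(classifier, image, class_index,
                             IgConfig(steps=steps, baseline=baseline))
    delta = (classifier.logits(image[None])[0, class_index]
             - classifier.logits(base[None])[0, class_index])
    if delta == 0:
        return float(abs(hm.values.sum()))
    return float(abs(hm.values.sum() - delta) / abs(delta))
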