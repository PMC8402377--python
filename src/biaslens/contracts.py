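"""Classifier contracts, analytic region oracles, and split metrics.

Two contracts are defined.  A *black-box* classifier only maps image
batches to softmax rows; that is all the perturbation-based explainers
(LIME, Squaregrid, RISE) require.  A *differentiable* classifier
additionally exposes the pre-softmax class score (``logits``), its
gradient with respect to input pixels, and named internal spatial
feature maps with their gradients — the surface the gradient-based
explainers (GradCAM, vanilla/smooth/integrated gradients) need.

All gradient-based attribution in this package differentiates the
pre-softmax logit of the target class; softmax probabilities are used
only as perturbation weights in RISE and LIME.

The *region oracle* is a fully analytic differentiable classifier whose
class-1 logit is a gain times the channel-weighted mean intensity over a
fixed pixel region.  Because its gradients and feature maps have closed
forms, it serves as ground truth for every explainer: a correct saliency
method must light up the oracle's region and nothing else.
"""
from __future__ import annotations

import abc
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import f1_score, roc_auc_score


class ClassifierContract(abc.ABC):
    """Batch of images -> batch of softmax probability rows."""

    n_classes: int = 2

    @abc.abstractmethod
    def predict(self, images: np.ndarray) -> np.ndarray:
        """``(n, H, W, C)`` images -> ``(n, n_classes)`` probabilities.

        Rows are nonnegative and sum to 1; batch order is preserved and
        the function is pure (same input, same output).
        """

    def predict_one(self, image: np.ndarray) -> np.ndarray:
        return self.predict(image[None])[0]


class DifferentiableClassifierContract(ClassifierContract):
    """Adds logits, input gradients and named internal feature maps."""

    @abc.abstractmethod
    def logits(self, images: np.ndarray) -> np.ndarray:
        """``(n, H, W, C)`` -> ``(n, n_classes)`` pre-softmax scores."""

    @abc.abstractmethod
    def input_gradient(self, image: np.ndarray, class_index: int) -> np.ndarray:
        """d logit_c / d pixel, shaped like ``image``, finite everywhere."""

    @abc.abstractmethod
    def feature_layers(self) -> list[str]:
        """Identifiers of layers exposing spatial feature maps."""

    @abc.abstractmethod
    def feature_maps(self, image: np.ndarray, layer_id: str) -> np.ndarray:
        """``(h, w, K)`` activations of the named layer."""

    @abc.abstractmethod
    def feature_map_gradient(self, image: np.ndarray, class_index: int,
                             layer_id: str) -> np.ndarray:
        """d logit_c / d activation, same ``(h, w, K)`` shape."""


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - np.max(z, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


# ---------------------------------------------------------------------------
# region oracle


class RegionOracle(DifferentiableClassifierContract):
    """Analytic two-class model keyed on one pixel region.

    The class-1 logit is ``gain * mean over the region of (w . pixel)``
    with channel weights ``w``; the class-0 logit is 0.  Probabilities are
    the softmax of the two logits.  The input gradient is constant inside
    the region and exactly zero outside — perturbing any pixel outside
    the region cannot change the prediction.

    One synthetic spatial layer (``"pooled"``) is exposed: the channel-
    weighted image, restricted to the region, average-pooled onto a
    ``pool_size`` grid.  Its gradient has the closed form
    ``gain * |region ∩ cell| / |region|`` per cell, which makes GradCAM
    verifiable analytically.
    """

    def __init__(self, region_mask: np.ndarray,
                 channel_weights=(1 / 3, 1 / 3, 1 / 3),
                 gain: float = 6.0, pool_size: int = 14):
        region_mask = np.asarray(region_mask, dtype=bool)
        if not region_mask.any():
            raise ValueError("region oracle requires a nonempty mask")
        self.mask = region_mask
        self.w = np.asarray(channel_weights, dtype=float)
        self.gain = float(gain)
        self.pool_size = int(pool_size)
        self.n_classes = 2
        self._n_region = int(region_mask.sum())

    # -- black-box surface
    def logits(self, images: np.ndarray) -> np.ndarray:
        images = np.asarray(images, dtype=float)
        weighted = np.tensordot(images, self.w, axes=([-1], [0]))  # (n, H, W)
        z1 = self.gain * weighted[:, self.mask].mean(axis=1)
        return np.stack([np.zeros_like(z1), z1], axis=1)

    def predict(self, images: np.ndarray) -> np.ndarray:
        return softmax(self.logits(images), axis=1)

    # -- differentiable surface
    def input_gradient(self, image: np.ndarray, class_index: int) -> np.ndarray:
        grad = np.zeros_like(np.asarray(image, dtype=float))
        if class_index == 1:
            grad[self.mask] = self.gain * self.w / self._n_region
        return grad

    def feature_layers(self) -> list[str]:
        return ["pooled"]

    def _cells(self, h: int, w: int):
        s = self.pool_size
        ys = np.linspace(0, h, s + 1).astype(int)
        xs = np.linspace(0, w, s + 1).astype(int)
        return ys, xs

    def feature_maps(self, image: np.ndarray, layer_id: str) -> np.ndarray:
        self._check_layer(layer_id)
        image = np.asarray(image, dtype=float)
        weighted = np.tensordot(image, self.w, axes=([-1], [0])) * self.mask
        h, w = weighted.shape
        ys, xs = self._cells(h, w)
        s = self.pool_size
        maps = np.zeros((s, s, 1))
        for i in range(s):
            for j in range(s):
                cell = weighted[ys[i]:ys[i + 1], xs[j]:xs[j + 1]]
                maps[i, j, 0] = cell.mean() if cell.size else 0.0
        return maps

    def feature_map_gradient(self, image: np.ndarray, class_index: int,
                             layer_id: str) -> np.ndarray:
        self._check_layer(layer_id)
        h, w = self.mask.shape
        ys, xs = self._cells(h, w)
        s = self.pool_size
        grad = np.zeros((s, s, 1))
        if class_index == 1:
            for i in range(s):
                for j in range(s):
                    overlap = self.mask[ys[i]:ys[i + 1], xs[j]:xs[j + 1]].sum()
                    grad[i, j, 0] = self.gain * overlap / self._n_region
        return grad

    def _check_layer(self, layer_id: str) -> None:
        if layer_id != "pooled":
            raise ValueError(f"region oracle has no layer {layer_id!r}")


def make_region_oracle(region_mask: np.ndarray,
                       channel_weights=(1 / 3, 1 / 3, 1 / 3),
                       gain: float = 6.0) -> RegionOracle:
    """Build an analytic classifier keyed on ``region_mask``.

    The defaults (channel-mean intensity, gain 6) keep the class-1 logit
    within the responsive part of the softmax for images in [0, 1], so
    occluding part of the region visibly moves the probability — the
    regime perturbation-based explainers rely on.  See
    :class:`RegionOracle`.
    """
    return RegionOracle(region_mask, channel_weights, gain)


class ConstantClassifier(ClassifierContract):
    """Always outputs the same probability row; a degenerate test model."""

    def __init__(self, probabilities=(0.5, 0.5)):
        p = np.asarray(probabilities, dtype=float)
        self.p = p / p.sum()
        self.n_classes = len(p)

    def predict(self, images: np.ndarray) -> np.ndarray:
        n = np.asarray(images).shape[0]
        return np.tile(self.p, (n, 1))


# ---------------------------------------------------------------------------
# checkpointing & metrics


@dataclass
class CheckpointPolicy:
    """Save weights whenever monitored validation accuracy crosses a bar.

    The comparison is strict (``acc > threshold``); every saved entry is
    ``(epoch, metric value, weights handle)``.
    """

    threshold: float = 0.80
    metric: str = "validation accuracy"
    saved: list[tuple[int, float, object]] = field(default_factory=list)

    def consider(self, epoch: int, value: float, weights: object) -> bool:
        if value > self.threshold:
            self.saved.append((epoch, float(value), weights))
            return True
        return False


@dataclass
class SplitMetrics:
    accuracy: float
    f1: float
    auc: float | None

    def as_dict(self) -> dict:
        return {"accuracy": self.accuracy, "f1": self.f1, "auc": self.auc}


def evaluate(classifier: ClassifierContract, images: np.ndarray,
             labels: np.ndarray) -> SplitMetrics:
    """Accuracy / binary F1 (positive class) / AUC of a classifier on a split.

    AUC is the probability that a random class-1 image outranks a random
    class-0 image by class-1 probability, ties counting one half; on a
    single-class split it is reported as ``None`` and the rest computed.
    """
    labels = np.asarray(labels)
    if len(labels) == 0:
        raise ValueError("cannot evaluate on an empty split")
    probs = classifier.predict(np.asarray(images))
    return metrics_from_probabilities(probs, labels)


def metrics_from_probabilities(probs: np.ndarray,
                               labels: np.ndarray) -> SplitMetrics:
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    pred = probs.argmax(axis=1)
    acc = float((pred == labels).mean())
    f1 = float(f1_score(labels, pred, pos_label=1, zero_division=0.0))
    if len(np.unique(labels)) < 2:
        auc = None
    else:
        auc = float(roc_auc_score(labels, probs[:, 1]))
    return SplitMetrics(accuracy=acc, f1=f1, auc=auc)
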