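"""Perturbation-based explainers: LIME over SLIC superpixels, Squaregrid,
and RISE.

All three treat the classifier as a black box: they occlude parts of the
input, watch the softmax probability of the target class move, and turn
those movements into a per-pixel heatmap.

LIME segments the image into superpixels (SLIC k-means in CIELAB+xy,
``nslic = 15`` by default), draws random on/off patterns over the
segments, replaces "off" segments with the image mean color, and fits a
distance-kernel-weighted ridge regression of the class probability on
the binary pattern; each pixel inherits its segment's coefficient.

Squaregrid removes the segmentation heuristic: it runs the same surrogate
fit over centered square grids at powers-of-two resolutions (2x2, 4x4,
...) and sums the per-level coefficient maps pixelwise.

RISE probes with N random soft masks M_i (low-resolution Bernoulli(p1)
grids, bilinearly upsampled and randomly shifted) and averages
``H = 1/(N p1) * sum_i f(I ⊙ M_i) M_i`` where f is the class probability
and ⊙ is per-pixel multiplication.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.segmentation import slic as _skimage_slic
from sklearn.linear_model import LinearRegression, Ridge

from .contracts import ClassifierContract
from .types import Heatmap

DEFAULT_NSLIC = 15
DEFAULT_LIME_SAMPLES = 1000
DEFAULT_SQUAREGRID_LEVELS = (1, 2, 3, 4, 5)
#: Width of the exponential cosine-distance kernel weighting LIME samples.
LIME_KERNEL_WIDTH = 0.25


@dataclass
class Segmentation:
    """A labelling of every pixel into one of ``n_segments`` regions."""

    labels: np.ndarray          # (H, W) int, values 0..n_segments-1
    n_segments: int
    degenerate: bool = False    # single segment from a constant image

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        present = np.unique(self.labels)
        if present.min() < 0 or present.max() >= self.n_segments:
            raise ValueError("segment labels out of range")
        if len(present) != self.n_segments:
            raise ValueError("every segment must be nonempty")


@dataclass
class RiseConfig:
    """RISE sampling parameters: N masks from an s x s Bernoulli(p1) grid."""

    n_masks: int = 4000
    cell_grid: int = 7
    keep_prob: float = 0.5
    seed: int = 0
    batch_size: int = 100

    def __post_init__(self) -> None:
        if self.n_masks < 1:
            raise ValueError("n_masks must be >= 1")
        if self.cell_grid < 2:
            raise ValueError("cell_grid must be >= 2")
        # keep_prob = 1 is the degenerate no-occlusion limit (all-ones masks)
        if not 0.0 < self.keep_prob <= 1.0:
            raise ValueError("keep_prob must lie in (0, 1]")


# ---------------------------------------------------------------------------
# segmentation


def slic_segment(pixels: np.ndarray, nslic: int = DEFAULT_NSLIC) -> Segmentation:
    """SLIC superpixels: k-means in CIELAB color + pixel coordinates.

    ``nslic`` is the *requested* segment count; the achieved count may
    differ.  A constant image cannot be segmented and yields a single
    segment flagged as degenerate.
    """
    if nslic < 2:
        raise ValueError("nslic must be >= 2")
    pixels = np.asarray(pixels, dtype=float)
    if np.ptp(pixels) == 0:
        return Segmentation(labels=np.zeros(pixels.shape[:2], dtype=int),
                            n_segments=1, degenerate=True)
    labels = _skimage_slic(pixels, n_segments=nslic, start_label=0,
                           channel_axis=-1)
    # compact to consecutive labels so downstream code can index by label
    _, labels = np.unique(labels, return_inverse=True)
    labels = labels.reshape(pixels.shape[:2])
    return Segmentation(labels=labels, n_segments=int(labels.max()) + 1)


def square_grid_segmentation(shape: tuple[int, int], level: int) -> Segmentation:
    """Centered 2^level x 2^level grid; residual offsets fall at the edges.

    Interior cells all have size ``floor(H/2^level) x floor(W/2^level)``;
    pixels in the residual border are absorbed by the nearest edge cell.
    """
    h, w = shape
    n = 2 ** level
    ch, cw = h // n, w // n
    if ch < 1 or cw < 1:
        raise ValueError(f"grid level {level} yields sub-pixel cells "
                         f"for shape {shape}")
    top, left = (h - ch * n) // 2, (w - cw * n) // 2
    rows = np.clip((np.arange(h) - top) // ch, 0, n - 1)
    cols = np.clip((np.arange(w) - left) // cw, 0, n - 1)
    labels = rows[:, None] * n + cols[None, :]
    return Segmentation(labels=labels.astype(int), n_segments=n * n)


# ---------------------------------------------------------------------------
# LIME


def _kernel_weights(z: np.ndarray) -> np.ndarray:
    """Exponential kernel on the cosine distance to the all-on vector."""
    n = z.shape[1]
    norms = np.sqrt(z.sum(axis=1) * n)
    cos = np.divide(z.sum(axis=1), norms, out=np.zeros(len(z)),
                    where=norms > 0)
    d = 1.0 - cos
    return np.exp(-(d ** 2) / LIME_KERNEL_WIDTH ** 2)


def _surrogate_fit(z: np.ndarray, probs: np.ndarray,
                   ridge_alpha: float) -> np.ndarray:
    weights = _kernel_weights(z)
    if ridge_alpha <= 0:
        model = LinearRegression()
    else:
        model = Ridge(alpha=ridge_alpha)
    model.fit(z, probs, sample_weight=weights)
    return np.asarray(model.coef_, dtype=float)


def lime_explain(classifier: ClassifierContract, image: np.ndarray,
                 segmentation: Segmentation, class_index: int = 1,
                 n_samples: int = DEFAULT_LIME_SAMPLES, seed: int = 0,
                 ridge_alpha: float = 1.0, exhaustive: bool = False,
                 batch_size: int = 64) -> Heatmap:
    """Fit a local linear surrogate over superpixel on/off perturbations.

    "Off" segments are replaced by the image mean color (a black fill
    would itself plant a dark artifact on CT-like images).  With
    ``exhaustive=True`` all 2^n on/off patterns are used — combined with
    ``ridge_alpha=0`` this reduces to exact ordinary least squares, the
    mode the oracle tests exercise.
    """
    image = np.asarray(image, dtype=float)
    labels, n_seg = segmentation.labels, segmentation.n_segments
    rng = np.random.default_rng(seed)
    if exhaustive:
        if n_seg > 16:
            raise ValueError("exhaustive perturbation limited to <= 16 segments")
        z = ((np.arange(2 ** n_seg)[:, None] >> np.arange(n_seg)) & 1
             ).astype(float)
    else:
        if n_samples < n_seg:
            raise ValueError("n_samples must be >= n_segments")
        z = rng.integers(0, 2, size=(n_samples, n_seg)).astype(float)
        z = np.vstack([z, np.ones(n_seg)])

    baseline = image.reshape(-1, image.shape[-1]).mean(axis=0)
    probs = np.empty(len(z))
    for start in range(0, len(z), batch_size):
        zz = z[start:start + batch_size]
        on = zz[:, labels]                       # (b, H, W)
        batch = (image[None] * on[..., None]
                 + baseline * (1.0 - on[..., None]))
        try:
            p = classifier.predict(batch)
        except Exception as exc:
            raise RuntimeError(
                f"classifier failed on perturbation batch starting at "
                f"sample {start}: {exc}") from exc
        probs[start:start + batch_size] = p[:, class_index]

    coef = _surrogate_fit(z, probs, ridge_alpha)
    return Heatmap(values=coef[labels], technique="lime",
                   scale_convention="symmetric_signed",
                   params={"n_segments": n_seg, "n_samples": len(z),
                           "ridge_alpha": ridge_alpha, "seed": seed,
                           "class_index": class_index,
                           "exhaustive": exhaustive})


def squaregrid_explain(classifier: ClassifierContract, image: np.ndarray,
                       class_index: int = 1,
                       levels=DEFAULT_SQUAREGRID_LEVELS,
                       n_samples_per_level: int = 256, seed: int = 0,
                       ridge_alpha: float = 1.0) -> Heatmap:
    """Sum of LIME surrogate maps over centered powers-of-two grids.

    Per-level contributions are summed without normalization; levels
    whose cells would fall below one pixel are skipped with a warning.
    """
    levels = tuple(levels)
    if not levels or any(lv < 1 for lv in levels):
        raise ValueError("levels must be a nonempty collection of ints >= 1")
    image = np.asarray(image, dtype=float)
    total = np.zeros(image.shape[:2])
    used = []
    for lv in levels:
        try:
            seg = square_grid_segmentation(image.shape[:2], lv)
        except ValueError:
            warnings.warn(f"squaregrid level {lv} skipped: cell below 1 px")
            continue
        n = max(n_samples_per_level, seg.n_segments)
        hm = lime_explain(classifier, image, seg, class_index=class_index,
                          n_samples=n,
                          seed=int(np.random.default_rng([seed, lv])
                                   .integers(2 ** 31)),
                          ridge_alpha=ridge_alpha)
        total += hm.values
        used.append(lv)
    return Heatmap(values=total, technique="squaregrid",
                   scale_convention="symmetric_signed",
                   params={"levels": used, "seed": seed,
                           "n_samples_per_level": n_samples_per_level,
                           "class_index": class_index,
                           "ridge_alpha": ridge_alpha})


# ---------------------------------------------------------------------------
# RISE


def _bilinear_matrix(n_out: int, n_in: int) -> np.ndarray:
    """(n_out, n_in) interpolation weights; source sampled at cell centers."""
    src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    i0 = np.clip(np.floor(src).astype(int), 0, n_in - 1)
    i1 = np.clip(i0 + 1, 0, n_in - 1)
    frac = np.clip(src - np.floor(src), 0.0, 1.0)
    mat = np.zeros((n_out, n_in), dtype=np.float32)
    mat[np.arange(n_out), i0] += 1.0 - frac
    mat[np.arange(n_out), i1] += frac
    return mat


def _mask_chunks(config: RiseConfig, out_size: tuple[int, int]):
    """Yield successive ``(b, H, W)`` float mask stacks, deterministically."""
    h, w = out_size
    s = config.cell_grid
    ch, cw = int(np.ceil(h / s)), int(np.ceil(w / s))
    big_h, big_w = (s + 1) * ch, (s + 1) * cw
    row_mat = _bilinear_matrix(big_h, s)
    col_mat = _bilinear_matrix(big_w, s)
    # draw all randomness up front so results are invariant to batch size
    rng = np.random.default_rng(config.seed)
    all_grids = (rng.random((config.n_masks, s, s))
                 < config.keep_prob).astype(np.float32)
    all_offs = rng.integers(0, (ch, cw), size=(config.n_masks, 2))
    for start in range(0, config.n_masks, config.batch_size):
        grids = all_grids[start:start + config.batch_size]
        offs = all_offs[start:start + config.batch_size]
        b = len(grids)
        big = np.einsum("ph,bhq->bpq", row_mat,
                        np.einsum("bhw,qw->bhq", grids, col_mat))
        rows = offs[:, 0, None] + np.arange(h)
        cols = offs[:, 1, None] + np.arange(w)
        yield big[np.arange(b)[:, None, None], rows[:, :, None],
                  cols[:, None, :]]


def rise_masks(config: RiseConfig, out_size: tuple[int, int]) -> np.ndarray:
    """The full ``(N, H, W)`` stack of RISE occlusion masks in [0, 1].

    Each mask starts as an ``s x s`` Bernoulli(keep_prob) grid, is
    bilinearly upsampled to a canvas one cell larger than ``out_size``,
    and cropped at a uniform random offset within one cell, so cell
    boundaries do not align across masks.
    """
    return np.concatenate(list(_mask_chunks(config, out_size)), axis=0)


def rise_explain(classifier: ClassifierContract, image: np.ndarray,
                 class_index: int = 1,
                 config: RiseConfig | None = None) -> Heatmap:
    """Monte-Carlo RISE heatmap ``1/(N p1) * sum_i f(I ⊙ M_i) M_i``."""
    config = config or RiseConfig()
    image = np.asarray(image, dtype=np.float32)
    h, w = image.shape[:2]
    acc = np.zeros((h, w))
    done = 0
    for masks in _mask_chunks(config, (h, w)):
        batch = image[None] * masks[..., None]
        try:
            p = classifier.predict(batch)[:, class_index]
        except Exception as exc:
            raise RuntimeError(
                f"classifier failed on mask batch starting at index "
                f"{done}: {exc}") from exc
        acc += np.tensordot(p, masks, axes=(0, 0))
        done += len(masks)
    values = acc / (config.n_masks * config.keep_prob)
    return Heatmap(values=values, technique="rise",
                   scale_convention="min_max",
                   params={"n_masks": config.n_masks,
                           "cell_grid": config.cell_grid,
                           "keep_prob": config.keep_prob,
                           "seed": config.seed,
                           "class_index": class_index})
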