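"""Synthetic CT-like benchmark with planted, class-correlated artifacts.

Real chest-CT classification corpora scraped from publications carry
spurious content — annotation letters burned into the film, colored
markings, off-gray hues, a round reconstruction frame, the scanner bed
visible at the bottom — and that content is unevenly distributed across
classes.  A classifier can therefore score well by reading the artifacts
instead of the anatomy.  This module generates images that reproduce that
*structure* (not the anatomy): a dark background, a light elliptical body
with two darker lungs, a bright lesion blob in every positive image, and
each artifact planted with class-conditional probability.  Every planted
feature's pixel mask is recorded, which is what makes attribution methods
testable: we know exactly where the shortcut lives.

The default composition mirrors a 746-image two-class corpus split
train/val/test = 425/118/203 with per-split class counts
(234, 191) / (58, 60) / (105, 98).
"""
from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image

#: Plantable artifact kinds; ``lesion`` is not plantable — it is the genuine
#: class signal, always present in class 1 and never in class 0.
ARTIFACT_KINDS = (
    "letter",
    "colored_marking",
    "hue_tint",
    "round_frame",
    "support_structure",
)
LESION = "lesion"
SPLITS = ("train", "val", "test")

_DEFAULT_SPLIT_SIZES = {"train": (234, 191), "val": (58, 60), "test": (105, 98)}
_DEFAULT_RATES = {
    "letter": (0.05, 0.60),
    "colored_marking": (0.00, 0.25),
    "hue_tint": (0.02, 0.10),
    "round_frame": (0.50, 0.50),
    "support_structure": (0.30, 0.70),
}


@dataclass
class DatasetSpec:
    """Composition, geometry and artifact statistics of a synthetic dataset.

    ``artifact_rates`` maps artifact kind to ``(rate_class0, rate_class1)``
    planting probabilities.  ``contrast_jitter`` is the half-width of the
    multiplicative intensity factor drawn per image (``1 ± jitter``),
    emulating heterogeneous acquisition contrast.  ``aspect_jitter`` > 0
    renders each image at a randomly stretched width before resizing back,
    emulating heterogeneous aspect ratios; off by default.
    """

    split_sizes: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(_DEFAULT_SPLIT_SIZES))
    image_size: tuple[int, int] = (224, 224)
    artifact_rates: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_RATES))
    contrast_jitter: float = 0.15
    aspect_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for split, (n0, n1) in self.split_sizes.items():
            if n0 < 0 or n1 < 0:
                raise ValueError(f"negative count in split {split!r}")
        h, w = self.image_size
        if h < 32 or w < 32:
            raise ValueError("image size must be at least 32x32")
        for kind, (r0, r1) in self.artifact_rates.items():
            if kind not in ARTIFACT_KINDS:
                raise ValueError(f"unknown artifact kind {kind!r}")
            if not (0.0 <= r0 <= 1.0 and 0.0 <= r1 <= 1.0):
                raise ValueError(f"rates for {kind!r} must lie in [0, 1]")
        if self.contrast_jitter < 0:
            raise ValueError("contrast_jitter must be nonnegative")

    @property
    def n_images(self) -> int:
        return sum(n0 + n1 for n0, n1 in self.split_sizes.values())

    def to_json(self, path: str | pathlib.Path) -> None:
        payload = {
            "split_sizes": {k: list(v) for k, v in self.split_sizes.items()},
            "image_size": list(self.image_size),
            "artifact_rates": {k: list(v) for k, v in self.artifact_rates.items()},
            "contrast_jitter": self.contrast_jitter,
            "aspect_jitter": self.aspect_jitter,
            "seed": self.seed,
        }
        pathlib.Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | pathlib.Path) -> "DatasetSpec":
        payload = json.loads(pathlib.Path(path).read_text())
        return cls(
            split_sizes={k: tuple(v) for k, v in payload["split_sizes"].items()},
            image_size=tuple(payload["image_size"]),
            artifact_rates={k: tuple(v) for k, v in payload["artifact_rates"].items()},
            contrast_jitter=payload["contrast_jitter"],
            aspect_jitter=payload.get("aspect_jitter", 0.0),
            seed=payload["seed"],
        )


@dataclass
class ScanImage:
    """One synthetic scan: RGB pixels in [0, 1] plus per-artifact masks."""

    pixels: np.ndarray          # (H, W, 3) float in [0, 1]
    label: int                  # 0 NonCOVID-like, 1 COVID-like
    split: str
    artifact_masks: dict[str, np.ndarray]   # kind -> (H, W) bool
    image_id: str

    def planted(self, kind: str) -> bool:
        mask = self.artifact_masks.get(kind)
        return mask is not None and bool(mask.any())


class DatasetManifest:
    """Tabular index of a written dataset: one row per image.

    Columns: ``image_id, path, label, split`` plus one 0/1 flag column per
    artifact kind (including ``lesion``).
    """

    def __init__(self, frame: pd.DataFrame, root: pathlib.Path | None = None):
        self.frame = frame
        self.root = pathlib.Path(root) if root is not None else None

    def __len__(self) -> int:
        return len(self.frame)

    @classmethod
    def read_csv(cls, path: str | pathlib.Path) -> "DatasetManifest":
        path = pathlib.Path(path)
        return cls(pd.read_csv(path), root=path.parent)

    def write_csv(self, path: str | pathlib.Path) -> None:
        self.frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# rendering


def _ellipse(yy, xx, cy, cx, ry, rx):
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _glyph_mask(h: int, w: int, top: int, left: int, height: int,
                stroke: int, shape: int) -> np.ndarray:
    """A crude letter-like glyph built from 2-3 bright bars."""
    m = np.zeros((h, w), dtype=bool)
    bar_w = max(1, int(round(height * 0.7)))
    v0, v1 = top, min(h, top + height)
    h0, h1 = left, min(w, left + stroke)
    m[v0:v1, h0:h1] = True                      # vertical stroke
    if shape == 0:      # "L"
        m[max(0, v1 - stroke):v1, left:min(w, left + bar_w)] = True
    elif shape == 1:    # "T"
        m[v0:min(h, v0 + stroke), left:min(w, left + bar_w)] = True
    else:               # "H"-ish: second vertical + crossbar
        h2 = min(w, left + bar_w)
        m[v0:v1, max(0, h2 - stroke):h2] = True
        mid = (v0 + v1) // 2
        m[mid:min(h, mid + stroke), left:h2] = True
    return m


def render_scan(label: int, artifact_draw: dict[str, bool],
                rng: np.random.Generator, spec: DatasetSpec,
                split: str = "train", image_id: str = "img") -> ScanImage:
    """Render one scan with the requested artifacts and record their masks.

    Artifact masks are empty exactly when the artifact was not requested;
    the ``letter`` and ``colored_marking`` masks never overlap (they are
    placed in distinct corners), while frame/support/hue masks may overlap
    anything, as on real scans.
    """
    for kind in artifact_draw:
        if kind not in ARTIFACT_KINDS:
            raise ValueError(f"unknown artifact kind {kind!r}; "
                             f"expected one of {ARTIFACT_KINDS}")
    h, w = spec.image_size
    render_w = w
    if spec.aspect_jitter > 0:
        stretch = 1.0 + rng.uniform(-spec.aspect_jitter, spec.aspect_jitter)
        render_w = max(32, int(round(w * stretch)))
    hh, ww = h, render_w
    yy, xx = np.mgrid[0:hh, 0:ww].astype(float)

    gray = np.full((hh, ww), 0.04)
    gray += 0.015 * rng.standard_normal((hh, ww))

    body = _ellipse(yy, xx, 0.52 * hh, 0.50 * ww, 0.40 * hh, 0.38 * ww)
    gray[body] = 0.55 + 0.04 * rng.standard_normal(int(body.sum()))

    lungs = (_ellipse(yy, xx, 0.50 * hh, 0.34 * ww, 0.27 * hh, 0.14 * ww)
             | _ellipse(yy, xx, 0.50 * hh, 0.66 * ww, 0.27 * hh, 0.14 * ww))
    gray[lungs] = 0.18 + 0.03 * rng.standard_normal(int(lungs.sum()))

    img = np.repeat(gray[:, :, None], 3, axis=2)
    masks: dict[str, np.ndarray] = {}

    # genuine signal: bright ground-glass-like blob in one lung, class 1 only
    lesion = np.zeros((hh, ww), dtype=bool)
    if label == 1:
        side = 0.34 if rng.random() < 0.5 else 0.66
        cy = hh * (0.50 + rng.uniform(-0.12, 0.12))
        cx = ww * (side + rng.uniform(-0.04, 0.04))
        r = 0.05 * min(hh, ww) * (1.0 + rng.uniform(-0.2, 0.2))
        lesion = (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2
        img[lesion] = 0.85
    masks[LESION] = lesion

    corners = [(0.04, 0.04), (0.04, 0.80), (0.84, 0.04), (0.84, 0.80)]
    order = rng.permutation(4)

    letter = np.zeros((hh, ww), dtype=bool)
    if artifact_draw.get("letter", False):
        cy, cx = corners[order[0]]
        n_glyphs = int(rng.integers(1, 4))
        height = max(6, int(round(0.07 * hh)))
        stroke = max(2, int(round(0.012 * hh)))
        left = int(cx * ww)
        for g in range(n_glyphs):
            letter |= _glyph_mask(hh, ww, int(cy * hh), left, height,
                                  stroke, int(rng.integers(0, 3)))
            left += int(height * 0.9)
        img[letter] = 0.95
    masks["letter"] = letter

    marking = np.zeros((hh, ww), dtype=bool)
    if artifact_draw.get("colored_marking", False):
        cy, cx = corners[order[1]]    # distinct corner from the letter
        r = 0.035 * min(hh, ww)
        marking = ((yy - (cy * hh + r)) ** 2 + (xx - (cx * ww + r)) ** 2
                   <= r ** 2)
        img[marking] = (0.90, 0.10, 0.10)
    masks["colored_marking"] = marking

    frame = np.zeros((hh, ww), dtype=bool)
    if artifact_draw.get("round_frame", False):
        rr = 0.46 * min(hh, ww)
        dist = np.sqrt((yy - 0.52 * hh) ** 2 + (xx - 0.50 * ww) ** 2)
        frame = np.abs(dist - rr) <= max(1.0, 0.006 * min(hh, ww))
        img[frame] = 0.80
    masks["round_frame"] = frame

    support = np.zeros((hh, ww), dtype=bool)
    if artifact_draw.get("support_structure", False):
        top = int(0.93 * hh)
        thick = max(2, int(0.022 * hh))
        support[top:top + thick, int(0.12 * ww):int(0.88 * ww)] = True
        img[support] = 0.50
    masks["support_structure"] = support

    tint = np.zeros((hh, ww), dtype=bool)
    if artifact_draw.get("hue_tint", False):
        # global shift off gray: warm or cold cast over the whole frame
        warm = rng.random() < 0.5
        factors = (1.10, 1.00, 0.88) if warm else (0.88, 1.00, 1.10)
        img *= np.asarray(factors)
        tint = np.ones((hh, ww), dtype=bool)
    masks["hue_tint"] = tint

    factor = 1.0 + rng.uniform(-spec.contrast_jitter, spec.contrast_jitter)
    img = np.clip(img * factor, 0.0, 1.0)

    if render_w != w:
        from skimage.transform import resize
        img = np.clip(resize(img, (h, w, 3), order=1, anti_aliasing=False), 0, 1)
        masks = {k: resize(m.astype(float), (h, w), order=0,
                           anti_aliasing=False).astype(bool)
                 for k, m in masks.items()}

    return ScanImage(pixels=img, label=int(label), split=split,
                     artifact_masks=masks, image_id=image_id)


def generate_dataset(spec: DatasetSpec) -> list[ScanImage]:
    """Generate the full dataset described by ``spec``.

    Counts are exact (not sampled); artifact planting is independent
    Bernoulli at the class-conditional rate.  Each image uses an RNG
    substream keyed by ``(spec.seed, image_index)`` so the result is
    deterministic and order-independent.
    """
    spec.validate()
    images: list[ScanImage] = []
    index = 0
    for split, (n0, n1) in spec.split_sizes.items():
        for label, n in ((0, n0), (1, n1)):
            for j in range(n):
                rng = np.random.default_rng([spec.seed, index])
                draw = {kind: bool(rng.random() < rates[label])
                        for kind, rates in spec.artifact_rates.items()}
                image_id = f"{split}_{label}_{j:04d}"
                images.append(render_scan(label, draw, rng, spec,
                                          split=split, image_id=image_id))
                index += 1
    return images


# ---------------------------------------------------------------------------
# persistence


def write_dataset(images: list[ScanImage],
                  directory: str | pathlib.Path) -> DatasetManifest:
    """Write images as 8-bit RGB PNGs under split subdirectories.

    Nonempty artifact masks go to ``masks/`` as 8-bit {0, 255} grayscale
    PNGs; the manifest CSV indexes everything.  Round-tripping through
    :func:`read_dataset` reproduces pixels to 8-bit quantization (max
    deviation 1/255 per channel).
    """
    root = pathlib.Path(directory)
    all_kinds = list(ARTIFACT_KINDS) + [LESION]
    rows = []
    for im in images:
        rel = pathlib.Path("images") / im.split / f"{im.image_id}.png"
        out = root / rel
        out.parent.mkdir(parents=True, exist_ok=True)
        try:
            arr = np.clip(np.rint(im.pixels * 255), 0, 255).astype(np.uint8)
            Image.fromarray(arr).save(out)
        except OSError as exc:
            raise OSError(f"failed to write image to {out}: {exc}") from exc
        for kind, mask in im.artifact_masks.items():
            if mask.any():
                mout = root / "masks" / im.split / f"{im.image_id}_{kind}.png"
                mout.parent.mkdir(parents=True, exist_ok=True)
                Image.fromarray((mask.astype(np.uint8)) * 255, mode="L").save(mout)
        row = {"image_id": im.image_id, "path": str(rel),
               "label": im.label, "split": im.split}
        row.update({kind: int(im.planted(kind)) for kind in all_kinds})
        rows.append(row)
    columns = ["image_id", "path", "label", "split"] + all_kinds
    frame = pd.DataFrame(rows, columns=columns)
    root.mkdir(parents=True, exist_ok=True)
    manifest = DatasetManifest(frame, root=root)
    manifest.write_csv(root / "manifest.csv")
    return manifest


def read_dataset(manifest: DatasetManifest | str | pathlib.Path) -> list[ScanImage]:
    """Load a written dataset (pixels and masks) back into memory."""
    if not isinstance(manifest, DatasetManifest):
        manifest = DatasetManifest.read_csv(
            pathlib.Path(manifest) / "manifest.csv"
            if pathlib.Path(manifest).is_dir() else manifest)
    assert manifest.root is not None
    images = []
    all_kinds = list(ARTIFACT_KINDS) + [LESION]
    for _, row in manifest.frame.iterrows():
        arr = np.asarray(Image.open(manifest.root / row["path"]),
                         dtype=float) / 255.0
        h, w = arr.shape[:2]
        masks = {}
        for kind in all_kinds:
            mpath = (manifest.root / "masks" / row["split"] /
                     f"{row['image_id']}_{kind}.png")
            if int(row.get(kind, 0)) and mpath.exists():
                masks[kind] = np.asarray(Image.open(mpath)) > 127
            else:
                masks[kind] = np.zeros((h, w), dtype=bool)
        images.append(ScanImage(pixels=arr, label=int(row["label"]),
                                split=row["split"], artifact_masks=masks,
                                image_id=row["image_id"]))
    return images
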