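"""Shared value types used across the explanation pipeline."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Allowed heatmap scale conventions.
#: - ``symmetric_signed``: values in [-m, m], 0 means "no influence" (LIME,
#:   Squaregrid, integrated gradients).
#: - ``min_max``: only the ordering of values carries meaning; rendered from
#:   the observed minimum to the observed maximum (RISE).
#: - ``unit``: values in [0, 1] after division by the maximum (GradCAM).
#: - ``magnitude``: nonnegative sensitivity magnitudes (vanilla / smooth
#:   gradients), sign deliberately discarded.
SCALE_CONVENTIONS = ("symmetric_signed", "min_max", "unit", "magnitude")


@dataclass
class Heatmap:
    """A per-pixel saliency map produced by one XAI technique.

    Attributes
    ----------
    values:
        ``(H, W)`` float array of relevances.
    technique:
        Short tag of the producing method, e.g. ``"lime"`` or ``"gradcam"``.
    scale_convention:
        One of :data:`SCALE_CONVENTIONS`; downstream scoring and rendering
        dispatch on it.
    params:
        Free-form record of the parameters and seed that produced the map.
    """

    values: np.ndarray
    technique: str
    scale_convention: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("heatmap values must be a 2-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("heatmap contains non-finite values")
        if self.scale_convention not in SCALE_CONVENTIONS:
            raise ValueError(
                f"unknown scale convention {self.scale_convention!r}; "
                f"expected one of {SCALE_CONVENTIONS}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    def relevance(self) -> np.ndarray:
        """Nonnegative relevance under this map's scale convention.

        Signed and unit maps keep their positive part, magnitude maps their
        absolute value, and min-max maps are shifted by their minimum (their
        absolute scale has no defined meaning, only differences do).
        """
        v = self.values
        if self.scale_convention in ("symmetric_signed", "unit"):
            return np.maximum(v, 0.0)
        if self.scale_convention == "magnitude":
            return np.abs(v)
        return v - v.min()


def save_heatmap(heatmap: Heatmap, path_stem: str) -> None:
    """Persist a heatmap as ``<stem>.npy`` plus a ``<stem>.json`` sidecar."""
    import json
    import pathlib

    stem = pathlib.Path(path_stem)
    np.save(str(stem) + ".npy", heatmap.values.astype(np.float32))
    sidecar = {
        "technique": heatmap.technique,
        "scale_convention": heatmap.scale_convention,
        "params": {k: _jsonable(v) for k, v in heatmap.params.items()},
    }
    with open(str(stem) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_heatmap(path_stem: str) -> Heatmap:
    import json

    values = np.load(path_stem + ".npy")
    with open(path_stem + ".json") as fh:
        sidecar = json.load(fh)
    return Heatmap(values=values, technique=sidecar["technique"],
                   scale_convention=sidecar["scale_convention"],
                   params=sidecar.get("params", {}))


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, np.ndarray):
        return v.tolist()
    return v
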