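"""A small trainable convolutional network with explicit backprop.

The network is deliberately desk-scale: three conv(3x3)-ReLU-maxpool
blocks, global average pooling, and a linear two-class head, implemented
directly on numpy (im2col convolutions, Adam updates).  It fills the
differentiable-classifier contract — softmax predictions, pre-softmax
logits, exact input gradients, and named spatial feature maps with their
gradients — so every gradient-based explainer can run against it, and
`forward_from` lets tests finite-difference the feature-map gradients.

Training follows a two-phase transfer-learning-style schedule: first the
convolutional stack is frozen and only the classification head is fitted,
then all layers are unfrozen and training continues with checkpointing —
after every unfrozen epoch the weights are saved iff validation accuracy
strictly exceeds the policy threshold (default 80%).  Real-time
augmentation (horizontal flip, small rotation, translation and zoom) is
applied to training images.
"""
from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from .contracts import (CheckpointPolicy, DifferentiableClassifierContract,
                        softmax)


@dataclass
class TrainingConfig:
    """Hyper-parameters for the two-phase schedule.

    ``epochs_phase1`` trains the head with frozen convolutions;
    ``epochs_phase2`` trains everything with per-epoch checkpointing.
    Augmentation magnitudes are fixed small: ±10° rotation, ±10%
    translation and zoom, horizontal flip.
    """

    epochs_phase1: int = 5
    epochs_phase2: int = 16
    batch_size: int = 32
    lr_phase1: float = 3e-3
    lr_phase2: float = 1e-3
    channels: tuple[int, int, int] = (8, 16, 32)
    augment: bool = True
    checkpoint_threshold: float = 0.80
    seed: int = 0

    def to_json(self, path) -> None:
        pathlib.Path(path).write_text(json.dumps(self.__dict__, default=list,
                                                 indent=2))


# ---------------------------------------------------------------------------
# layer primitives (stride-1 same-padding 3x3 conv, 2x2 max pool)


def _conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """x (n,H,W,Cin), w (3,3,Cin,K) -> (n,H,W,K)."""
    n, h, ww_, cin = x.shape
    k = w.shape[-1]
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    cols = sliding_window_view(xp, (3, 3), axis=(1, 2))  # (n,H,W,Cin,3,3)
    cols = cols.transpose(0, 1, 2, 4, 5, 3).reshape(n * h * ww_, 9 * cin)
    wmat = w.reshape(9 * cin, k)
    return (cols @ wmat + b).reshape(n, h, ww_, k)


def _conv2d_backward(x: np.ndarray, w: np.ndarray, dout: np.ndarray):
    n, h, ww_, cin = x.shape
    k = w.shape[-1]
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    cols = sliding_window_view(xp, (3, 3), axis=(1, 2))
    cols = cols.transpose(0, 1, 2, 4, 5, 3).reshape(n * h * ww_, 9 * cin)
    dflat = dout.reshape(n * h * ww_, k)
    dw = (cols.T @ dflat).reshape(3, 3, cin, k)
    db = dflat.sum(axis=0)
    # dx = same-padding correlation of dout with the flipped kernel
    wflip = w[::-1, ::-1].transpose(0, 1, 3, 2)  # (3,3,K,Cin)
    dx = _conv2d(dout, wflip, np.zeros(cin))
    return dx, dw, db


def _maxpool(x: np.ndarray):
    n, h, w, c = x.shape
    h2, w2 = h // 2, w // 2
    xr = x[:, :h2 * 2, :w2 * 2].reshape(n, h2, 2, w2, 2, c)
    win = xr.transpose(0, 1, 3, 2, 4, 5).reshape(n, h2, w2, 4, c)
    idx = win.argmax(axis=3)
    out = np.take_along_axis(win, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]
    return out, idx


def _maxpool_backward(dout: np.ndarray, idx: np.ndarray, in_shape):
    n, h, w, c = in_shape
    h2, w2 = h // 2, w // 2
    dwin = np.zeros((n, h2, w2, 4, c))
    np.put_along_axis(dwin, idx[:, :, :, None, :], dout[:, :, :, None, :],
                      axis=3)
    dx = np.zeros(in_shape)
    dx[:, :h2 * 2, :w2 * 2] = (dwin.reshape(n, h2, w2, 2, 2, c)
                               .transpose(0, 1, 3, 2, 4, 5)
                               .reshape(n, h2 * 2, w2 * 2, c))
    return dx


def _meanpool(x: np.ndarray):
    n, h, w, c = x.shape
    h2, w2 = h // 2, w // 2
    out = x[:, :h2 * 2, :w2 * 2].reshape(n, h2, 2, w2, 2, c).mean(axis=(2, 4))
    return out, None


def _meanpool_backward(dout: np.ndarray, in_shape):
    n, h, w, c = in_shape
    h2, w2 = h // 2, w // 2
    dx = np.zeros(in_shape)
    dx[:, :h2 * 2, :w2 * 2] = np.repeat(np.repeat(dout, 2, axis=1), 2,
                                        axis=2) / 4.0
    return dx


def _softplus(z: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, z)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))


class SmallCnn(DifferentiableClassifierContract):
    """Three conv blocks + GAP + linear head over RGB images in [0, 1].

    ``activation="softplus"`` together with ``pool="mean"`` gives an
    everywhere-smooth network, useful when analysing quantities defined
    through exact derivatives (finite-difference checks, the integrated-
    gradients completeness gap); the ReLU/max default is the one trained.
    """

    LAYERS = ("conv1", "conv2", "conv3")

    def __init__(self, input_size: tuple[int, int],
                 channels: tuple[int, int, int] = (8, 16, 32), seed: int = 0,
                 activation: str = "relu", pool: str = "max"):
        if activation not in ("relu", "softplus"):
            raise ValueError(f"unknown activation {activation!r}")
        if pool not in ("max", "mean"):
            raise ValueError(f"unknown pool {pool!r}")
        self.activation = activation
        self.pool = pool
        self.input_size = tuple(input_size)
        self.channels = tuple(channels)
        self.n_classes = 2
        rng = np.random.default_rng(seed)
        cs = [3, *channels]
        self.params: dict[str, np.ndarray] = {}
        for i in range(3):
            fan_in = 9 * cs[i]
            self.params[f"W{i + 1}"] = rng.normal(
                0.0, np.sqrt(2.0 / fan_in), size=(3, 3, cs[i], cs[i + 1]))
            self.params[f"b{i + 1}"] = np.zeros(cs[i + 1])
        self.params["Wd"] = rng.normal(0.0, np.sqrt(2.0 / channels[-1]),
                                       size=(channels[-1], 2))
        self.params["bd"] = np.zeros(2)

    # -- forward / backward ------------------------------------------------

    def _act(self, z: np.ndarray) -> np.ndarray:
        return np.maximum(z, 0.0) if self.activation == "relu" else _softplus(z)

    def _act_deriv(self, z: np.ndarray) -> np.ndarray:
        return (z > 0).astype(float) if self.activation == "relu" else _sigmoid(z)

    def _pool(self, r: np.ndarray):
        return _maxpool(r) if self.pool == "max" else _meanpool(r)

    def _pool_backward(self, da, idx, in_shape):
        if self.pool == "max":
            return _maxpool_backward(da, idx, in_shape)
        return _meanpool_backward(da, in_shape)

    def _forward(self, x: np.ndarray) -> dict:
        cache: dict = {"x": x}
        a = x
        for i in (1, 2, 3):
            z = _conv2d(a, self.params[f"W{i}"], self.params[f"b{i}"])
            r = self._act(z)
            p, idx = self._pool(r)
            cache[f"in{i}"], cache[f"z{i}"] = a, z
            cache[f"relu{i}"], cache[f"idx{i}"] = r, idx
            a = p
        cache["pre_gap"] = a
        gap = a.mean(axis=(1, 2))
        cache["gap"] = gap
        cache["logits"] = gap @ self.params["Wd"] + self.params["bd"]
        return cache

    def _backward(self, cache: dict, dlogits: np.ndarray,
                  stop_layer: str | None = None) -> dict:
        grads: dict = {}
        grads["Wd"] = cache["gap"].T @ dlogits
        grads["bd"] = dlogits.sum(axis=0)
        dgap = dlogits @ self.params["Wd"].T
        a = cache["pre_gap"]
        da = np.broadcast_to(dgap[:, None, None, :], a.shape) / (
            a.shape[1] * a.shape[2])
        for i in (3, 2, 1):
            drelu = self._pool_backward(da, cache[f"idx{i}"],
                                        cache[f"relu{i}"].shape)
            grads[f"d_conv{i}"] = drelu
            if stop_layer == f"conv{i}":
                return grads
            dz = drelu * self._act_deriv(cache[f"z{i}"])
            da, grads[f"W{i}"], grads[f"b{i}"] = _conv2d_backward(
                cache[f"in{i}"], self.params[f"W{i}"], dz)
        grads["d_input"] = da
        return grads

    # -- contract surface --------------------------------------------------

    def logits(self, images: np.ndarray) -> np.ndarray:
        images = np.asarray(images, dtype=float)
        out = []
        for start in range(0, len(images), 64):
            out.append(self._forward(images[start:start + 64])["logits"])
        return np.concatenate(out, axis=0)

    def predict(self, images: np.ndarray) -> np.ndarray:
        return softmax(self.logits(images), axis=1)

    def input_gradient(self, image: np.ndarray, class_index: int) -> np.ndarray:
        cache = self._forward(np.asarray(image, dtype=float)[None])
        dlogits = np.zeros((1, 2))
        dlogits[0, class_index] = 1.0
        return self._backward(cache, dlogits)["d_input"][0]

    def feature_layers(self) -> list[str]:
        return list(self.LAYERS)

    def feature_maps(self, image: np.ndarray, layer_id: str) -> np.ndarray:
        self._check_layer(layer_id)
        cache = self._forward(np.asarray(image, dtype=float)[None])
        return cache[f"relu{layer_id[-1]}"][0]

    def feature_map_gradient(self, image: np.ndarray, class_index: int,
                             layer_id: str) -> np.ndarray:
        self._check_layer(layer_id)
        cache = self._forward(np.asarray(image, dtype=float)[None])
        dlogits = np.zeros((1, 2))
        dlogits[0, class_index] = 1.0
        grads = self._backward(cache, dlogits, stop_layer=layer_id)
        return grads[f"d_{layer_id}"][0]

    def forward_from(self, layer_id: str, maps: np.ndarray) -> np.ndarray:
        """Logits obtained by resuming the forward pass from the post-ReLU
        activations of ``layer_id`` — the hook finite-difference tests use."""
        self._check_layer(layer_id)
        start = int(layer_id[-1])
        a, _ = self._pool(np.asarray(maps, dtype=float)[None])
        for i in range(start + 1, 4):
            z = _conv2d(a, self.params[f"W{i}"], self.params[f"b{i}"])
            a, _ = self._pool(self._act(z))
        gap = a.mean(axis=(1, 2))
        return (gap @ self.params["Wd"] + self.params["bd"])[0]

    def _check_layer(self, layer_id: str) -> None:
        if layer_id not in self.LAYERS:
            raise ValueError(f"unknown layer {layer_id!r}; "
                             f"expected one of {self.LAYERS}")

    @property
    def last_spatial_layer(self) -> str:
        return self.LAYERS[-1]

    # -- persistence -------------------------------------------------------

    def copy_weights(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        self.params = {k: v.copy() for k, v in weights.items()}

    def save(self, path_stem: str, meta: dict | None = None) -> None:
        np.savez(path_stem + ".npz", **self.params)
        sidecar = {"input_size": list(self.input_size),
                   "channels": list(self.channels),
                   "activation": self.activation, "pool": self.pool}
        sidecar.update(meta or {})
        pathlib.Path(path_stem + ".json").write_text(json.dumps(sidecar,
                                                                indent=2))

    @classmethod
    def load(cls, path_stem: str) -> "SmallCnn":
        sidecar = json.loads(pathlib.Path(path_stem + ".json").read_text())
        model = cls(tuple(sidecar["input_size"]), tuple(sidecar["channels"]),
                    activation=sidecar.get("activation", "relu"),
                    pool=sidecar.get("pool", "max"))
        with np.load(path_stem + ".npz") as data:
            model.params = {k: data[k] for k in data.files}
        return model


# ---------------------------------------------------------------------------
# augmentation and training


def augment_image(image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random horizontal flip, ±10° rotation, ±10% translation and zoom."""
    out = image[:, ::-1] if rng.random() < 0.5 else image
    h, w = out.shape[:2]
    angle = np.deg2rad(rng.uniform(-10, 10))
    zoom = 1.0 + rng.uniform(-0.1, 0.1)
    ty, tx = rng.uniform(-0.1, 0.1, size=2) * (h, w)
    c, s = np.cos(angle), np.sin(angle)
    mat = np.array([[c, -s], [s, c]]) / zoom
    center = np.array([h / 2, w / 2])
    offset = center - mat @ center + np.array([ty, tx])
    chans = [ndimage.affine_transform(out[:, :, ch], mat, offset=offset,
                                      order=1, mode="nearest")
             for ch in range(out.shape[2])]
    return np.clip(np.stack(chans, axis=2), 0.0, 1.0)


def _cross_entropy_grad(logits: np.ndarray, labels: np.ndarray):
    p = softmax(logits, axis=1)
    n = len(labels)
    loss = float(-np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean())
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, dlogits / n


class _Adam:
    def __init__(self, keys, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: 0.0 for k in keys}
        self.v = {k: 0.0 for k in keys}
        self.t = 0

    def step(self, params, grads, keys):
        self.t += 1
        for k in keys:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            params[k] = params[k] - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train_small_cnn(data, config: TrainingConfig | None = None
                    ) -> tuple[SmallCnn, CheckpointPolicy]:
    """Train the small CNN on a synthetic dataset with the two-phase schedule.

    ``data`` is a list of ``ScanImage`` (or a ``DatasetManifest``, loaded
    from disk); the ``train`` and ``val`` splits must both be nonempty.
    Phase 1 fits only the head; phase 2 unfreezes everything and
    checkpoints after every epoch whose validation accuracy strictly
    exceeds the policy threshold.  The returned model carries the weights
    of the best phase-2 validation epoch (validation-epoch accuracy can
    oscillate; the above-threshold snapshots are the usable artefacts).
    Deterministic given ``config.seed``.
    """
    from .synthetic import DatasetManifest, read_dataset

    config = config or TrainingConfig()
    if isinstance(data, DatasetManifest):
        data = read_dataset(data)
    xs = {"train": [], "val": []}
    ys = {"train": [], "val": []}
    for im in data:
        if im.split in xs:
            xs[im.split].append(im.pixels)
            ys[im.split].append(im.label)
    if not xs["train"] or not xs["val"]:
        raise ValueError("train and val splits must both be nonempty")
    x_train = np.asarray(xs["train"], dtype=float)
    y_train = np.asarray(ys["train"], dtype=int)
    x_val = np.asarray(xs["val"], dtype=float)
    y_val = np.asarray(ys["val"], dtype=int)

    model = SmallCnn(x_train.shape[1:3], config.channels, seed=config.seed)
    policy = CheckpointPolicy(threshold=config.checkpoint_threshold)
    rng = np.random.default_rng(config.seed)
    head_keys = ["Wd", "bd"]
    all_keys = list(model.params.keys())

    def run_epoch(opt, keys):
        order = rng.permutation(len(x_train))
        for start in range(0, len(order), config.batch_size):
            sel = order[start:start + config.batch_size]
            batch = x_train[sel]
            if config.augment:
                batch = np.stack([augment_image(b, rng) for b in batch])
            cache = model._forward(batch)
            loss, dlogits = _cross_entropy_grad(cache["logits"], y_train[sel])
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite training loss ({loss})")
            grads = model._backward(cache, dlogits)
            opt.step(model.params, grads, keys)

    opt1 = _Adam(head_keys, config.lr_phase1)
    for _ in range(config.epochs_phase1):
        run_epoch(opt1, head_keys)

    opt2 = _Adam(all_keys, config.lr_phase2)
    best: tuple[float, dict] | None = None
    for epoch in range(config.epochs_phase2):
        run_epoch(opt2, all_keys)
        val_acc = float((model.predict(x_val).argmax(axis=1) == y_val).mean())
        weights = model.copy_weights()
        policy.consider(epoch, val_acc, weights)
        if best is None or val_acc > best[0]:
            best = (val_acc, weights)
    # the returned model is the best validation snapshot seen in phase 2
    if best is not None:
        model.set_weights(best[1])
    return model, policy
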