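"""Configurable-depth 3D U-Net segmenter with de-novo and fine-tune training.

The estimator follows scikit-learn conventions: :class:`UNetSegmenter` holds
hyperparameters, ``fit`` trains on a list of patches, fitted state lives in
trailing-underscore attributes, and ``get_params``/``set_params`` come from
``BaseEstimator``. Transfer learning moves a :class:`ModelCheckpoint` between
tasks: ``mode="fine_tune"`` initializes every layer from the parent
checkpoint and continues training all layers at the same learning rate — so
before the first gradient step a fine-tuned model predicts voxel-identically
to its parent.

Whole-volume inference tiles the volume with half-stride sliding windows and
averages per-voxel class probabilities over overlapping windows.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io
import json

import numpy as np
from sklearn.base import BaseEstimator

from .grids import LabelGrid, VolumeGrid
from .nn import Adam, UNet3D, softmax, softmax_cross_entropy

__all__ = [
    "UNetConfig",
    "TrainConfig",
    "ModelCheckpoint",
    "UNetSegmenter",
    "build_model",
    "train",
    "predict_volume",
    "binarize",
]

MODES = ("de_novo", "fine_tune")


@dataclasses.dataclass
class UNetConfig:
    """Architecture: encoder depth, channels, features, training patch size.

    ``patch_size`` must be divisible by ``2**n_levels`` with at least a
    2-voxel bottleneck, so the pooling pyramid and the mirrored decoder line
    up exactly.
    """

    n_levels: int = 4
    in_channels: int = 1
    base_features: int = 8
    out_classes: int = 2
    patch_size: int = 32

    def __post_init__(self):
        if self.n_levels not in (3, 4, 5):
            raise ValueError("n_levels must be one of {3, 4, 5}")
        down = 2**self.n_levels
        if self.patch_size % down != 0 or self.patch_size // down < 2:
            raise ValueError(
                f"patch_size {self.patch_size} must be divisible by 2^{self.n_levels} "
                f"with a bottleneck of at least 2 voxels"
            )

    def compatible_weights(self, other: "UNetConfig") -> bool:
        """Same weight shapes (patch_size may differ; the net is fully convolutional)."""
        return (
            self.n_levels == other.n_levels
            and self.in_channels == other.in_channels
            and self.base_features == other.base_features
            and self.out_classes == other.out_classes
        )


@dataclasses.dataclass
class TrainConfig:
    """Training regime. The full-scale defaults are 30 epochs, Adam, lr 1e-5,
    voxelwise cross-entropy over 2 classes; desk-scale runs raise the learning
    rate (tiny networks, tiny patch sets)."""

    epochs: int = 30
    learning_rate: float = 1e-5
    batch_size: int = 4
    seed: int = 0
    mode: str = "de_novo"
    init_checkpoint: "ModelCheckpoint | None" = None

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.mode == "fine_tune" and self.init_checkpoint is None:
            raise ValueError("fine_tune mode requires init_checkpoint")
        if self.mode == "de_novo" and self.init_checkpoint is not None:
            raise ValueError("de_novo mode must not receive init_checkpoint")


class ModelCheckpoint:
    """Serialized weights plus architecture and training provenance."""

    def __init__(self, weights, config: UNetConfig, provenance: dict):
        self.weights = [np.asarray(w, dtype=np.float32) for w in weights]
        self.config = config
        self.provenance = dict(provenance)
        if "id" not in self.provenance:
            h = hashlib.sha256()
            for w in self.weights:
                h.update(w.tobytes())
            self.provenance["id"] = h.hexdigest()[:16]

    @property
    def id(self) -> str:
        return self.provenance["id"]

    def save(self, path):
        arrays = {f"w{i}": w for i, w in enumerate(self.weights)}
        meta = {"config": dataclasses.asdict(self.config), "provenance": self.provenance}
        buf = io.BytesIO()
        np.savez_compressed(buf, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)
        with open(path, "wb") as fh:
            fh.write(buf.getvalue())
        return path

    @classmethod
    def load(cls, path) -> "ModelCheckpoint":
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"]).decode())
            weights = [z[f"w{i}"] for i in range(sum(1 for k in z.files if k.startswith("w")))]
        return cls(weights, UNetConfig(**meta["config"]), meta["provenance"])

    def build(self) -> UNet3D:
        model = build_model(self.config, seed=0)
        model.set_weights(self.weights)
        return model


def build_model(cfg: UNetConfig, seed: int) -> UNet3D:
    """Reproducibly-initialized U-Net for the given architecture config."""
    return UNet3D(cfg.n_levels, cfg.in_channels, cfg.base_features, cfg.out_classes, seed)


def _patch_arrays(patches, in_channels):
    """Stack patches into channels-last (N, d, h, w, C) plus (N, d, h, w) labels."""
    xs, ys = [], []
    for p in patches:
        img = np.asarray(p.image_patch, dtype=np.float32)
        if img.ndim == 3:
            img = img[..., None]
        else:  # stored channel-first (C, d, h, w)
            img = np.moveaxis(img, 0, -1)
        if img.shape[-1] != in_channels:
            raise ValueError(f"patch has {img.shape[-1]} channels, model expects {in_channels}")
        xs.append(img)
        ys.append(np.asarray(p.label_patch, dtype=np.int64))
    return np.stack(xs), np.stack(ys)


def _manifest_hash(patches) -> str:
    h = hashlib.sha256()
    for p in patches:
        h.update(str((p.source_id, tuple(p.center_voxel), p.augmentation_id)).encode())
        h.update(np.ascontiguousarray(p.image_patch, dtype=np.float32).tobytes())
    return h.hexdigest()[:16]


def train(patches, tcfg: TrainConfig, ucfg: UNetConfig) -> ModelCheckpoint:
    """Train (de-novo or fine-tuned) and return a checkpoint with loss history.

    Deterministic for fixed seed: patch order is shuffled per epoch by a
    seeded generator and all arithmetic is single-threaded numpy.
    """
    if not patches:
        raise ValueError("patch list is empty")
    X, Y = _patch_arrays(patches, ucfg.in_channels)
    rng = np.random.default_rng(tcfg.seed)
    model = build_model(ucfg, seed=int(rng.integers(2**31)))
    parent = None
    if tcfg.mode == "fine_tune":
        parent = tcfg.init_checkpoint
        if not ucfg.compatible_weights(parent.config):
            raise ValueError(
                f"fine_tune architecture mismatch: parent {parent.config} vs requested {ucfg}"
            )
        model.set_weights(parent.weights)
    opt = Adam(model.params(), lr=tcfg.learning_rate)
    n = len(X)
    loss_history = []
    for _ in range(tcfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, tcfg.batch_size):
            idx = order[start : start + tcfg.batch_size]
            model.zero_grad()
            logits = model.forward(X[idx], train=True)
            loss, grad = softmax_cross_entropy(logits, Y[idx])
            model.backward(grad)
            opt.step()
            losses.append(loss)
        loss_history.append(float(np.mean(losses)))
    provenance = {
        "mode": tcfg.mode,
        "parent": parent.id if parent is not None else None,
        "kind": parent.provenance.get("kind", "model") if parent is not None else "model",
        "data_manifest": _manifest_hash(patches),
        "n_patches": n,
        "seed": int(tcfg.seed),
        "epochs": int(tcfg.epochs),
        "learning_rate": float(tcfg.learning_rate),
        "loss_history": loss_history,
    }
    return ModelCheckpoint(model.get_weights(), ucfg, provenance)


def _as_channel_stack(volumes):
    if isinstance(volumes, VolumeGrid):
        volumes = [volumes]
    ref = volumes[0]
    for v in volumes[1:]:
        if not ref.same_geometry(v):
            raise ValueError("channel volumes must share geometry")
    return np.stack([v.intensities for v in volumes]).astype(np.float32), ref


def predict_volume(ckpt: ModelCheckpoint, volumes, stride=None, batch_windows=8) -> VolumeGrid:
    """Whole-volume lesion probability by sliding-window tiling.

    Windows of ``patch_size`` at stride ``patch_size // 2`` (plus flush end
    positions); per-voxel class-1 probabilities are averaged over overlapping
    windows. Volumes smaller than the patch are reflect-padded and the output
    cropped back. Output geometry equals the input geometry, values in [0, 1].
    """
    stacked, ref = _as_channel_stack(volumes)
    x = np.moveaxis(stacked, 0, -1)  # channels-last (D, H, W, C)
    ps = ckpt.config.patch_size
    stride = stride or max(1, ps // 2)
    shape = x.shape[:3]
    pad = [(0, max(0, ps - s)) for s in shape]
    if any(p[1] for p in pad):
        x = np.pad(x, pad + [(0, 0)], mode="reflect")
    pshape = x.shape[:3]
    model = ckpt.build()

    starts = []
    for ax in range(3):
        s = list(range(0, pshape[ax] - ps + 1, stride))
        if s[-1] != pshape[ax] - ps:
            s.append(pshape[ax] - ps)
        starts.append(s)
    wins = [(i, j, k) for i in starts[0] for j in starts[1] for k in starts[2]]

    acc = np.zeros(pshape, dtype=np.float64)
    cnt = np.zeros(pshape, dtype=np.float64)
    for b0 in range(0, len(wins), batch_windows):
        batch = wins[b0 : b0 + batch_windows]
        tiles = np.stack([x[i : i + ps, j : j + ps, k : k + ps, :] for i, j, k in batch])
        probs = softmax(model.forward(tiles, train=False))[..., 1].astype(np.float64)
        for t, (i, j, k) in enumerate(batch):
            acc[i : i + ps, j : j + ps, k : k + ps] += probs[t]
            cnt[i : i + ps, j : j + ps, k : k + ps] += 1.0
    prob = acc / cnt
    prob = prob[: shape[0], : shape[1], : shape[2]]
    return VolumeGrid(prob, ref.spacing_mm, ref.origin, ref.identifier)


def binarize(prob: VolumeGrid, threshold: float = 0.5) -> LabelGrid:
    """Threshold a probability map into a binary lesion mask (prob >= threshold)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    mask = (prob.intensities >= threshold).astype(np.int16)
    return LabelGrid(mask, prob.spacing_mm, prob.origin, prob.identifier)


class UNetSegmenter(BaseEstimator):
    """scikit-learn style wrapper around the 3D U-Net training pipeline.

    Parameters mirror :class:`UNetConfig` and :class:`TrainConfig`; ``fit``
    takes a list of :class:`~mslesionseg.preprocess.Patch` and exposes the
    trained :class:`ModelCheckpoint` as ``checkpoint_``.
    """

    def __init__(
        self,
        n_levels=4,
        in_channels=1,
        base_features=8,
        out_classes=2,
        patch_size=32,
        epochs=30,
        learning_rate=1e-5,
        batch_size=4,
        mode="de_novo",
        init_checkpoint=None,
        threshold=0.5,
        seed=0,
    ):
        self.n_levels = n_levels
        self.in_channels = in_channels
        self.base_features = base_features
        self.out_classes = out_classes
        self.patch_size = patch_size
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.mode = mode
        self.init_checkpoint = init_checkpoint
        self.threshold = threshold
        self.seed = seed

    def _configs(self):
        ucfg = UNetConfig(
            self.n_levels, self.in_channels, self.base_features, self.out_classes, self.patch_size
        )
        tcfg = TrainConfig(
            self.epochs, self.learning_rate, self.batch_size, self.seed, self.mode, self.init_checkpoint
        )
        return ucfg, tcfg

    def fit(self, patches, y=None):
        ucfg, tcfg = self._configs()
        self.checkpoint_ = train(patches, tcfg, ucfg)
        self.loss_history_ = list(self.checkpoint_.provenance["loss_history"])
        self.n_parameters_ = self.checkpoint_.build().n_parameters()
        return self

    def predict_proba(self, volumes) -> VolumeGrid:
        self._check_fitted()
        return predict_volume(self.checkpoint_, volumes)

    def predict(self, volumes) -> LabelGrid:
        return binarize(self.predict_proba(volumes), self.threshold)

    def _check_fitted(self):
        if not hasattr(self, "checkpoint_"):
            raise RuntimeError("UNetSegmenter is not fitted; call fit() first")
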