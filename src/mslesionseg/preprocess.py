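"""Image preparation: z-normalization, isotropic resampling, elastic
augmentation and stratified patch extraction.

The chain mirrors standard volumetric-segmentation practice: every image is
normalized to zero mean / unit (population) SD, resampled to isotropic
resolution by linear interpolation (nearest-neighbour for label maps), and
split into fixed-size cubic patches. Training patches are stratified: half
are *lesion-inclusive* (contain at least one lesion voxel; centers drawn
uniformly from lesion voxels) and half *lesion-exclusive* (zero lesion
voxels; rejection-sampled uniform centers). Each training volume is subjected
to ``n_augmentations`` whole-volume elastic augmentations — augmentation 0 is
the identity, the rest are random smooth warps — and the same patch centers
are extracted from every augmented copy, so a study with the default 30+30
centers and 3 augmentations yields 180 patches.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .grids import LabelGrid, VolumeGrid

__all__ = [
    "ElasticParams",
    "PatchSamplingConfig",
    "Patch",
    "znormalize",
    "resample_isotropic",
    "resample_label_isotropic",
    "elastic_augment",
    "sample_patches",
    "build_training_patches",
]


class DegenerateVolumeError(ValueError):
    """Raised for volumes that cannot be normalized (zero variance)."""


@dataclasses.dataclass
class ElasticParams:
    """Smooth random deformation: Gaussian displacements on a coarse control
    grid, upsampled to voxel resolution. ``displacement_sd_mm`` = 0 is the
    identity."""

    control_grid_spacing_mm: float = 8.0
    displacement_sd_mm: float = 1.5

    def __post_init__(self):
        if self.control_grid_spacing_mm <= 0:
            raise ValueError("control_grid_spacing_mm must be positive")
        if self.displacement_sd_mm < 0:
            raise ValueError("displacement_sd_mm must be >= 0")


@dataclasses.dataclass
class PatchSamplingConfig:
    """Stratified patch sampling. Defaults follow the 30/30/3 scheme with a
    desk-scale 24-voxel patch (the full-scale setting is 96)."""

    patch_size_voxels: tuple = (24, 24, 24)
    n_lesion_inclusive: int = 30
    n_lesion_exclusive: int = 30
    n_augmentations: int = 3
    max_attempts: int = 1000

    def __post_init__(self):
        if isinstance(self.patch_size_voxels, int):
            self.patch_size_voxels = (self.patch_size_voxels,) * 3
        self.patch_size_voxels = tuple(int(v) for v in self.patch_size_voxels)
        if any(v <= 0 for v in self.patch_size_voxels):
            raise ValueError("patch size must be positive")
        if self.n_lesion_inclusive < 0 or self.n_lesion_exclusive < 0:
            raise ValueError("patch counts must be >= 0")
        if self.n_augmentations < 1:
            raise ValueError("n_augmentations must be >= 1")


@dataclasses.dataclass
class Patch:
    """Fixed-size image/label sub-volume with provenance."""

    image_patch: np.ndarray
    label_patch: np.ndarray
    source_id: str
    center_voxel: tuple
    augmentation_id: int


def znormalize(vol: VolumeGrid) -> VolumeGrid:
    """Normalize to zero mean and unit population SD over all voxels."""
    x = vol.intensities
    sd = float(x.std())  # population SD
    if sd == 0:
        raise DegenerateVolumeError(f"volume {vol.identifier!r} is constant; cannot z-normalize")
    return vol.copy(intensities=(x - x.mean()) / sd)


def _resample(data, spacing, target_mm, order):
    shape = data.shape
    out_shape = tuple(int(round(n * s / target_mm)) for n, s in zip(shape, spacing))
    coords = np.meshgrid(
        *[np.arange(m) * target_mm / s for m, s in zip(out_shape, spacing)], indexing="ij"
    )
    return ndimage.map_coordinates(data, coords, order=order, mode="nearest"), out_shape


def resample_isotropic(vol: VolumeGrid, target_mm: float = 1.0) -> VolumeGrid:
    """Resample to isotropic ``target_mm`` resolution by trilinear interpolation.

    Output shape per axis is ``round(shape * spacing / target)``. A volume
    already at the target spacing passes through voxel-identically.
    """
    if target_mm <= 0:
        raise ValueError("target_mm must be positive")
    if np.allclose(vol.spacing_mm, target_mm):
        return vol.copy()
    out, _ = _resample(vol.intensities, vol.spacing_mm, target_mm, order=1)
    return VolumeGrid(out, (target_mm,) * 3, vol.origin, vol.identifier)


def resample_label_isotropic(mask: LabelGrid, target_mm: float = 1.0) -> LabelGrid:
    """Nearest-neighbour resampling variant for label maps."""
    if target_mm <= 0:
        raise ValueError("target_mm must be positive")
    if np.allclose(mask.spacing_mm, target_mm):
        return mask.copy()
    out, _ = _resample(mask.labels, mask.spacing_mm, target_mm, order=0)
    return LabelGrid(out.astype(mask.labels.dtype), (target_mm,) * 3, mask.origin, mask.identifier)


def _displacement_field(shape, spacing, params: ElasticParams, rng):
    """Per-axis voxel-displacement arrays from a coarse Gaussian control grid."""
    ctrl_shape = tuple(
        max(2, int(np.ceil(n * s / params.control_grid_spacing_mm)) + 1) for n, s in zip(shape, spacing)
    )
    fields = []
    for ax in range(3):
        ctrl = rng.normal(0.0, params.displacement_sd_mm, size=ctrl_shape)
        zoom = [n / c for n, c in zip(shape, ctrl_shape)]
        f = ndimage.zoom(ctrl, zoom, order=3)
        fields.append(f / spacing[ax])  # mm -> voxels
    return fields


def _as_channels(image):
    """Normalize the image argument to a list of channel VolumeGrids."""
    if isinstance(image, VolumeGrid):
        return [image], True
    chans = list(image)
    if not chans:
        raise ValueError("empty channel list")
    for c in chans[1:]:
        if not chans[0].same_geometry(c):
            raise ValueError("channel volumes must share geometry")
    return chans, False


def elastic_augment(image, label: LabelGrid, params: ElasticParams, seed: int):
    """Warp image and label with the same smooth random displacement field.

    ``image`` may be a single VolumeGrid or a sequence of channel volumes (all
    warped with the same field). The image is interpolated linearly, the label
    with nearest-neighbour (so a binary mask stays binary). Deterministic for
    a fixed seed; a zero displacement SD returns voxel-identical copies.
    """
    chans, single = _as_channels(image)
    if chans[0].shape != label.shape:
        raise ValueError("image and label geometry must match")
    if params.displacement_sd_mm == 0:
        out = [c.copy() for c in chans]
        return (out[0] if single else out), label.copy()
    rng = np.random.default_rng(seed)
    disp = _displacement_field(label.shape, chans[0].spacing_mm, params, rng)
    base = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in label.shape], indexing="ij")
    coords = [b + d for b, d in zip(base, disp)]
    warped = [
        c.copy(intensities=ndimage.map_coordinates(c.intensities, coords, order=1, mode="nearest"))
        for c in chans
    ]
    warped_lab = ndimage.map_coordinates(label.labels, coords, order=0, mode="nearest")
    return (warped[0] if single else warped), label.copy(labels=warped_lab.astype(label.labels.dtype))


def _clamp_start(center, size, shape):
    return tuple(
        int(np.clip(c - sz // 2, 0, n - sz)) for c, sz, n in zip(center, size, shape)
    )


def _extract(data, start, size):
    sl = tuple(slice(s, s + sz) for s, sz in zip(start, size))
    return data[sl]


def _sample_centers(label: LabelGrid, cfg: PatchSamplingConfig, rng):
    shape = label.shape
    size = cfg.patch_size_voxels
    if any(sz > n for sz, n in zip(size, shape)):
        raise ValueError(f"patch size {size} exceeds volume shape {shape}")
    lesion_idx = np.argwhere(label.labels > 0)
    centers = []
    if cfg.n_lesion_inclusive > 0 and lesion_idx.size == 0:
        raise ValueError("lesion-inclusive patches requested but the label map is empty")
    for _ in range(cfg.n_lesion_inclusive):
        c = tuple(lesion_idx[rng.integers(len(lesion_idx))])
        centers.append((tuple(int(v) for v in c), True))
    if cfg.n_lesion_exclusive > 0:
        clean = _lesion_free_starts(label.labels > 0, size)
        if len(clean) == 0:
            raise ValueError(
                f"no lesion-free {size} window exists in volume {label.identifier!r}"
            )
        for _ in range(cfg.n_lesion_exclusive):
            start = clean[rng.integers(len(clean))]
            c = tuple(int(s + sz // 2) for s, sz in zip(start, size))
            centers.append((c, False))
    return centers


def _lesion_free_starts(fg, size):
    """All window start corners whose patch contains zero lesion voxels,
    via a 3D summed-area table (exact, no rejection sampling)."""
    sat = np.zeros(tuple(n + 1 for n in fg.shape), dtype=np.int64)
    sat[1:, 1:, 1:] = fg.astype(np.int64).cumsum(0).cumsum(1).cumsum(2)
    nx, ny, nz = (n - s + 1 for n, s in zip(fg.shape, size))
    sx, sy, sz = size
    a = sat[sx : sx + nx, sy : sy + ny, sz : sz + nz]
    b = sat[0:nx, sy : sy + ny, sz : sz + nz]
    c = sat[sx : sx + nx, 0:ny, sz : sz + nz]
    d = sat[sx : sx + nx, sy : sy + ny, 0:nz]
    e = sat[0:nx, 0:ny, sz : sz + nz]
    f = sat[0:nx, sy : sy + ny, 0:nz]
    g = sat[sx : sx + nx, 0:ny, 0:nz]
    h = sat[0:nx, 0:ny, 0:nz]
    sums = a - b - c - d + e + f + g - h
    return np.argwhere(sums == 0)


def _extract_patch(chans, single, label, c, size, aug_id):
    start = _clamp_start(c, size, label.shape)
    imgs = [_extract(ch.intensities, start, size).copy() for ch in chans]
    img = imgs[0] if single else np.stack(imgs)
    return Patch(
        img,
        (_extract(label.labels, start, size) > 0).astype(np.int8),
        chans[0].identifier,
        tuple(c),
        aug_id,
    )


def sample_patches(image, label: LabelGrid, cfg: PatchSamplingConfig, seed: int):
    """Sample ``n_lesion_inclusive + n_lesion_exclusive`` stratified patches.

    Lesion-inclusive centers are drawn uniformly from lesion voxels and
    clamped so the patch fits in-bounds (patches are shifted inward, never
    padded); lesion-exclusive centers are rejection-sampled until the patch
    contains no lesion voxel. Sampling is with replacement. ``image`` may be
    a sequence of channel volumes, in which case patches are channel-stacked.
    """
    chans, single = _as_channels(image)
    if not chans[0].same_geometry(label):
        raise ValueError("image and label geometry must match")
    rng = np.random.default_rng(seed)
    centers = _sample_centers(label, cfg, rng)
    return [_extract_patch(chans, single, label, c, cfg.patch_size_voxels, 0) for c, _ in centers]


def build_training_patches(studies, cfg: PatchSamplingConfig, elastic: ElasticParams, seed: int):
    """Stratified patches from whole-volume augmented copies of each study.

    Per study: centers are sampled once on the un-warped volume, then
    ``n_augmentations`` copies of the volume/label are produced (augmentation
    0 = identity, others elastic) and the same centers are extracted from each
    copy, giving ``(n_inc + n_exc) * n_augmentations`` patches per study.
    """
    if not studies:
        raise ValueError("study list is empty")
    rng = np.random.default_rng(seed)
    size = cfg.patch_size_voxels
    out = []
    for image, label in studies:
        chans, single = _as_channels(image)
        centers = _sample_centers(label, cfg, rng)
        for aug_id in range(cfg.n_augmentations):
            if aug_id == 0:
                img_a, lab_a = image, label
            else:
                img_a, lab_a = elastic_augment(image, label, elastic, int(rng.integers(2**31)))
            chans_a, _ = _as_channels(img_a)
            for c, _ in centers:
                out.append(_extract_patch(chans_a, single, lab_a, c, size, aug_id))
    return out
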