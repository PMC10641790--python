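"""Synthetic 3D brain phantoms with known lesion ground truth.

The generator emulates the statistical structure of three segmentation tasks
on a simplified brain: an ellipsoidal "brain" with a darker central
"ventricle", a smooth random texture field, additive Gaussian noise, and
hyperintense lesions placed by rejection sampling.

Domains
-------
``ms_focal``
    Many small spherical/ellipsoidal hyperintense lesions, preferentially
    periventricular — the multiple-sclerosis-like target domain.
``source_geographic``
    One or two large irregular smoothed blobs occupying at least 5% of the
    brain volume — the source domain standing in for the large geographic
    signal abnormalities (tumors, leukoencephalopathy) that pretrained the
    single-timepoint and new-lesion default models.
``source_enhancing_foci``
    Numerous small bright foci — the metastasis-like source domain for the
    contrast-enhancement task; used by :func:`generate_contrast_pair`.

All generators are pure functions of ``(config, seed)``: calling twice with
the same arguments yields voxel-identical output. Lesions are rendered
hard-edged (only the background texture is smoothed) so that ground-truth
component counts and voxel-recovery guarantees are exact.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy import ndimage

from .grids import LabelGrid, VolumeGrid, save_grid, save_sidecar
from .transforms import RigidTransform, apply_to_label, apply_to_volume

__all__ = [
    "PhantomConfig",
    "StudySample",
    "LongitudinalSample",
    "ContrastPairSample",
    "PlacementError",
    "generate_study",
    "generate_longitudinal_pair",
    "generate_contrast_pair",
    "write_study",
    "benchmark_config",
]

DOMAINS = ("ms_focal", "source_geographic", "source_enhancing_foci")


class PlacementError(RuntimeError):
    """Raised when non-overlapping lesion placement cannot be satisfied."""


@dataclasses.dataclass
class PhantomConfig:
    """Geometry, intensity model and lesion statistics of the phantom.

    Intensities are in arbitrary units with tissue at ``tissue_mean``; the
    lesion increment ``lesion_contrast`` defaults to 5x the voxel noise —
    above the 4x separability floor (a threshold at ``tissue_mean +
    lesion_contrast/2`` still recovers >= 90% of lesion voxels), so the
    learning problem is solvable yet non-trivial: the smoothed texture field
    leaves lesion-like lumps that an undertrained model false-positives on.
    """

    grid_shape: tuple = (64, 64, 64)
    spacing_mm: tuple = (1.0, 1.0, 1.0)
    brain_axes_mm: tuple = (26.0, 30.0, 24.0)
    ventricle_axes_mm: tuple = (7.0, 11.0, 7.0)
    tissue_mean: float = 1.0
    tissue_sd: float = 0.05
    texture_smoothing_mm: float = 4.0
    noise_sd: float = 0.05
    lesion_count_range: tuple = (2, 12)
    lesion_radius_range_mm: tuple = (2.0, 6.0)
    lesion_contrast: float = 0.25
    ventricle_contrast: float = -0.4
    domain: str = "ms_focal"
    rigid_jitter: tuple = (2.0, 2.0)  # (max |translation| mm per axis, max |rotation| deg per axis)
    distractor_on: bool = False
    distractor_contrast: float = 0.25
    geographic_radius_range_mm: tuple = (8.0, 12.0)
    max_placement_attempts: int = 200

    def __post_init__(self):
        self.grid_shape = tuple(int(v) for v in self.grid_shape)
        if any(v < 16 for v in self.grid_shape):
            raise ValueError("grid_shape axes must all be >= 16")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")
        lo, hi = self.lesion_count_range
        if lo < 0 or hi < lo:
            raise ValueError("lesion_count_range must be a non-negative interval")
        rlo, rhi = self.lesion_radius_range_mm
        if rlo <= 0 or rhi < rlo:
            raise ValueError("lesion_radius_range_mm must be positive")
        if rhi >= min(self.brain_axes_mm):
            raise ValueError("lesions must fit inside the brain mask")
        if self.domain not in DOMAINS:
            raise ValueError(f"domain must be one of {DOMAINS}")

    @property
    def center_mm(self) -> np.ndarray:
        return (np.asarray(self.grid_shape) - 1) / 2 * np.asarray(self.spacing_mm)


def benchmark_config(domain: str = "ms_focal", **overrides) -> PhantomConfig:
    """Scaled 32^3 preset used by the desk-scale transfer benchmark."""
    base = dict(
        grid_shape=(32, 32, 32),
        brain_axes_mm=(13.0, 14.0, 12.0),
        ventricle_axes_mm=(3.5, 5.0, 3.5),
        lesion_count_range=(2, 5),
        lesion_radius_range_mm=(2.0, 3.5),
        geographic_radius_range_mm=(5.0, 7.0),
        rigid_jitter=(1.5, 1.5),
        domain=domain,
    )
    if domain == "source_enhancing_foci":
        base["lesion_count_range"] = (6, 10)
        base["lesion_radius_range_mm"] = (1.5, 2.5)
    base.update(overrides)
    return PhantomConfig(**base)


@dataclasses.dataclass
class StudySample:
    """One synthetic study: image, binary lesion mask, and provenance."""

    image: VolumeGrid
    lesion_mask: LabelGrid
    lesion_centers: list
    seed: int
    domain: str


@dataclasses.dataclass
class LongitudinalSample:
    """Baseline/follow-up pair sharing persistent lesions plus new lesions."""

    baseline: StudySample
    follow_up: StudySample
    new_lesion_mask: LabelGrid  # in follow-up native space
    applied_transform: RigidTransform


@dataclasses.dataclass
class ContrastPairSample:
    """Pre/post-contrast pair with enhancing foci and optional falx distractor."""

    pre: VolumeGrid
    post: VolumeGrid
    enhancing_mask: LabelGrid
    distractor_mask: LabelGrid


# ---------------------------------------------------------------------------
# geometry helpers


def _coords_mm(cfg: PhantomConfig):
    axes = [np.arange(n) * s for n, s in zip(cfg.grid_shape, cfg.spacing_mm)]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid_mask(cfg, semi_axes):
    X, Y, Z = _coords_mm(cfg)
    c = cfg.center_mm
    a = np.asarray(semi_axes, dtype=float)
    q = ((X - c[0]) / a[0]) ** 2 + ((Y - c[1]) / a[1]) ** 2 + ((Z - c[2]) / a[2]) ** 2
    return q <= 1.0


def _inside_shrunken_ellipsoid(point_mm, center, semi_axes, margin):
    a = np.asarray(semi_axes) - margin
    if np.any(a <= 0):
        return False
    d = (np.asarray(point_mm) - center) / a
    return float(d @ d) <= 1.0


def _outside_grown_ellipsoid(point_mm, center, semi_axes, margin):
    a = np.asarray(semi_axes) + margin
    d = (np.asarray(point_mm) - center) / a
    return float(d @ d) >= 1.0


def _background(cfg: PhantomConfig, rng) -> np.ndarray:
    """Tissue + ventricle + smooth texture field (noise added separately)."""
    brain = _ellipsoid_mask(cfg, cfg.brain_axes_mm)
    vent = _ellipsoid_mask(cfg, cfg.ventricle_axes_mm)
    img = np.zeros(cfg.grid_shape, dtype=np.float64)
    img[brain] = cfg.tissue_mean
    img[vent] += cfg.ventricle_contrast
    if cfg.tissue_sd > 0:
        field = rng.standard_normal(cfg.grid_shape)
        sigma = cfg.texture_smoothing_mm / np.asarray(cfg.spacing_mm)
        field = ndimage.gaussian_filter(field, sigma)
        sd = field.std()
        if sd > 0:
            field *= cfg.tissue_sd / sd
        img[brain] += field[brain]
    return img


def _rasterize_ellipsoid(cfg, center_mm, semi_axes_mm) -> np.ndarray:
    X, Y, Z = _coords_mm(cfg)
    a = np.asarray(semi_axes_mm, dtype=float)
    q = ((X - center_mm[0]) / a[0]) ** 2 + ((Y - center_mm[1]) / a[1]) ** 2 + ((Z - center_mm[2]) / a[2]) ** 2
    return q <= 1.0


def _sample_focal_center(cfg, rng, radius_mm):
    """One candidate center: periventricular with p=0.5, else anywhere in brain."""
    c = cfg.center_mm
    margin_vox = 2.0 * max(cfg.spacing_mm)
    for _ in range(cfg.max_placement_attempts):
        if rng.random() < 0.5:
            # point just outside the ventricle surface
            u = rng.standard_normal(3)
            u /= np.linalg.norm(u)
            scale = 1.0 + (radius_mm + margin_vox + rng.random() * 3.0) / min(cfg.ventricle_axes_mm)
            p = c + u * np.asarray(cfg.ventricle_axes_mm) * scale
        else:
            u = rng.uniform(-1, 1, size=3)
            p = c + u * np.asarray(cfg.brain_axes_mm)
        if _inside_shrunken_ellipsoid(p, c, cfg.brain_axes_mm, radius_mm + max(cfg.spacing_mm)) and _outside_grown_ellipsoid(
            p, c, cfg.ventricle_axes_mm, radius_mm + margin_vox
        ):
            return p
    return None


def _place_focal_lesions(cfg, rng, n, existing=(), radius_range=None):
    """Rejection-sample n non-overlapping lesions; returns (mask, centers_vox, specs)."""
    radius_range = radius_range or cfg.lesion_radius_range_mm
    sep = 2.0 * max(cfg.spacing_mm)  # extra 2-voxel margin keeps components countable
    placed = list(existing)  # (center_mm, max_radius_mm)
    mask = np.zeros(cfg.grid_shape, dtype=bool)
    centers_vox, specs = [], []
    for _ in range(n):
        ok = False
        for _ in range(cfg.max_placement_attempts):
            r = rng.uniform(*radius_range)
            p = _sample_focal_center(cfg, rng, r)
            if p is None:
                continue
            axes = r * rng.uniform(0.85, 1.15, size=3)
            rmax = float(axes.max())
            if all(np.linalg.norm(p - q) >= rmax + rq + sep for q, rq in placed):
                ok = True
                break
        if not ok:
            raise PlacementError(
                f"could not place {n} non-overlapping lesions in the brain mask "
                f"(radius range {radius_range} mm, grid {cfg.grid_shape})"
            )
        les = _rasterize_ellipsoid(cfg, p, axes)
        if not les.any():  # pragma: no cover - radii >= spacing always rasterize
            raise PlacementError("lesion rasterized to zero voxels")
        mask |= les
        placed.append((p, rmax))
        centers_vox.append(tuple(int(round(v / s)) for v, s in zip(p, cfg.spacing_mm)))
        specs.append((tuple(p), tuple(axes)))
    return mask, centers_vox, specs, placed


def _place_geographic(cfg, rng):
    """1-2 large irregular blobs totalling >= 5% of the brain volume.

    Placement is unilateral (glioma-like: confined to one randomly chosen
    hemisphere, hard-clipped at the midline), which also guarantees that the
    contralateral half of the grid stays lesion-free for background patches.
    """
    brain = _ellipsoid_mask(cfg, cfg.brain_axes_mm)
    vent = _ellipsoid_mask(cfg, cfg.ventricle_axes_mm)
    target = 0.05 * brain.sum()
    X, Y, Z = _coords_mm(cfg)
    c = cfg.center_mm
    side = 1 if rng.random() < 0.5 else -1
    hemi = (X - c[0]) * side >= 0
    for _ in range(cfg.max_placement_attempts):
        n_blobs = int(rng.integers(1, 3))
        mask = np.zeros(cfg.grid_shape, dtype=bool)
        centers = []
        placed = []
        failed = False
        for _ in range(n_blobs):
            r0 = rng.uniform(*cfg.geographic_radius_range_mm)
            p = None
            for _ in range(cfg.max_placement_attempts):
                u = rng.uniform(-1, 1, size=3)
                u[0] = abs(u[0]) * side  # hemispheric bias
                q = c + u * np.asarray(cfg.brain_axes_mm) * 0.6
                if not _inside_shrunken_ellipsoid(q, c, cfg.brain_axes_mm, 0.5 * r0):
                    continue
                if all(np.linalg.norm(q - pc) >= 1.3 * (r0 + pr) + 2.0 for pc, pr in placed):
                    p = q
                    break
            if p is None:
                failed = True
                break
            # irregular boundary: radius modulated by a smooth random field
            field = ndimage.gaussian_filter(rng.standard_normal(cfg.grid_shape), 3.0)
            sd = field.std()
            if sd > 0:
                field /= sd
            dist = np.sqrt((X - p[0]) ** 2 + (Y - p[1]) ** 2 + (Z - p[2]) ** 2)
            blob = (dist <= r0 * (1.0 + 0.25 * field)) & brain & ~vent & hemi
            mask |= blob
            placed.append((p, r0))
            centers.append(tuple(int(round(v / s)) for v, s in zip(p, cfg.spacing_mm)))
        if failed:
            continue
        lab, n_comp = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
        if mask.sum() >= target and n_comp == n_blobs:
            return mask, centers
    raise PlacementError("could not place geographic lesions covering >= 5% of brain volume")


# ---------------------------------------------------------------------------
# generators


def generate_study(config: PhantomConfig, seed: int) -> StudySample:
    """Generate one synthetic study (image + binary lesion mask).

    Deterministic for fixed ``(config, seed)``. The lesion count is drawn
    uniformly from ``config.lesion_count_range``; placement is
    rejection-sampled with a minimum center separation of the two radii plus
    two voxels, so the connected-component count of the mask equals the
    number of placed lesions exactly.
    """
    rng = np.random.default_rng(seed)
    scene = _background(config, rng)
    if config.domain == "source_geographic":
        mask, centers = _place_geographic(config, rng)
    else:  # ms_focal and source_enhancing_foci both place small foci
        lo, hi = config.lesion_count_range
        n = int(rng.integers(lo, hi + 1))
        mask, centers, _, _ = _place_focal_lesions(config, rng, n)
    img = scene + config.lesion_contrast * mask
    if config.noise_sd > 0:
        img = img + rng.normal(0.0, config.noise_sd, size=config.grid_shape)
    ident = f"{config.domain}-{seed}"
    image = VolumeGrid(img, config.spacing_mm, identifier=ident)
    lesion_mask = LabelGrid(mask.astype(np.int16), config.spacing_mm, identifier=ident)
    return StudySample(image, lesion_mask, centers, int(seed), config.domain)


def _random_jitter(cfg: PhantomConfig, rng) -> RigidTransform:
    tmax, rmax = cfg.rigid_jitter
    t = rng.uniform(-tmax, tmax, size=3)
    r = rng.uniform(-rmax, rmax, size=3)
    return RigidTransform(tuple(t), tuple(r), tuple(cfg.center_mm))


def generate_longitudinal_pair(config: PhantomConfig, n_new_lesions: int, seed: int) -> LongitudinalSample:
    """Baseline plus follow-up: shared anatomy, persistent lesions, new lesions,
    and a random rigid jitter (within ``config.rigid_jitter``) applied to the
    follow-up scan before re-noising. The new-lesion mask is stored in
    follow-up native space and the applied transform is recorded.
    """
    if n_new_lesions < 0:
        raise ValueError("n_new_lesions must be >= 0")
    rng = np.random.default_rng(seed)
    scene = _background(config, rng)
    lo, hi = config.lesion_count_range
    n_base = int(rng.integers(lo, hi + 1))
    base_mask, base_centers, _, placed = _place_focal_lesions(config, rng, n_base)
    new_mask, new_centers, _, _ = _place_focal_lesions(config, rng, n_new_lesions, existing=placed)

    base_img = scene + config.lesion_contrast * base_mask
    base_noise = rng.normal(0.0, config.noise_sd, size=config.grid_shape) if config.noise_sd > 0 else 0.0
    baseline = StudySample(
        VolumeGrid(base_img + base_noise, config.spacing_mm, identifier=f"base-{seed}"),
        LabelGrid(base_mask.astype(np.int16), config.spacing_mm, identifier=f"base-{seed}"),
        base_centers,
        int(seed),
        config.domain,
    )

    follow_scene = scene + config.lesion_contrast * (base_mask | new_mask)
    transform = _random_jitter(config, rng)
    follow_vol = apply_to_volume(VolumeGrid(follow_scene, config.spacing_mm), transform)
    follow_img = follow_vol.intensities
    if config.noise_sd > 0:
        follow_img = follow_img + rng.normal(0.0, config.noise_sd, size=config.grid_shape)
    all_mask_t = apply_to_label(
        LabelGrid((base_mask | new_mask).astype(np.int16), config.spacing_mm), transform
    )
    new_mask_t = apply_to_label(LabelGrid(new_mask.astype(np.int16), config.spacing_mm), transform)
    follow_up = StudySample(
        VolumeGrid(follow_img, config.spacing_mm, identifier=f"follow-{seed}"),
        all_mask_t.copy(identifier=f"follow-{seed}"),
        new_centers,
        int(seed),
        config.domain,
    )
    return LongitudinalSample(baseline, follow_up, new_mask_t, transform)


def generate_contrast_pair(config: PhantomConfig, n_enhancing: int, seed: int) -> ContrastPairSample:
    """Pre/post-contrast pair: the post image adds ``n_enhancing`` bright foci
    plus, if ``config.distractor_on``, a falx-like mid-sagittal enhancing
    plane that is excluded from the ground-truth mask.
    """
    if n_enhancing < 0:
        raise ValueError("n_enhancing must be >= 0")
    rng = np.random.default_rng(seed)
    scene = _background(config, rng)

    distractor = np.zeros(config.grid_shape, dtype=bool)
    existing = []
    if config.distractor_on:
        brain = _ellipsoid_mask(config, config.brain_axes_mm)
        vent = _ellipsoid_mask(config, config.ventricle_axes_mm)
        cx = config.grid_shape[0] // 2
        distractor[cx, :, :] = True
        distractor &= brain & ~vent
        # keep foci clear of the plane: treat it as a fat pseudo-lesion wall
        plane_x = cx * config.spacing_mm[0]
        sep = 2.0 * max(config.spacing_mm)

    for _ in range(10 * config.max_placement_attempts if config.distractor_on else 1):
        mask, centers, _, _ = _place_focal_lesions(config, rng, n_enhancing, existing=existing)
        if not config.distractor_on or not (mask & ndimage.binary_dilation(distractor, iterations=2)).any():
            break
    else:
        raise PlacementError("could not place enhancing foci clear of the distractor plane")

    pre = scene + rng.normal(0.0, config.noise_sd, size=config.grid_shape)
    post = (
        scene
        + config.lesion_contrast * mask
        + config.distractor_contrast * distractor
        + rng.normal(0.0, config.noise_sd, size=config.grid_shape)
    )
    sp = config.spacing_mm
    return ContrastPairSample(
        VolumeGrid(pre, sp, identifier=f"pre-{seed}"),
        VolumeGrid(post, sp, identifier=f"post-{seed}"),
        LabelGrid(mask.astype(np.int16), sp, identifier=f"enh-{seed}"),
        LabelGrid(distractor.astype(np.int16), sp, identifier=f"distractor-{seed}"),
    )


# ---------------------------------------------------------------------------
# persistence


def write_study(sample, directory) -> dict:
    """Write a generated sample as NIfTI-1 files plus a JSON sidecar.

    Returns a dict of logical name -> written path. Accepts StudySample,
    LongitudinalSample and ContrastPairSample.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}

    def put(name, grid):
        paths[name] = str(save_grid(grid, directory / f"{name}.nii.gz"))

    if isinstance(sample, StudySample):
        put("image", sample.image)
        put("lesion_mask", sample.lesion_mask)
        meta = {"seed": sample.seed, "domain": sample.domain, "lesion_centers": sample.lesion_centers}
    elif isinstance(sample, LongitudinalSample):
        put("baseline_image", sample.baseline.image)
        put("baseline_mask", sample.baseline.lesion_mask)
        put("follow_image", sample.follow_up.image)
        put("follow_mask", sample.follow_up.lesion_mask)
        put("new_lesion_mask", sample.new_lesion_mask)
        meta = {
            "seed": sample.baseline.seed,
            "domain": sample.baseline.domain,
            "applied_transform": sample.applied_transform.to_dict(),
        }
    elif isinstance(sample, ContrastPairSample):
        put("pre", sample.pre)
        put("post", sample.post)
        put("enhancing_mask", sample.enhancing_mask)
        put("distractor_mask", sample.distractor_mask)
        meta = {}
    else:
        raise TypeError(f"cannot write sample of type {type(sample)}")
    sidecar = directory / "meta.json"
    save_sidecar(sidecar, meta)
    paths["meta"] = str(sidecar)
    return paths


def read_sidecar(directory) -> dict:
    return json.loads((Path(directory) / "meta.json").read_text())
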