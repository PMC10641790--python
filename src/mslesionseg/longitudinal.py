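"""Longitudinal pair processing: rigid registration and subtraction volumes.

A follow-up scan is rigidly registered to its baseline (mean-squared-error
objective; phase-correlation translation initialization followed by Powell
refinement over the 6 rigid parameters), both volumes are z-normalized and
resampled to isotropic resolution, and the baseline is subtracted from the
registered follow-up. New lesions appear as positive blobs in the
subtraction volume, which is the single input channel of the new-lesion
segmenter.

Deformable registration is deliberately out of scope: the rigid model
matches the phantom generator's inter-scan jitter, and an externally
computed displacement field can be applied upstream if real data demand it.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import optimize
from skimage.registration import phase_cross_correlation

from .grids import VolumeGrid
from .preprocess import resample_isotropic, znormalize
from .transforms import RigidTransform, apply_to_volume

__all__ = [
    "RigidTransform",
    "RegistrationResult",
    "SubtractionVolume",
    "register_rigid",
    "make_subtraction",
    "prepare_pair",
]


@dataclasses.dataclass
class RegistrationResult:
    transform: RigidTransform
    registered: VolumeGrid
    mse: float
    mse_identity: float
    converged: bool  # False: failed to improve on identity; identity returned


@dataclasses.dataclass
class SubtractionVolume:
    """(follow-up - baseline) intensities with provenance."""

    volume: VolumeGrid
    baseline_id: str
    follow_id: str
    transform: RigidTransform | None = None


def _mse(a, b):
    d = a - b
    return float(np.mean(d * d))


def register_rigid(moving: VolumeGrid, fixed: VolumeGrid, max_translation_mm=8.0, max_rotation_deg=8.0):
    """Rigid registration of ``moving`` onto ``fixed`` by MSE minimization.

    Returns a :class:`RegistrationResult`; if optimization fails to improve
    on the identity transform the identity is returned with
    ``converged=False`` (never silently).
    """
    if moving.shape != fixed.shape:
        raise ValueError("registration requires equal shapes (same field of view)")
    center = tuple((np.asarray(fixed.shape) - 1) / 2 * np.asarray(fixed.spacing_mm))
    spacing = np.asarray(fixed.spacing_mm)

    # translation init: phase correlation gives the voxel shift of moving vs fixed
    shift_vox, _, _ = phase_cross_correlation(
        fixed.intensities, moving.intensities, upsample_factor=4, normalization=None
    )
    t0 = np.clip(shift_vox * spacing, -max_translation_mm, max_translation_mm)

    # The MSE objective is evaluated on Gaussian-blurred copies (sigma 1
    # voxel) resampled with cubic splines: resampling a *noisy* image at
    # fractional offsets with linear interpolation smooths its noise, so
    # raw-intensity MSE is minimized slightly away from true alignment (by up
    # to noise_var/2). Pre-blurring plus near-interpolating cubic resampling
    # removes that bias; the returned registered volume still uses linear
    # interpolation, matching the pipeline's stated resampling scheme.
    from scipy import ndimage

    from .transforms import _voxel_affine

    def objective_for(mov_arr, fix_arr, order):
        # prefilter spline coefficients once; each Powell evaluation then
        # only resamples
        coeff = ndimage.spline_filter(mov_arr, order=order) if order > 1 else mov_arr

        def objective(params):
            T = RigidTransform(tuple(params[:3]), tuple(params[3:]), center)
            M, off = _voxel_affine(T, moving.spacing_mm, moving.origin)
            warped = ndimage.affine_transform(
                coeff, M, offset=off, order=order, mode="constant", cval=0.0, prefilter=False
            )
            return _mse(warped, fix_arr)

        return objective

    bounds = [(-max_translation_mm, max_translation_mm)] * 3 + [(-max_rotation_deg, max_rotation_deg)] * 3
    mov_s = ndimage.gaussian_filter(moving.intensities, 1.0)
    fix_s = ndimage.gaussian_filter(fixed.intensities, 1.0)
    res = optimize.minimize(
        objective_for(mov_s, fix_s, 3),
        np.concatenate([t0, np.zeros(3)]),
        method="Powell",
        bounds=bounds,
        options={"xtol": 1e-3, "ftol": 1e-9, "maxiter": 2000},
    )
    mse_id = _mse(moving.intensities, fixed.intensities)
    best = res.x
    best_mse = float(objective_for(moving.intensities, fixed.intensities, 1)(best))
    if best_mse > mse_id:  # optimizer contract: never worse than identity
        T = RigidTransform((0.0, 0.0, 0.0), (0.0, 0.0, 0.0), center)
        return RegistrationResult(T, moving.copy(), mse_id, mse_id, converged=False)
    T = RigidTransform(tuple(best[:3]), tuple(best[3:]), center)
    return RegistrationResult(T, apply_to_volume(moving, T), best_mse, mse_id, converged=True)


def make_subtraction(baseline: VolumeGrid, follow_registered: VolumeGrid, transform=None) -> SubtractionVolume:
    """Voxelwise (follow-up - baseline); inputs are expected normalized and
    resampled, so new lesions manifest as positive blobs."""
    if not baseline.same_geometry(follow_registered):
        raise ValueError("baseline and registered follow-up geometry mismatch")
    diff = follow_registered.intensities - baseline.intensities
    vol = VolumeGrid(
        diff, baseline.spacing_mm, baseline.origin, f"sub-{baseline.identifier}"
    )
    return SubtractionVolume(vol, baseline.identifier, follow_registered.identifier, transform)


def prepare_pair(baseline_raw: VolumeGrid, follow_raw: VolumeGrid, target_mm: float = 1.0) -> SubtractionVolume:
    """Full chain: register follow-up to baseline, z-normalize both, resample
    both to isotropic resolution, subtract. Output geometry is the baseline's
    at ``target_mm`` isotropic."""
    reg = register_rigid(follow_raw, baseline_raw)
    base = resample_isotropic(znormalize(baseline_raw), target_mm)
    follow = resample_isotropic(znormalize(reg.registered), target_mm)
    return make_subtraction(base, follow, reg.transform)
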