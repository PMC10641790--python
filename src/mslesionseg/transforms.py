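"""Rigid 3D transforms in physical (mm) coordinates.

A rigid transform maps a physical point ``p`` to ``R (p - c) + c + t`` where
``R`` is the rotation built from per-axis angles applied in x -> y -> z order
(``R = Rz @ Ry @ Rx``), ``c`` the rotation center and ``t`` the translation.
Volumes are resampled through the *inverse* map so that the image content is
moved by the transform.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .grids import LabelGrid, VolumeGrid

__all__ = ["RigidTransform", "apply_to_volume", "apply_to_label"]


def _rotation_matrix(rotation_deg):
    rx, ry, rz = np.deg2rad(np.asarray(rotation_deg, dtype=float))
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


@dataclasses.dataclass
class RigidTransform:
    """Rigid motion: rotation about ``center`` followed by translation (mm)."""

    translation_mm: tuple = (0.0, 0.0, 0.0)
    rotation_deg: tuple = (0.0, 0.0, 0.0)
    center: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.translation_mm = tuple(float(v) for v in self.translation_mm)
        self.rotation_deg = tuple(float(v) for v in self.rotation_deg)
        self.center = tuple(float(v) for v in self.center)

    @property
    def matrix(self) -> np.ndarray:
        return _rotation_matrix(self.rotation_deg)

    def apply_point(self, p) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        c = np.asarray(self.center)
        return self.matrix @ (p - c) + c + np.asarray(self.translation_mm)

    def inverse(self) -> "RigidTransform":
        # inverse of p -> R(p-c)+c+t is p -> R^T(p-c-t)+c, re-expressed about
        # the same center; R^T is the rotation with negated angles in reverse
        # order, which is not a plain negation of the x->y->z angles, so keep
        # the matrix route and recover angles from it.
        Rinv = self.matrix.T
        t = np.asarray(self.translation_mm)
        # p -> Rinv (p - c) + c + t_inv with t_inv = -Rinv @ t
        return RigidTransform(tuple(-Rinv @ t), _angles_from_matrix(Rinv), self.center)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self after other: (self o other)(p) = self(other(p))."""
        Ra, Rb = self.matrix, other.matrix
        c = np.asarray(self.center)
        # other about its own center re-expressed about self.center
        def as_affine(T):
            R = T.matrix
            cc = np.asarray(T.center)
            b = -R @ cc + cc + np.asarray(T.translation_mm)
            return R, b

        Ra, ba = as_affine(self)
        Rb, bb = as_affine(other)
        R = Ra @ Rb
        b = Ra @ bb + ba
        t = R @ c + b - c  # so that R(p-c)+c+t == R p + b
        return RigidTransform(tuple(t), _angles_from_matrix(R), tuple(c))

    def max_displacement(self, radius_mm: float) -> float:
        """Worst-case displacement (mm) over a sphere of given radius about center."""
        t = np.linalg.norm(self.translation_mm)
        # rotation moves a point at distance r by 2 r sin(theta/2)
        theta = np.arccos(np.clip((np.trace(self.matrix) - 1) / 2, -1, 1))
        return float(t + 2 * radius_mm * np.sin(theta / 2))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d) -> "RigidTransform":
        return cls(tuple(d["translation_mm"]), tuple(d["rotation_deg"]), tuple(d["center"]))


def _angles_from_matrix(R):
    """Recover (rx, ry, rz) in degrees with R = Rz @ Ry @ Rx (no gimbal lock expected)."""
    ry = np.arcsin(np.clip(-R[2, 0], -1, 1))
    if np.isclose(np.cos(ry), 0):  # pragma: no cover - jitters are a few degrees
        rx = np.arctan2(R[0, 1], R[1, 1])
        rz = 0.0
    else:
        rx = np.arctan2(R[2, 1], R[2, 2])
        rz = np.arctan2(R[1, 0], R[0, 0])
    return tuple(np.rad2deg([rx, ry, rz]))


def _voxel_affine(transform: RigidTransform, spacing, origin):
    """Matrix/offset mapping *output* voxel index to *input* voxel index."""
    S = np.diag(spacing)
    Sinv = np.diag(1.0 / np.asarray(spacing, dtype=float))
    Rinv = transform.matrix.T
    c = np.asarray(transform.center)
    t = np.asarray(transform.translation_mm)
    o = np.asarray(origin, dtype=float)
    M = Sinv @ Rinv @ S
    off = Sinv @ (Rinv @ (o - c - t) + c - o)
    return M, off


def apply_to_volume(vol: VolumeGrid, transform: RigidTransform, order: int = 1) -> VolumeGrid:
    """Resample ``vol`` so its content is moved by ``transform`` (linear interp)."""
    M, off = _voxel_affine(transform, vol.spacing_mm, vol.origin)
    out = ndimage.affine_transform(vol.intensities, M, offset=off, order=order, mode="constant", cval=0.0)
    return vol.copy(intensities=out)


def apply_to_label(mask: LabelGrid, transform: RigidTransform) -> LabelGrid:
    """Nearest-neighbour variant for label maps (stays integer)."""
    M, off = _voxel_affine(transform, mask.spacing_mm, mask.origin)
    out = ndimage.affine_transform(mask.labels, M, offset=off, order=0, mode="constant", cval=0)
    return mask.copy(labels=out.astype(mask.labels.dtype))
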