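"""Volumetric data carriers.

A :class:`VolumeGrid` is the universal image container of the pipeline: a 3D
intensity array plus per-axis physical voxel spacing (mm). A
:class:`LabelGrid` carries integer labels (0 background, 1 lesion for binary
masks, component ids for labelled masks) on the same geometry as its paired
image. Both round-trip through NIfTI-1 via nibabel, with the spacing on the
diagonal of the affine.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["VolumeGrid", "LabelGrid", "load_volume", "load_label", "save_grid"]


@dataclasses.dataclass
class VolumeGrid:
    """3D real-valued image with physical spacing.

    Parameters
    ----------
    intensities : ndarray, shape (nx, ny, nz)
        Voxel intensities; must be finite.
    spacing_mm : tuple of 3 floats
        Physical voxel size per axis, all positive.
    origin : tuple of 3 floats
        Physical offset of voxel (0, 0, 0), mm.
    identifier : str
        Study id used for provenance.
    """

    intensities: np.ndarray
    spacing_mm: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)
    identifier: str = ""

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 3:
            raise ValueError(f"expected 3 axes, got {self.intensities.ndim}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing_mm}")
        self.origin = tuple(float(o) for o in self.origin)
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")

    @property
    def shape(self):
        return self.intensities.shape

    def copy(self, intensities=None, identifier=None) -> "VolumeGrid":
        return VolumeGrid(
            self.intensities.copy() if intensities is None else intensities,
            self.spacing_mm,
            self.origin,
            self.identifier if identifier is None else identifier,
        )

    def same_geometry(self, other) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm)
            and np.allclose(self.origin, other.origin)
        )


@dataclasses.dataclass
class LabelGrid:
    """3D non-negative integer label map sharing geometry with its image."""

    labels: np.ndarray
    spacing_mm: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)
    identifier: str = ""

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"expected 3 axes, got {self.labels.ndim}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            rounded = np.rint(self.labels)
            if not np.allclose(self.labels, rounded):
                raise ValueError("labels must be integers")
            self.labels = rounded.astype(np.int32)
        if self.labels.min(initial=0) < 0:
            raise ValueError("labels must be non-negative")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing_mm}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self):
        return self.labels.shape

    @property
    def is_binary(self) -> bool:
        return bool(np.isin(self.labels, (0, 1)).all())

    def copy(self, labels=None, identifier=None) -> "LabelGrid":
        return LabelGrid(
            self.labels.copy() if labels is None else labels,
            self.spacing_mm,
            self.origin,
            self.identifier if identifier is None else identifier,
        )

    def same_geometry(self, other) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm)
            and np.allclose(self.origin, other.origin)
        )


def _affine(spacing_mm, origin):
    aff = np.diag(list(spacing_mm) + [1.0])
    aff[:3, 3] = origin
    return aff


def save_grid(grid, path) -> Path:
    """Write a VolumeGrid or LabelGrid as NIfTI-1 (spacing on the affine diagonal)."""
    path = Path(path)
    data = grid.intensities if isinstance(grid, VolumeGrid) else grid.labels
    dtype = np.float32 if isinstance(grid, VolumeGrid) else np.int16
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype), _affine(grid.spacing_mm, grid.origin))
    img.header.set_zooms(grid.spacing_mm)
    nib.save(img, str(path))
    return path


def _load(path):
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return data, spacing, origin


def load_volume(path, identifier="") -> VolumeGrid:
    data, spacing, origin = _load(path)
    return VolumeGrid(np.asarray(data, dtype=np.float64), spacing, origin, identifier or Path(path).stem)


def load_label(path, identifier="") -> LabelGrid:
    data, spacing, origin = _load(path)
    return LabelGrid(np.asarray(np.rint(data), dtype=np.int32), spacing, origin, identifier or Path(path).stem)


def save_sidecar(path, payload: dict) -> Path:
    """JSON sidecar for provenance (seed, config) next to a NIfTI file."""
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=_json_default))
    return path


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
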