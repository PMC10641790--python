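"""Lesionwise detection metrics.

A "lesion" is a connected component of a binary mask under a configurable
neighbourhood (6/18/26; default 26). Matching is overlap-based with
asymmetric denominators, the standard resolution of many-to-many matches in
detection scoring:

* **sensitivity** counts ground-truth components: a true lesion is detected
  if it shares at least ``overlap_criterion`` voxels with the union of
  predictions (one predicted blob spanning two true lesions detects both);
* **PPV** counts predicted components: a predicted lesion is a true positive
  if it shares at least ``overlap_criterion`` voxels with the union of truth.

Sensitivity is undefined when a study has no true lesions and PPV when a
model predicts nothing; undefined values are flagged and excluded from
aggregation. Per-set aggregation reports mean +/- standard error (sample
SD / sqrt(n)).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .grids import LabelGrid

__all__ = [
    "EvalConfig",
    "LesionMatchResult",
    "MetricSummary",
    "label_components",
    "lesionwise_metrics",
    "dice_score",
    "summarize",
]

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclasses.dataclass
class EvalConfig:
    connectivity: int = 26
    overlap_criterion: int = 1  # minimum overlapping voxels for a match
    min_lesion_voxels: int = 1  # no minimum lesion size by default

    def __post_init__(self):
        if self.connectivity not in _STRUCTURES:
            raise ValueError("connectivity must be 6, 18 or 26")
        if self.overlap_criterion < 1:
            raise ValueError("overlap_criterion must be >= 1")
        if self.min_lesion_voxels < 1:
            raise ValueError("min_lesion_voxels must be >= 1")


@dataclasses.dataclass
class LesionMatchResult:
    """Per-study lesionwise counts and the derived sensitivity/PPV."""

    n_true: int
    n_pred: int
    tp_true: int  # true components overlapped by any prediction
    tp_pred: int  # predicted components overlapping any truth

    @property
    def fn(self) -> int:
        return self.n_true - self.tp_true

    @property
    def fp(self) -> int:
        return self.n_pred - self.tp_pred

    @property
    def sensitivity(self):
        return self.tp_true / self.n_true if self.n_true > 0 else None

    @property
    def ppv(self):
        return self.tp_pred / self.n_pred if self.n_pred > 0 else None

    @property
    def sensitivity_defined(self) -> bool:
        return self.n_true > 0

    @property
    def ppv_defined(self) -> bool:
        return self.n_pred > 0


@dataclasses.dataclass
class MetricSummary:
    values: list
    mean: float
    standard_error: float
    n: int


def _check_binary(mask: LabelGrid, name):
    if not mask.is_binary:
        raise ValueError(f"{name} mask must be binary (values in {{0, 1}})")


def label_components(mask: LabelGrid, connectivity: int = 26, min_lesion_voxels: int = 1):
    """Label connected components; returns (LabelGrid of ids, count).

    Components smaller than ``min_lesion_voxels`` are removed before id
    assignment, so ids are contiguous 1..count.
    """
    _check_binary(mask, "input")
    lab, n = ndimage.label(mask.labels > 0, structure=_STRUCTURES[connectivity])
    if min_lesion_voxels > 1 and n > 0:
        sizes = np.bincount(lab.ravel())
        keep = np.flatnonzero(sizes >= min_lesion_voxels)
        keep = keep[keep > 0]
        remap = np.zeros(n + 1, dtype=np.int32)
        remap[keep] = np.arange(1, len(keep) + 1)
        lab = remap[lab]
        n = len(keep)
    return mask.copy(labels=lab.astype(np.int32)), int(n)


def lesionwise_metrics(pred: LabelGrid, truth: LabelGrid, cfg: EvalConfig = EvalConfig()) -> LesionMatchResult:
    """Lesionwise TP/FP/FN counts between a predicted and a truth mask."""
    if not pred.same_geometry(truth):
        raise ValueError("pred and truth geometry mismatch")
    _check_binary(pred, "pred")
    _check_binary(truth, "truth")
    t_lab, n_true = label_components(truth, cfg.connectivity, cfg.min_lesion_voxels)
    p_lab, n_pred = label_components(pred, cfg.connectivity, cfg.min_lesion_voxels)
    tp_true = _n_overlapping(t_lab.labels, n_true, p_lab.labels > 0, cfg.overlap_criterion)
    tp_pred = _n_overlapping(p_lab.labels, n_pred, t_lab.labels > 0, cfg.overlap_criterion)
    return LesionMatchResult(n_true, n_pred, tp_true, tp_pred)


def _n_overlapping(lab, n, other_fg, min_overlap):
    if n == 0:
        return 0
    overlap = np.bincount(lab[other_fg].ravel(), minlength=n + 1)
    return int(np.count_nonzero(overlap[1:] >= min_overlap))


def dice_score(pred: LabelGrid, truth: LabelGrid) -> float:
    """Voxel-overlap Dice 2|A.B| / (|A|+|B|); 1.0 when both masks are empty."""
    if not pred.same_geometry(truth):
        raise ValueError("pred and truth geometry mismatch")
    _check_binary(pred, "pred")
    _check_binary(truth, "truth")
    a = pred.labels > 0
    b = truth.labels > 0
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def summarize(values) -> MetricSummary:
    """Mean and standard error (sample SD / sqrt(n)); SE is 0 for n = 1."""
    vals = [float(v) for v in values]
    if not vals:
        raise ValueError("cannot summarize an empty list")
    n = len(vals)
    mean = float(np.mean(vals))
    se = float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return MetricSummary(vals, mean, se, n)
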