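"""Voxel-wise confusion counting and segmentation overlap metrics.

Comparing a predicted binary mask against ground truth classifies every
voxel as TP/TN/FP/FN; the four indicators are

    Dice = 2TP / (2TP + FP + FN)
    Sensitivity = TP / (TP + FN)
    Specificity = TN / (TN + FP)
    VOE  = 1 - TP / (TP + FP + FN)   (one minus the Jaccard index)

Dice and VOE are linked algebraically: VOE = 1 - Dice / (2 - Dice).
Degenerate empty-vs-empty comparisons score as perfect (with a warning) so
batch evaluation never raises.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .volume_io import MaskVolume

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "dice",
    "sensitivity",
    "specificity",
    "voe",
    "evaluate_masks",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    dice: float
    sensitivity: float
    specificity: float
    voe: float
    counts: ConfusionCounts

    def as_dict(self) -> dict:
        return {
            "dice": self.dice,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "voe": self.voe,
            "tp": self.counts.tp,
            "tn": self.counts.tn,
            "fp": self.counts.fp,
            "fn": self.counts.fn,
        }


def _as_binary(x, name):
    a = x.voxels if isinstance(x, MaskVolume) else np.asarray(x)
    if not np.isin(np.unique(a), (0, 1)).all():
        raise ValueError(f"{name} is not binary")
    return a.astype(bool)


def confusion(pred, truth) -> ConfusionCounts:
    """Exhaustive voxel classification of prediction against ground truth."""
    p = _as_binary(pred, "prediction")
    t = _as_binary(truth, "truth")
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = p.size - tp - fp - fn
    return ConfusionCounts(tp, tn, fp, fn)


def _ratio(num, den, empty_value, what):
    if den == 0:
        warnings.warn(f"degenerate {what}: empty denominator, returning {empty_value}")
        return float(empty_value)
    return num / den


def dice(c: ConfusionCounts) -> float:
    return _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, 1.0, "Dice")


def sensitivity(c: ConfusionCounts) -> float:
    return _ratio(c.tp, c.tp + c.fn, 1.0, "sensitivity")


def specificity(c: ConfusionCounts) -> float:
    return _ratio(c.tn, c.tn + c.fp, 1.0, "specificity")


def voe(c: ConfusionCounts) -> float:
    if c.tp + c.fp + c.fn == 0:
        warnings.warn("degenerate VOE: empty denominator, returning 0.0")
        return 0.0
    return 1.0 - c.tp / (c.tp + c.fp + c.fn)


def evaluate_masks(pred, truth) -> MetricsReport:
    """All four indicators plus the underlying counts for one mask pair."""
    c = confusion(pred, truth)
    return MetricsReport(dice(c), sensitivity(c), specificity(c), voe(c), c)
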