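"""Segmentation evaluation metrics on binary mask pairs.

Overlap metrics come from the confusion counts TP/FP/TN/FN:
DSC = 2TP/(2TP+FP+FN), IoU = TP/(TP+FP+FN), Accuracy, Specificity,
Sensitivity, Precision.  Fractions are reported x100 (percent), matching
how segmentation results are conventionally printed.

Surface metrics use the symmetric surface-distance construction: the
surface of a mask is its foreground pixels with at least one background
4-neighbour (the image border counts as background); directed distances
are Euclidean nearest-surface distances, pooled over both directions;
HD95 is the 95th percentile (linear interpolation between order
statistics) and ASSD the mean of the pooled set, in pixel units.

Conventions for degenerate pairs: both masks empty -> perfect agreement
(DSC=IoU=100, HD95=ASSD=0); exactly one empty -> DSC=IoU=0 and
HD95=ASSD=image diagonal (a finite sentinel).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = ["MetricsReport", "overlap_metrics", "surface_distances", "evaluate_pair",
           "dice_coefficient"]

_FOUR_NEIGHBOUR = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool)


@dataclass
class MetricsReport:
    """Per-case metric values; fractions in percent, distances in pixels."""

    dsc: float
    iou: float
    accuracy: float
    specificity: float
    sensitivity: float
    precision: float
    hd95: float = float("nan")
    assd: float = float("nan")

    def as_dict(self):
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _validate_pair(prediction, truth):
    p = np.asarray(prediction)
    g = np.asarray(truth)
    if p.shape != g.shape:
        raise ValueError(f"mask shapes differ: {p.shape} vs {g.shape}")
    for name, m in (("prediction", p), ("truth", g)):
        if not np.all((m == 0) | (m == 1)):
            raise ValueError(f"{name} mask must be binary")
    return p.astype(bool), g.astype(bool)


def _safe(num, den, empty_value=1.0):
    return num / den if den > 0 else empty_value


def overlap_metrics(prediction, truth) -> MetricsReport:
    p, g = _validate_pair(prediction, truth)
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    tn = int(np.count_nonzero(~p & ~g))
    return MetricsReport(
        dsc=100.0 * _safe(2 * tp, 2 * tp + fp + fn),
        iou=100.0 * _safe(tp, tp + fp + fn),
        accuracy=100.0 * _safe(tp + tn, tp + fp + fn + tn),
        specificity=100.0 * _safe(tn, tn + fp),
        sensitivity=100.0 * _safe(tp, tp + fn),
        precision=100.0 * _safe(tp, tp + fp),
    )


def dice_coefficient(prediction, truth) -> float:
    """Confusion-count Dice as a fraction in [0, 1] (evaluation form)."""
    return overlap_metrics(prediction, truth).dsc / 100.0


def _surface_pixels(mask):
    """Foreground pixels with a background 4-neighbour; border is background."""
    eroded = ndimage.binary_erosion(mask, structure=_FOUR_NEIGHBOUR, border_value=0)
    return np.argwhere(mask & ~eroded)


def surface_distances(prediction, truth):
    """(HD95, ASSD) in pixel units, symmetric in the two masks."""
    p, g = _validate_pair(prediction, truth)
    p_any, g_any = bool(p.any()), bool(g.any())
    if not p_any and not g_any:
        return 0.0, 0.0
    if p_any != g_any:
        diag = math.hypot(*p.shape)
        return diag, diag
    sp = _surface_pixels(p).astype(np.float64)
    sg = _surface_pixels(g).astype(np.float64)
    d_pg, _ = cKDTree(sg).query(sp, k=1)
    d_gp, _ = cKDTree(sp).query(sg, k=1)
    pooled = np.concatenate([d_pg, d_gp])
    return float(np.percentile(pooled, 95)), float(pooled.mean())


def evaluate_pair(prediction, truth) -> MetricsReport:
    """Full eight-metric report for one mask pair."""
    report = overlap_metrics(prediction, truth)
    report.hd95, report.assd = surface_distances(prediction, truth)
    return report
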