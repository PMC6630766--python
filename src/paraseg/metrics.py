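"""Segmentation evaluation: DSC, sensitivity/specificity, Hausdorff distance.

Conventions for degenerate inputs follow common medical-imaging practice:
DSC of two empty masks is 1 (perfect agreement about absence); the
Hausdorff distance is undefined (NaN) when either mask is empty; a rate
with a zero denominator is NaN and excluded from aggregation. The Hausdorff
distance is computed between 8-connectivity boundary pixels using an exact
Euclidean distance transform and reported in millimetres via the pixel
spacing.

Note on the sensitivity formula: the source formulation of TPR prints
``TP / (TP + TN)``, which contradicts the name "sensitivity"; the standard
``TP / (TP + FN)`` is implemented, with the printed form available behind
``printed_eq_compat=True`` for auditing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

_8CONN = np.ones((3, 3), dtype=bool)


def _check_pair(seg: np.ndarray, gt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    seg = np.asarray(seg)
    gt = np.asarray(gt)
    if seg.shape != gt.shape:
        raise ValueError(f"shape mismatch: {seg.shape} vs {gt.shape}")
    return seg > 0, gt > 0


def dsc(seg: np.ndarray, gt: np.ndarray) -> float:
    """Dice similarity coefficient ``2|A∩B| / (|A|+|B|)``; 1 if both empty."""
    s, g = _check_pair(seg, gt)
    denom = s.sum() + g.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(s, g).sum() / denom


@dataclass(frozen=True)
class ConfusionCounts:
    true_positive: int
    false_positive: int
    true_negative: int
    false_negative: int

    @property
    def total(self) -> int:
        return (self.true_positive + self.false_positive
                + self.true_negative + self.false_negative)


def confusion(seg: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    """Pixelwise confusion counts with ``gt`` as the reference."""
    s, g = _check_pair(seg, gt)
    tp = int(np.logical_and(s, g).sum())
    fp = int(np.logical_and(s, ~g).sum())
    fn = int(np.logical_and(~s, g).sum())
    tn = int(np.logical_and(~s, ~g).sum())
    return ConfusionCounts(tp, fp, tn, fn)


def tpr_tnr(c: ConfusionCounts, printed_eq_compat: bool = False
            ) -> tuple[float, float]:
    """Return (sensitivity, specificity); NaN where the denominator is zero."""
    tp, fp, tn, fn = (c.true_positive, c.false_positive,
                      c.true_negative, c.false_negative)
    tpr_den = tp + tn if printed_eq_compat else tp + fn
    if tpr_den == 0:
        warnings.warn("TPR undefined (empty denominator); reporting NaN")
        tpr = float("nan")
    else:
        tpr = tp / tpr_den
    if fp + tn == 0:
        warnings.warn("TNR undefined (empty denominator); reporting NaN")
        tnr = float("nan")
    else:
        tnr = tn / (fp + tn)
    return tpr, tnr


def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """Boundary of a binary mask: pixels removed by 8-connected erosion."""
    m = np.asarray(mask) > 0
    er = ndimage.binary_erosion(m, structure=_8CONN, border_value=0)
    return m & ~er


def hausdorff_mm(seg: np.ndarray, gt: np.ndarray, spacing_w: float) -> float:
    """Symmetric Hausdorff distance between mask boundaries, in mm.

    ``max(h(A,B), h(B,A))`` with ``h(A,B) = max_{a∈A} min_{b∈B} ||a-b||``
    over boundary pixels, scaled by ``spacing_w``. NaN (with a warning) if
    either mask is empty.
    """
    if not spacing_w > 0:
        raise ValueError("spacing_w must be positive")
    s, g = _check_pair(seg, gt)
    if not s.any() or not g.any():
        warnings.warn("Hausdorff distance undefined for an empty mask")
        return float("nan")
    bs = boundary_pixels(s)
    bg = boundary_pixels(g)
    # exact EDT to the nearest boundary pixel of the other mask
    dt_s = ndimage.distance_transform_edt(~bs)
    dt_g = ndimage.distance_transform_edt(~bg)
    h_gs = dt_s[bg].max()   # farthest gt-boundary pixel from seg boundary
    h_sg = dt_g[bs].max()
    return float(max(h_gs, h_sg)) * float(spacing_w)


@dataclass
class MetricReport:
    """Per-image metric rows plus mean/std aggregates."""

    per_image: pd.DataFrame           # identifier, dsc, tpr, tnr, hd_mm
    mean: pd.Series
    std: pd.Series

    def summary(self) -> str:
        parts = [f"{m}: {self.mean[m]:.3f} ± {self.std[m]:.3f}"
                 for m in self.mean.index]
        return ", ".join(parts)


def evaluate_pair(identifier: str, seg: np.ndarray, gt: np.ndarray,
                  spacing_w: float) -> dict:
    """All four metrics for one segmentation/reference pair."""
    c = confusion(seg, gt)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tpr, tnr = tpr_tnr(c)
        hd = hausdorff_mm(seg, gt, spacing_w)
    return {"identifier": identifier, "dsc": dsc(seg, gt),
            "tpr": tpr, "tnr": tnr, "hd_mm": hd}


def aggregate(rows: list[dict]) -> MetricReport:
    """Mean and sample standard deviation per metric; NaN rows excluded
    per metric (ddof=1; std is 0 for a single row)."""
    if not rows:
        raise ValueError("cannot aggregate an empty row list")
    frame = pd.DataFrame(rows)
    metrics = [c for c in frame.columns if c != "identifier"]
    mean = frame[metrics].mean(skipna=True)
    std = frame[metrics].std(ddof=1, skipna=True).fillna(0.0)
    return MetricReport(per_image=frame, mean=mean, std=std)
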