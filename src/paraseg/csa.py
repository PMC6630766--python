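"""Cross-sectional-area measurement and method-agreement analysis.

From a per-pixel probability map ``P`` of side ``L`` with pixel spacing
``w`` (mm), the muscle CSA is obtained by binarising at a threshold,
averaging to the area fraction ``F = mean(B)``, and scaling to physical
units ``A = F * (w * L)**2`` (mm^2). Agreement between automatic and manual
areas is assessed by simple linear regression (slope ``b1``, intercept
``b0``, coefficient of determination R^2) and by Bland–Altman analysis
(mean difference, SD of differences, limits of agreement at mean ± 1.96 SD,
and the fraction of points inside the limits; about 95% is expected for
normally distributed differences).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class CsaMeasurement:
    identifier: str
    area_fraction: float          # dimensionless F in [0, 1]
    physical_area_mm2: float      # A = F * (w * L)**2
    source: str = "automatic"     # "automatic" | "manual"


def measure_csa(p: np.ndarray, spacing_w: float, threshold: float = 0.5,
                identifier: str = "", source: str = "automatic") -> CsaMeasurement:
    """Binarise a square probability map and convert to physical area."""
    p = np.asarray(p)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError(f"probability map must be square 2-D, got {p.shape}")
    if not spacing_w > 0:
        raise ValueError("spacing_w must be positive")
    b = p >= threshold
    f = float(b.mean())
    side_mm = spacing_w * p.shape[0]
    return CsaMeasurement(identifier=identifier, area_fraction=f,
                          physical_area_mm2=f * side_mm * side_mm,
                          source=source)


def mask_from_annotation(curve_raster: np.ndarray, threshold: float = 0.5
                         ) -> np.ndarray:
    """Convert a rasterised closed-curve annotation to a filled binary mask.

    The raster is thresholded and the enclosed region flood-filled. An
    already-solid mask passes through unchanged. A curve that does not
    close (nothing to fill and no interior) raises ``ValueError``.
    """
    curve = np.asarray(curve_raster) > threshold
    if not curve.any():
        raise ValueError("annotation raster is empty")
    filled = ndimage.binary_fill_holes(curve)
    if filled.sum() == curve.sum():
        # nothing was filled: either already solid, or an open curve
        interior = ndimage.binary_erosion(curve, np.ones((3, 3), dtype=bool))
        if not interior.any():
            raise ValueError(
                "annotation curve does not close: no enclosed interior "
                "(the contour leaks to the outside)")
    return filled.astype(np.uint8)


def linear_regression(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares fit ``y = b0 + b1 x``; returns ``(b0, b1, r_squared)``.

    ``b1 = sum((x-xbar)(y-ybar)) / sum((x-xbar)^2)``, ``b0 = ybar - b1*xbar``
    and ``R^2 = 1 - SS_res / SS_tot``.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    xbar, ybar = x.mean(), y.mean()
    sxx = ((x - xbar) ** 2).sum()
    if sxx == 0:
        raise ValueError("x is constant; the slope is undefined")
    b1 = ((x - xbar) * (y - ybar)).sum() / sxx
    b0 = ybar - b1 * xbar
    ss_res = ((y - (b0 + b1 * x)) ** 2).sum()
    ss_tot = ((y - ybar) ** 2).sum()
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(b0), float(b1), float(r2)


@dataclass(frozen=True)
class BlandAltmanStats:
    mean_diff: float
    sd_diff: float
    lower_limit: float
    upper_limit: float
    fraction_within_limits: float
    n: int


def bland_altman(m1: np.ndarray, m2: np.ndarray) -> BlandAltmanStats:
    """Bland–Altman statistics for paired measurements (``d = m1 - m2``).

    Limits of agreement at ``mean(d) ± 1.96 * sd(d)`` with the sample SD.
    Degenerate zero-spread differences count as within the (zero-width)
    limits.
    """
    m1 = np.asarray(m1, dtype=np.float64)
    m2 = np.asarray(m2, dtype=np.float64)
    if m1.shape != m2.shape or m1.ndim != 1:
        raise ValueError("m1 and m2 must be paired 1-D arrays")
    if m1.size < 3:
        raise ValueError("need at least 3 pairs")
    d = m1 - m2
    mean_diff = float(d.mean())
    sd = float(d.std(ddof=1))
    lo = mean_diff - 1.96 * sd
    hi = mean_diff + 1.96 * sd
    within = float(np.mean((d >= lo) & (d <= hi)))
    return BlandAltmanStats(mean_diff=mean_diff, sd_diff=sd, lower_limit=lo,
                            upper_limit=hi, fraction_within_limits=within,
                            n=int(d.size))


@dataclass(frozen=True)
class AgreementReport:
    slope: float
    intercept: float
    r_squared: float
    bland_altman: BlandAltmanStats

    def to_dict(self) -> dict:
        ba = self.bland_altman
        return {"slope": self.slope, "intercept": self.intercept,
                "r_squared": self.r_squared,
                "bland_altman": {
                    "mean_diff": ba.mean_diff, "sd_diff": ba.sd_diff,
                    "lower_limit": ba.lower_limit, "upper_limit": ba.upper_limit,
                    "fraction_within_limits": ba.fraction_within_limits,
                    "n": ba.n}}


def agreement(auto_areas: np.ndarray, manual_areas: np.ndarray) -> AgreementReport:
    """Full agreement analysis: regression of manual on automatic areas
    (``x`` = automatic/predicted, ``y`` = manual/true) plus Bland–Altman of
    automatic minus manual."""
    b0, b1, r2 = linear_regression(auto_areas, manual_areas)
    ba = bland_altman(auto_areas, manual_areas)
    return AgreementReport(slope=b1, intercept=b0, r_squared=r2, bland_altman=ba)


def bland_altman_plot(m1: np.ndarray, m2: np.ndarray, ax=None,
                      label_1: str = "automatic", label_2: str = "manual"):
    """Difference-vs-mean plot with the limits of agreement drawn in.

    Requires matplotlib (``paraseg[plot]``); returns the axes.
    """
    import matplotlib.pyplot as plt

    stats = bland_altman(m1, m2)
    m1 = np.asarray(m1, dtype=np.float64)
    m2 = np.asarray(m2, dtype=np.float64)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter((m1 + m2) / 2.0, m1 - m2, s=12, alpha=0.7)
    for y, style in ((stats.mean_diff, "-"),
                     (stats.lower_limit, "--"), (stats.upper_limit, "--")):
        ax.axhline(y, linestyle=style, color="k", linewidth=1)
    ax.set_xlabel(f"mean of {label_1} and {label_2}")
    ax.set_ylabel(f"{label_1} − {label_2}")
    return ax
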