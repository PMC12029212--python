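"""Classification of genomic bins in SON-vs-LMNB1 TSA-seq scatter space.

Three printed rules from scatterplot analysis of speckle (SON) versus
lamina (LMNB1) TSA-seq scores:

* H1 ROI lines — bins strictly below LMNB1 = -1.5*SON - 1.3 are regions of
  interest; within them, bins below LMNB1 = -1.5*SON - 2.2 are ROI-C2 and
  the rest ROI-C1.
* LAD quadrants — LAD bins split into C1..C4 quadrants around the center
  (SON = -3.0, LMNB1 = 0.25): C1 top-left, C2 top-right, C3 bottom-left,
  C4 bottom-right (top/right include the boundary).
* Equatorial LAD clusters — LAD bins with LMNB1 TSA > 0.75 are equatorial
  (EQ, cluster 1; takes precedence); else SON TSA < 0.98 marks
  non-equatorial (cluster 2).

Plus count-thresholded 2D overlay histograms (per-pixel mean of an overlay
value, masked below a minimum bin count).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "classify_h1_roi",
    "classify_quadrant",
    "classify_eq_lads",
    "overlay_histogram",
    "OverlayGrid",
]


def classify_h1_roi(
    son,
    lmnb1,
    slope: float = -1.5,
    roi_intercept: float = -1.3,
    c2_intercept: float = -2.2,
) -> np.ndarray:
    """ROI classification by the two off-diagonal scatterplot lines.

    A bin is ROI iff lmnb1 < slope*son + roi_intercept (strict); within the
    ROI, C2 iff lmnb1 < slope*son + c2_intercept, else C1.
    Returns an array over {'ROI_C1', 'ROI_C2', 'none'}.
    """
    son = np.asarray(son, dtype=float)
    lmnb1 = np.asarray(lmnb1, dtype=float)
    roi = lmnb1 < slope * son + roi_intercept
    c2 = lmnb1 < slope * son + c2_intercept
    return np.where(c2, "ROI_C2", np.where(roi, "ROI_C1", "none"))


def classify_quadrant(son, lmnb1, center: tuple[float, float] = (-3.0, 0.25)) -> np.ndarray:
    """Quadrant classes of LAD bins around ``center`` = (SON, LMNB1).

    left iff son < center[0]; top iff lmnb1 >= center[1] (boundaries go
    right/top).  C1 = top-left, C2 = top-right, C3 = bottom-left,
    C4 = bottom-right.
    """
    son = np.asarray(son, dtype=float)
    lmnb1 = np.asarray(lmnb1, dtype=float)
    left = son < center[0]
    top = lmnb1 >= center[1]
    return np.where(
        top, np.where(left, "C1", "C2"), np.where(left, "C3", "C4")
    )


def classify_eq_lads(
    son,
    lmnb1,
    is_lad,
    lmnb1_thresh: float = 0.75,
    son_thresh: float = 0.98,
) -> np.ndarray:
    """Equatorial / non-equatorial LAD clusters of flat (HFF-like) nuclei.

    EQ (cluster 1) iff lmnb1 > lmnb1_thresh, taking precedence; else nonEQ
    (cluster 2) iff son < son_thresh; else 'none'.  Raises if any bin is not
    a LAD (the rule is defined on LAD bins only).
    """
    son = np.asarray(son, dtype=float)
    lmnb1 = np.asarray(lmnb1, dtype=float)
    is_lad = np.asarray(is_lad, dtype=bool)
    if not is_lad.all():
        raise ValueError("classify_eq_lads applies to LAD bins only")
    eq = lmnb1 > lmnb1_thresh
    noneq = ~eq & (son < son_thresh)
    return np.where(eq, "EQ_cluster1", np.where(noneq, "nonEQ_cluster2", "none"))


@dataclass
class OverlayGrid:
    """A 2D histogram with per-pixel counts and count-thresholded means."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    count: np.ndarray  # shape (nx, ny)
    mean: np.ndarray  # NaN where count < min_count
    min_count: int

    @property
    def total_count(self) -> int:
        return int(self.count.sum())

    def to_frame(self) -> pd.DataFrame:
        """Long-format export (x_lo, y_lo, count, mean)."""
        xi, yi = np.nonzero(self.count)
        return pd.DataFrame(
            {
                "x_lo": self.x_edges[xi],
                "y_lo": self.y_edges[yi],
                "count": self.count[xi, yi],
                "mean": self.mean[xi, yi],
            }
        )


def overlay_histogram(
    x,
    y,
    value=None,
    pixel: float = 0.1,
    min_count: int = 10,
) -> OverlayGrid:
    """Count-thresholded 2D overlay histogram in scatter space.

    Pixels are ``pixel``-sized squares with edges snapped to multiples of
    ``pixel``.  The per-pixel mean of ``value`` is reported only where at
    least ``min_count`` genomic bins fall in the pixel (masked NaN
    elsewhere); counts are kept for every pixel, so the total count always
    equals the number of input bins.
    """
    if pixel <= 0:
        raise ValueError("pixel must be positive")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if value is None:
        value = np.zeros_like(x)
    value = np.asarray(value, dtype=float)
    if x.size == 0:
        z = np.zeros((0, 0))
        return OverlayGrid(np.empty(0), np.empty(0), z, z.copy(), min_count)
    x0 = np.floor(x.min() / pixel) * pixel
    y0 = np.floor(y.min() / pixel) * pixel
    nx = int(np.floor((x.max() - x0) / pixel)) + 1
    ny = int(np.floor((y.max() - y0) / pixel)) + 1
    xi = np.minimum(((x - x0) / pixel).astype(int), nx - 1)
    yi = np.minimum(((y - y0) / pixel).astype(int), ny - 1)
    count = np.zeros((nx, ny))
    vsum = np.zeros((nx, ny))
    np.add.at(count, (xi, yi), 1)
    np.add.at(vsum, (xi, yi), value)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(count >= min_count, vsum / np.where(count > 0, count, 1), np.nan)
    return OverlayGrid(
        x_edges=x0 + pixel * np.arange(nx),
        y_edges=y0 + pixel * np.arange(ny),
        count=count,
        mean=mean,
        min_count=min_count,
    )
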