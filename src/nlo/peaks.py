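"""SON TSA-seq local-maximum peak calling and Type I/II classification.

Pipeline: LOESS-smooth the score track, apply a centered local maximum
filter of half-width ``w`` bins, and keep bins whose smoothed value equals
the window maximum while every other value in the window is strictly
smaller (the max-filter minus smoothed difference is negative off-apex and
zero at the apex).  The (span, w) pair is chosen by maximizing peak
agreement between two replicates over a grid.  Peaks are typed by the Hi-C
subcompartment overlapping the apex: A1 -> Type I, A2/B1 -> Type II.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter1d

from .tracks import BinnedTrack, loess_smooth

__all__ = [
    "max_filter",
    "call_peaks",
    "peak_agreement",
    "optimize_parameters",
    "classify_peaks",
    "match_peaks",
    "write_peaks_bed",
]


def max_filter(values: np.ndarray, w: int) -> np.ndarray:
    """Maximum over the centered window [i-w, i+w], clipped at vector ends.

    Missing (NaN) values are ignored inside windows; a window with no finite
    value yields NaN.
    """
    if w < 1:
        raise ValueError("w must be >= 1")
    v = np.asarray(values, dtype=float)
    filled = np.where(np.isfinite(v), v, -np.inf)
    out = maximum_filter1d(filled, size=2 * w + 1, mode="constant", cval=-np.inf)
    return np.where(np.isinf(out), np.nan, out)


def _apexes_1d(sm: np.ndarray, w: int) -> list[int]:
    """Strict-local-maximum apex bins of one smoothed chromosome vector.

    Values within a relative 1e-9 tolerance are treated as tied, so
    floating-point jitter on flat stretches cannot fabricate apexes.
    """
    n = len(sm)
    mf = max_filter(sm, w)
    finite = np.isfinite(sm)
    eps = 1e-9 * np.maximum(1.0, np.abs(sm))
    cand = finite & (sm >= mf - eps)
    apexes: list[int] = []
    i = 0
    while i < n:
        if not cand[i]:
            i += 1
            continue
        # plateau: run of (tolerance-)equal-valued candidate bins
        j = i
        while j + 1 < n and cand[j + 1] and abs(sm[j + 1] - sm[i]) <= eps[i]:
            j += 1
        if i == 0 or j == n - 1:
            i = j + 1  # endpoints are not strict interior maxima
            continue
        lo, hi = max(0, i - w), min(n, j + 1 + w)
        window = sm[lo:hi].copy()
        window[i - lo : j + 1 - lo] = np.nan  # exclude the plateau itself
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            wmax = np.nanmax(window)
        if np.isfinite(wmax) and wmax < sm[i] - eps[i]:
            apexes.append(int(round((i + j) / 2)))
        i = j + 1
    return apexes


def call_peaks(track: BinnedTrack, span: float = 0.005, w: int = 50) -> pd.DataFrame:
    """Call local-maximum peaks on a (speckle TSA-seq) track.

    Returns a DataFrame (chrom, apex_bin, apex_bp, score, type) sorted by
    position, with the parameters echoed in ``df.attrs``.  ``apex_bp`` is
    the apex-bin midpoint.  Plateaus of equal smoothed values yield a single
    apex at the plateau centroid; plateaus touching a chromosome end are not
    peaks.  Chromosomes shorter than 2w+1 bins are processed with clipped
    windows (a warning is emitted).
    """
    sm_track = loess_smooth(track, span)
    rows = []
    for chrom in sm_track.data:
        sm = sm_track.data[chrom]
        if len(sm) < 2 * w + 1:
            warnings.warn(f"chromosome {chrom} shorter than 2w+1 bins; windows clipped")
        for b in _apexes_1d(sm, w):
            rows.append(
                (chrom, b, int((b + 0.5) * track.bin_size), float(sm[b]), "unclassified")
            )
    df = pd.DataFrame(rows, columns=["chrom", "apex_bin", "apex_bp", "score", "type"])
    df = df.sort_values(["chrom", "apex_bin"]).reset_index(drop=True)
    df.attrs.update(span=span, w=w, bin_size=track.bin_size, source=track.assay)
    return df


def match_peaks(a: pd.DataFrame, b: pd.DataFrame, tol: int = 2) -> list[tuple[int, int]]:
    """Greedy nearest-first one-to-one matching of apexes within ``tol`` bins.

    Returns (row-index-in-a, row-index-in-b) pairs.  Candidate pairs are
    taken in order of increasing apex distance (ties by position) so each
    apex matches its nearest available partner.
    """
    pairs: list[tuple[int, int, int]] = []
    for chrom in set(a["chrom"]).intersection(b["chrom"]):
        ia = a.index[a["chrom"] == chrom]
        ib = b.index[b["chrom"] == chrom]
        for i in ia:
            for j in ib:
                d = abs(int(a.at[i, "apex_bin"]) - int(b.at[j, "apex_bin"]))
                if d <= tol:
                    pairs.append((d, i, j))
    pairs.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    matched = []
    for _, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matched.append((i, j))
    return matched


def peak_agreement(a: pd.DataFrame, b: pd.DataFrame, tol: int = 2) -> float:
    """Jaccard agreement of two peak sets: matched / (|a| + |b| - matched)."""
    if len(a) == 0 and len(b) == 0:
        return 0.0
    m = len(match_peaks(a, b, tol))
    return m / (len(a) + len(b) - m)


def optimize_parameters(
    rep1: BinnedTrack,
    rep2: BinnedTrack,
    span_grid=(0.002, 0.005, 0.01, 0.02),
    w_grid=(10, 25, 50),
    tol: int = 2,
) -> tuple[float, int, pd.DataFrame]:
    """Exhaustive (span, w) grid search maximizing replicate peak agreement.

    Returns (span, w, surface) where ``surface`` lists the agreement at
    every grid point.  Ties break toward larger span then larger w
    (smoother tracks, fewer calls).
    """
    if not len(span_grid) or not len(w_grid):
        raise ValueError("grids must be non-empty")
    rows = []
    best = None
    for span in span_grid:
        p1_cache = None
        for w in w_grid:
            p1 = call_peaks(rep1, span, w)
            p2 = call_peaks(rep2, span, w)
            agr = peak_agreement(p1, p2, tol)
            rows.append((span, w, agr, len(p1), len(p2)))
            key = (agr, span, w)
            if best is None or key > best:
                best = key
    surface = pd.DataFrame(rows, columns=["span", "w", "agreement", "n_peaks_rep1", "n_peaks_rep2"])
    return best[1], best[2], surface


def classify_peaks(peaks: pd.DataFrame, subcompartments: pd.DataFrame) -> pd.DataFrame:
    """Type peaks by Hi-C subcompartment at the apex: A1 -> I, A2/B1 -> II.

    ``subcompartments`` is an interval DataFrame (chrom, start, end, name)
    with labels among A1/A2/B1/B2/B3; overlapping annotation intervals are
    rejected.  Apexes in B2/B3 or unannotated gaps stay 'unclassified'.
    """
    allowed = {"A1", "A2", "B1", "B2", "B3"}
    bad = set(subcompartments["name"]) - allowed
    if bad:
        raise ValueError(f"unknown subcompartment labels: {sorted(bad)}")
    out = peaks.copy()
    out["type"] = "unclassified"
    for chrom, grp in subcompartments.groupby("chrom"):
        grp = grp.sort_values("start")
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"overlapping subcompartment intervals on {chrom}")
        sel = out["chrom"] == chrom
        if not sel.any():
            continue
        pos = out.loc[sel, "apex_bp"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        inside = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(ends) - 1)])
        labels = grp["name"].to_numpy()[np.clip(idx, 0, len(ends) - 1)]
        typed = np.where(
            inside & (labels == "A1"),
            "I",
            np.where(inside & np.isin(labels, ("A2", "B1")), "II", "unclassified"),
        )
        out.loc[sel, "type"] = typed
    out.attrs.update(peaks.attrs)
    return out


def write_peaks_bed(peaks: pd.DataFrame, path) -> None:
    """Write peaks as BED5: apex-bin interval, name = type, score = apex value."""
    bs = peaks.attrs.get("bin_size", 1)
    with open(path, "w") as fh:
        for _, r in peaks.sort_values(["chrom", "apex_bin"]).iterrows():
            s = int(r["apex_bin"]) * bs
            fh.write(f"{r['chrom']}\t{s}\t{s + bs}\t{r['type']}\t{r['score']:.6g}\n")
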