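"""Replication-timing statistics: E/L log-ratio, Trep/Twidth, initiation zones.

The S-phase coordinate is the fraction index scaled to [0, 1]: fraction i of
n covers [(i-1)/n, i/n); no wall-clock hours are imputed.  Trep is the
linearly interpolated S-phase coordinate at which the cumulative
incorporation reaches one half (timing of replication); Twidth is the
quartile span of that cumulative (variation in replication timing).
Initiation zones (IZs) are peaks of the earliness track 1 - Trep, called
with the same local-maximum pipeline as speckle peaks.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .tracks import BinnedTrack
from .peaks import call_peaks

__all__ = [
    "el_log_ratio",
    "trep_twidth",
    "call_izs",
    "iz_timing_classes",
    "TIMING_CLASSES",
]

TIMING_CLASSES = ("early", "early-mid", "late-mid", "late")


def el_log_ratio(early: BinnedTrack, late: BinnedTrack, pseudocount: float = 1.0) -> BinnedTrack:
    """2-fraction Repli-seq timing: log2((E + pc) / (L + pc)) per bin."""
    if early.bin_size != late.bin_size:
        raise ValueError("bin sizes differ")
    data = {}
    for chrom in early.data:
        e = early.data[chrom]
        l = late.data[chrom]
        if len(e) != len(l):
            raise ValueError(f"bin counts differ on {chrom}")
        if np.nanmin(e) < 0 or np.nanmin(l) < 0:
            raise ValueError("negative incorporation values")
        data[chrom] = np.log2((e + pseudocount) / (l + pseudocount))
    return BinnedTrack(bin_size=early.bin_size, data=data, assay="RepliEL", cell_type=early.cell_type)


def _cum_coordinate(p: np.ndarray, q: float) -> np.ndarray:
    """S-phase coordinate where the cumulative of each profile row reaches q."""
    n = p.shape[1]
    cum = np.cumsum(p, axis=1)
    # first fraction index where cum >= q
    idx = np.argmax(cum >= q - 1e-12, axis=1)
    prev = np.where(idx > 0, np.take_along_axis(cum, (idx - 1)[:, None], axis=1)[:, 0], 0.0)
    pi = np.take_along_axis(p, idx[:, None], axis=1)[:, 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(pi > 0, (q - prev) / pi, 0.0)
    return (idx + frac) / n


def trep_twidth(
    profiles: np.ndarray,
    q_low: float = 0.25,
    q_high: float = 0.75,
) -> tuple[np.ndarray, np.ndarray]:
    """Trep and Twidth of multi-fraction Repli-seq profiles.

    ``profiles`` has shape (n_bins, n_fractions); rows are normalized to sum
    1 (all-zero rows are undefined, NaN).  Trep = coordinate at cumulative
    0.5 with within-fraction linear interpolation; Twidth = coordinate at
    ``q_high`` minus coordinate at ``q_low``.
    """
    p = np.atleast_2d(np.asarray(profiles, dtype=float))
    tot = p.sum(axis=1, keepdims=True)
    ok = tot[:, 0] > 0
    norm = np.where(tot > 0, p / np.where(tot > 0, tot, 1), 0.0)
    trep = np.full(len(p), np.nan)
    twidth = np.full(len(p), np.nan)
    if ok.any():
        trep[ok] = _cum_coordinate(norm[ok], 0.5)
        twidth[ok] = _cum_coordinate(norm[ok], q_high) - _cum_coordinate(norm[ok], q_low)
    return trep, twidth


def call_izs(
    profiles: np.ndarray,
    bin_size: int = 25_000,
    chrom: str = "chr1",
    span: float = 0.005,
    w: int = 50,
) -> pd.DataFrame:
    """Call DNA replication initiation zones as peaks in earliness (1 - Trep).

    Reuses the speckle-peak local-maximum caller on the earliness track;
    apexes are IZ centers.  Returns a peak DataFrame with an extra ``trep``
    column (Trep at the apex).
    """
    trep, _ = trep_twidth(profiles)
    earliness = BinnedTrack(bin_size=bin_size, data={chrom: 1.0 - trep}, assay="earliness")
    izs = call_peaks(earliness, span=span, w=w)
    if len(izs):
        izs["trep"] = trep[izs["apex_bin"].to_numpy(dtype=int)]
    else:
        izs["trep"] = np.empty(0)
    return izs


def iz_timing_classes(trep_at_apex: np.ndarray) -> np.ndarray:
    """Quartile split of IZ Trep values into early .. late classes.

    Ties at quartile edges go to the earlier class (class rule: early iff
    trep <= Q25, early-mid iff <= Q50, late-mid iff <= Q75, else late).
    Fewer than 4 IZs cannot support quartiles: all become 'early' with a
    warning.
    """
    t = np.asarray(trep_at_apex, dtype=float)
    if len(t) < 4:
        warnings.warn("fewer than 4 IZs; all assigned 'early'")
        return np.full(len(t), "early", dtype=object)
    q25, q50, q75 = np.quantile(t, [0.25, 0.5, 0.75])
    out = np.where(
        t <= q25,
        "early",
        np.where(t <= q50, "early-mid", np.where(t <= q75, "late-mid", "late")),
    )
    return out.astype(object)
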