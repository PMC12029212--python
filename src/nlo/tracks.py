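"""Binned genomic signal tracks: data model, I/O, and preprocessing.

A :class:`BinnedTrack` holds fixed-width bin scores per chromosome for one
assay in one cell type (SON / LMNB1 / MKI67IP TSA-seq, LMNB1 DamID, ChIP
percentiles, Repli-seq fractions ...).  Bin ``i`` covers the 0-based
half-open interval ``[i*bin_size, (i+1)*bin_size)``.  Missing values are
explicit ``NaN``, never silent zeros, and every preprocessing step
propagates them without imputation so downstream segmentation cannot
hallucinate signal at assay gaps.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BinnedTrack",
    "read_track",
    "read_bedgraph",
    "write_bedgraph",
    "read_bigwig",
    "write_bigwig",
    "read_bed",
    "write_bed",
    "znormalize",
    "loess_smooth",
    "percentile_transform",
    "rebin",
]


@dataclass
class BinnedTrack:
    """Per-chromosome fixed-width bin scores for one assay in one cell type.

    Parameters
    ----------
    bin_size : int
        Bin width in bp.
    data : dict
        Chromosome name -> float array of length ``ceil(chrom_len/bin_size)``.
        ``NaN`` marks missing bins.
    assay, cell_type : str
        Free-text labels (e.g. ``"SON_TSA"``, ``"H1"``).
    coverage : dict, optional
        Chromosome -> fraction of each bin covered by source intervals
        (populated by :func:`read_track`; 1.0 means fully covered).
    """

    bin_size: int
    data: dict[str, np.ndarray]
    assay: str = ""
    cell_type: str = ""
    coverage: dict[str, np.ndarray] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        self.data = {c: np.asarray(v, dtype=float) for c, v in self.data.items()}

    @property
    def chromosomes(self) -> list[str]:
        return list(self.data)

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.data[chrom]

    def n_bins(self) -> int:
        return int(sum(len(v) for v in self.data.values()))

    def values(self) -> np.ndarray:
        """All bin scores concatenated in chromosome order."""
        if not self.data:
            return np.empty(0)
        return np.concatenate([self.data[c] for c in self.data])

    def copy_with(self, data: dict[str, np.ndarray], **labels) -> "BinnedTrack":
        kw = dict(assay=self.assay, cell_type=self.cell_type)
        kw.update(labels)
        return BinnedTrack(bin_size=self.bin_size, data=data, **kw)

    def bin_index(self, pos: int) -> int:
        return int(pos // self.bin_size)


# ---------------------------------------------------------------------------
# I/O


def read_bedgraph(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float},
        skip_blank_lines=True,
    )
    # tolerate track definition lines
    bad = df["chrom"].str.startswith(("track", "browser"))
    if bad.any():
        df = df[~bad].reset_index(drop=True)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
    return df


def read_track(path, bin_size: int, format: str | None = None, chrom_sizes: dict[str, int] | None = None) -> BinnedTrack:
    """Read a bedGraph or bigWig file and re-bin to ``bin_size``.

    Values are re-binned by coverage-weighted mean; bins with no covering
    source interval are missing (NaN).  The per-bin covered fraction is kept
    in ``track.coverage`` so partially covered bins are identifiable.

    Raises ``ValueError`` on overlapping source intervals (first collision is
    named) and on chromosomes absent from ``chrom_sizes`` when given.
    """
    if format is None:
        format = "bigwig" if str(path).endswith((".bw", ".bigwig", ".bigWig")) else "bedgraph"
    if format == "bigwig":
        df = _bigwig_to_intervals(path)
    elif format == "bedgraph":
        df = read_bedgraph(path)
    else:
        raise ValueError(f"unknown format: {format!r}")
    if df.empty:
        logger.warning("empty track file: %s", path)
        return BinnedTrack(bin_size=bin_size, data={})

    data: dict[str, np.ndarray] = {}
    cov: dict[str, np.ndarray] = {}
    for chrom, grp in df.groupby("chrom", sort=True):
        if chrom_sizes is not None and chrom not in chrom_sizes:
            raise ValueError(f"unknown chromosome {chrom!r} not in chrom_sizes")
        grp = grp.sort_values("start")
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        vals = grp["value"].to_numpy()
        olap = np.nonzero(starts[1:] < ends[:-1])[0]
        if olap.size:
            i = olap[0]
            raise ValueError(
                f"overlapping intervals on {chrom}: "
                f"[{starts[i]},{ends[i]}) and [{starts[i + 1]},{ends[i + 1]})"
            )
        length = chrom_sizes[chrom] if chrom_sizes is not None else int(ends.max())
        n = int(np.ceil(length / bin_size))
        wsum = np.zeros(n)
        vsum = np.zeros(n)
        for s, e, v in zip(starts, ends, vals):
            b0, b1 = int(s // bin_size), int((e - 1) // bin_size)
            for b in range(b0, b1 + 1):
                ov = min(e, (b + 1) * bin_size) - max(s, b * bin_size)
                if ov > 0:
                    wsum[b] += ov
                    vsum[b] += v * ov
        with np.errstate(invalid="ignore", divide="ignore"):
            scores = np.where(wsum > 0, vsum / np.where(wsum > 0, wsum, 1), np.nan)
        data[chrom] = scores
        cov[chrom] = wsum / bin_size
    return BinnedTrack(bin_size=bin_size, data=data, coverage=cov)


def _bigwig_to_intervals(path) -> pd.DataFrame:
    import pyBigWig

    rows = []
    with pyBigWig.open(str(path)) as bw:
        for chrom in bw.chroms():
            for s, e, v in bw.intervals(chrom) or []:
                rows.append((chrom, s, e, v))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def write_bedgraph(track: BinnedTrack, path, drop_missing: bool = True) -> None:
    """Write a track as sorted bedGraph (0-based half-open)."""
    with open(path, "w") as fh:
        for chrom in sorted(track.data):
            v = track.data[chrom]
            for i in range(len(v)):
                if drop_missing and not np.isfinite(v[i]):
                    continue
                fh.write(f"{chrom}\t{i * track.bin_size}\t{(i + 1) * track.bin_size}\t{v[i]:.6g}\n")


def read_bigwig(path, bin_size: int) -> BinnedTrack:
    return read_track(path, bin_size, format="bigwig")


def write_bigwig(track: BinnedTrack, path) -> None:
    import pyBigWig

    bw = pyBigWig.open(str(path), "w")
    chroms = sorted(track.data)
    bw.addHeader([(c, len(track.data[c]) * track.bin_size) for c in chroms])
    for chrom in chroms:
        v = track.data[chrom]
        keep = np.isfinite(v)
        if not keep.any():
            continue
        idx = np.nonzero(keep)[0]
        bw.addEntries(
            [chrom] * len(idx),
            [int(i) * track.bin_size for i in idx],
            ends=[(int(i) + 1) * track.bin_size for i in idx],
            values=[float(v[i]) for i in idx],
        )
    bw.close()


def read_bed(path) -> pd.DataFrame:
    """Read BED3/4/5 into a sorted interval DataFrame (chrom,start,end,name,score)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, skip_blank_lines=True)
    cols = ["chrom", "start", "end", "name", "score"][: df.shape[1]]
    df = df.iloc[:, : len(cols)]
    df.columns = cols
    for missing in ("name", "score"):
        if missing not in df.columns:
            df[missing] = "." if missing == "name" else 0.0
    df = df.sort_values(["chrom", "start"]).reset_index(drop=True)
    if (df["start"] >= df["end"]).any():
        raise ValueError("BED intervals must have start < end")
    return df


def write_bed(df: pd.DataFrame, path, columns=("chrom", "start", "end", "name", "score")) -> None:
    cols = [c for c in columns if c in df.columns]
    df.sort_values(["chrom", "start"])[cols].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Preprocessing


def znormalize(track: BinnedTrack) -> BinnedTrack:
    """Genome-wide z-normalization, population-sd convention.

    Whole-genome tracks are treated as the full population of bins, so the
    divisor is n (not n-1).  Missing bins stay missing and are excluded from
    the mean/sd.  Raises on zero variance or fewer than 2 usable bins.
    """
    vals = track.values()
    ok = np.isfinite(vals)
    if ok.sum() < 2:
        raise ValueError("znormalize needs at least 2 non-missing bins")
    mu = vals[ok].mean()
    sd = vals[ok].std()  # population sd (ddof=0)
    if sd == 0:
        raise ValueError("znormalize: zero variance")
    return track.copy_with({c: (v - mu) / sd for c, v in track.data.items()})


def percentile_transform(track: BinnedTrack) -> BinnedTrack:
    """Map scores to genome-wide percentiles in [0, 100].

    Average-rank convention for ties; percentile = rank / n * 100 so the
    maximum maps to 100.  Matches the fold-change-to-percentile transform
    used for ChIP enrichment overlays.
    """
    from scipy.stats import rankdata

    vals = track.values()
    ok = np.isfinite(vals)
    if ok.sum() < 1:
        raise ValueError("percentile_transform needs at least 1 non-missing bin")
    out = np.full(vals.shape, np.nan)
    out[ok] = rankdata(vals[ok], method="average") / ok.sum() * 100.0
    data = {}
    off = 0
    for c, v in track.data.items():
        data[c] = out[off : off + len(v)]
        off += len(v)
    return track.copy_with(data)


def rebin(track: BinnedTrack, new_bin_size: int) -> BinnedTrack:
    """Aggregate to a coarser bin size by missing-aware mean.

    ``new_bin_size`` must be an integer multiple of the current bin size
    (e.g. 25 kb assay bins -> 100 kb cLAD bins).  Groups whose constituent
    bins are all missing stay missing.
    """
    if new_bin_size % track.bin_size != 0:
        raise ValueError(
            f"new_bin_size {new_bin_size} is not a multiple of bin_size {track.bin_size}"
        )
    k = new_bin_size // track.bin_size
    if k == 1:
        return track.copy_with({c: v.copy() for c, v in track.data.items()})
    data = {}
    for c, v in track.data.items():
        n_out = int(np.ceil(len(v) / k))
        padded = np.full(n_out * k, np.nan)
        padded[: len(v)] = v
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN groups
            data[c] = np.nanmean(padded.reshape(n_out, k), axis=1)
    out = track.copy_with(data)
    out.bin_size = new_bin_size
    return out


def _loess_1d(x: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    """Local linear regression with tricube weights over the k nearest points.

    x must be sorted.  The k nearest neighbours of a sorted grid form a
    contiguous window, found by a two-pointer sweep; the fit is evaluated at
    each x_i via the closed-form weighted normal equations on centred x.
    """
    n = len(x)
    k = min(k, n)
    starts = np.empty(n, dtype=np.intp)
    s = 0
    for i in range(n):
        while s + k < n and x[s + k] - x[i] < x[i] - x[s]:
            s += 1
        starts[i] = s
    xw = np.lib.stride_tricks.sliding_window_view(x, k)[starts]
    yw = np.lib.stride_tricks.sliding_window_view(y, k)[starts]
    xc = xw - x[:, None]
    d = np.abs(xc)
    dmax = d.max(axis=1, keepdims=True)
    dmax[dmax == 0] = 1.0
    w = (1.0 - (d / dmax) ** 3) ** 3
    sw = w.sum(axis=1)
    swx = (w * xc).sum(axis=1)
    swy = (w * yw).sum(axis=1)
    swxx = (w * xc * xc).sum(axis=1)
    swxy = (w * xc * yw).sum(axis=1)
    denom = sw * swxx - swx * swx
    scale = sw * swxx + swx * swx
    singular = denom <= 1e-12 * np.maximum(scale, 1e-300)
    with np.errstate(invalid="ignore", divide="ignore"):
        fit = (swxx * swy - swx * swxy) / denom
    fit = np.where(singular, swy / sw, fit)
    return fit


def loess_smooth(track: BinnedTrack, span: float) -> BinnedTrack:
    """LOESS smoothing (locally weighted linear regression), per chromosome.

    ``span`` is the fraction of each chromosome's non-missing bins forming
    the tricube-weighted neighbourhood (k = ceil(span * n), nearest bins).
    Smoothing never crosses chromosome ends; missing bins are excluded from
    every fit and remain missing.  Chromosomes whose neighbourhood would
    hold fewer than 3 bins pass through unsmoothed with a warning.
    """
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    data = {}
    for c, v in track.data.items():
        out = v.copy()
        ok = np.isfinite(v)
        n_ok = int(ok.sum())
        k = int(np.ceil(span * n_ok))
        if n_ok < 3 or k < 3:
            if n_ok:
                warnings.warn(
                    f"loess_smooth: <3 usable neighbours on {c} "
                    f"(span {span}, {n_ok} bins); values pass through unsmoothed"
                )
            data[c] = out
            continue
        idx = np.nonzero(ok)[0]
        out[idx] = _loess_1d(idx.astype(float), v[idx], k)
        data[c] = out
    return track.copy_with(data)
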