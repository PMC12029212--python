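"""Linking locale-proximity changes to gene expression and replication timing.

Per-gene delta tables compare two cell types A and B: changes in
z-normalized TSA-seq scores for the three locale markers (SON = speckles,
LMNB1 = lamina, MKI67IP = nucleolus) at the gene's bin, the expression
change log2((FPKM_A + 1)/(FPKM_B + 1)), and optionally the change in E/L
replication-timing log-ratio.  Multi-predictor ordinary least squares then
asks which locale's proximity change carries the expression (or timing)
change.  Speckle-association statistics (distance-threshold fractions) and
Hartigan's dip test for bimodal speckle-distance distributions live here
too.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .tracks import BinnedTrack, znormalize
from .dip import dip_bimodality  # re-exported: bimodality testing belongs to this analysis

logger = logging.getLogger(__name__)

__all__ = [
    "build_delta_table",
    "fit_linear_model",
    "association_fraction",
    "dip_bimodality",
]

TSA_ASSAYS = ("son", "lmnb1", "mki67ip")


def _gene_bins(genes: pd.DataFrame, bin_size: int, mode: str) -> pd.Series:
    if mode == "tss":
        return genes["tss"] // bin_size
    if mode == "midpoint":
        return (genes["start"] + genes["end"]) // 2 // bin_size
    raise ValueError(f"unknown gene-to-bin mode {mode!r}")


def build_delta_table(
    tracks: dict[str, dict[str, BinnedTrack]],
    genes: pd.DataFrame,
    pair: tuple[str, str],
    timing: dict[str, BinnedTrack] | None = None,
    mode: str = "tss",
    znorm: bool = True,
) -> pd.DataFrame:
    """Per-gene deltas between cell types A and B (A - B everywhere).

    ``tracks[cell][assay]`` holds the TSA tracks ('son', 'lmnb1', 'mki67ip');
    ``genes`` needs gene_id, chrom, start, end, tss, fpkm_<A>, fpkm_<B>.
    Genes are assigned to the bin containing their TSS (``mode='tss'``,
    promoter-anchored) or their midpoint.  Tracks are z-normalized before
    differencing unless ``znorm=False``.  Genes landing on missing bins in
    any track are dropped (count logged).

    Returns a DataFrame with columns gene_id, d_son, d_lmnb1, d_mki67ip,
    d_expr and (when ``timing`` is given) d_timing.
    """
    a, b = pair
    prepped: dict[str, dict[str, BinnedTrack]] = {}
    bin_size = None
    for cell in pair:
        prepped[cell] = {}
        for assay in TSA_ASSAYS:
            tr = tracks[cell][assay]
            if bin_size is None:
                bin_size = tr.bin_size
            elif tr.bin_size != bin_size:
                raise ValueError("mismatched bin sizes across tracks")
            prepped[cell][assay] = znormalize(tr) if znorm else tr
    bins = _gene_bins(genes, bin_size, mode)
    out = {"gene_id": genes["gene_id"].to_numpy()}
    keep = np.ones(len(genes), dtype=bool)
    for assay in TSA_ASSAYS:
        delta = np.full(len(genes), np.nan)
        for i, (chrom, bn) in enumerate(zip(genes["chrom"], bins)):
            va = prepped[a][assay].data.get(chrom)
            vb = prepped[b][assay].data.get(chrom)
            if va is None or vb is None or bn >= len(va) or bn >= len(vb):
                continue
            delta[i] = va[bn] - vb[bn]
        out[f"d_{assay}"] = delta
        keep &= np.isfinite(delta)
    out["d_expr"] = np.log2((genes[f"fpkm_{a}"] + 1.0) / (genes[f"fpkm_{b}"] + 1.0))
    if timing is not None:
        dt = np.full(len(genes), np.nan)
        for i, (chrom, bn) in enumerate(zip(genes["chrom"], bins)):
            va = timing[a].data.get(chrom)
            vb = timing[b].data.get(chrom)
            if va is None or vb is None or bn >= len(va) or bn >= len(vb):
                continue
            dt[i] = va[bn] - vb[bn]
        out["d_timing"] = dt
        keep &= np.isfinite(dt)
    df = pd.DataFrame(out)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("build_delta_table: dropped %d genes on missing bins", dropped)
    return df[keep].reset_index(drop=True)


def fit_linear_model(
    table: pd.DataFrame,
    response: str = "d_expr",
    predictors: tuple[str, ...] = ("d_son", "d_lmnb1", "d_mki67ip"),
    subset: np.ndarray | None = None,
) -> dict:
    """OLS of a delta response on the locale delta predictors, with intercept.

    Returns coefficients, classical standard errors and 95% confidence
    intervals as a dict keyed by term.  ``subset`` restricts the fit to a
    boolean row mask (e.g. LAD, iLAD or speckle-peak bins, fit separately
    per stratum).  A rank-deficient design is rejected with the collinear
    columns named.
    """
    import statsmodels.api as sm

    df = table if subset is None else table[np.asarray(subset, dtype=bool)]
    if len(df) < 10:
        raise ValueError("need at least 10 rows to fit")
    X = df[list(predictors)].to_numpy()
    Xd = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xd)
    if rank < Xd.shape[1]:
        bad = [p for i, p in enumerate(predictors) if np.std(X[:, i]) == 0]
        if not bad:
            # name predictors whose removal restores full column rank
            bad = [
                p
                for i, p in enumerate(predictors)
                if np.linalg.matrix_rank(np.delete(Xd, i + 1, axis=1)) == rank
            ]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    fit = sm.OLS(df[response].to_numpy(), Xd).fit()
    terms = ["intercept", *predictors]
    ci = fit.conf_int(alpha=0.05)
    return {
        "n": int(fit.nobs),
        "response": response,
        "coef": dict(zip(terms, fit.params)),
        "se": dict(zip(terms, fit.bse)),
        "ci95": {t: (float(ci[i][0]), float(ci[i][1])) for i, t in enumerate(terms)},
        "r2": float(fit.rsquared),
    }


def association_fraction(distances, threshold: float = 250.0) -> float:
    """Fraction of distances strictly below ``threshold`` (nm).

    The speckle association fraction of the imaging analyses: loci within
    250 nm of a speckle surface count as associated; a distance exactly at
    the threshold is excluded (strict inequality).
    """
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("association_fraction of an empty sample is undefined")
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    return float(np.mean(d < threshold))
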