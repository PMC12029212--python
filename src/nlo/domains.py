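"""LAD calling, cross-cell-type consensus, and fiLAD classification.

LADs are called from LMNB1 DamID log-ratios with a 2-state Gaussian-emission
HMM (lamina-contacting versus interior state).  A consensus set merges every
region that is a LAD in at least one cell type; each consensus domain is
then classified per cell type as LAD, "peak-within-valley" facultative iLAD
(p-w-v fiLAD: a residual local DamID maximum relative to its flanks despite
an overall iLAD state, i.e. partial repression), or "valley" fiLAD
(v fiLAD: no residual lamina signal, full derepression).  The class boundary
follows local enrichment: a fiLAD whose enrichment falls below the 5th
percentile of the cell type's own LAD enrichments is a v fiLAD.  The cLAD
score counts, per 100 kb bin, the cell lines calling the bin a LAD.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .tracks import BinnedTrack

__all__ = [
    "call_lads_hmm",
    "build_consensus",
    "local_enrichment",
    "classify_consensus",
    "clad_score",
]

DOMAIN_CLASSES = ("LAD", "pwv_fiLAD", "v_fiLAD", "iLAD")


def _runs(states: np.ndarray, value: int) -> list[tuple[int, int]]:
    """Half-open index runs where ``states == value``."""
    hits = np.concatenate([[False], states == value, [False]])
    d = np.diff(hits.astype(int))
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    return list(zip(starts, ends))


def call_lads_hmm(damid: BinnedTrack, min_bins: int = 5, cell_type: str | None = None) -> pd.DataFrame:
    """Call LADs as runs of the high-mean state of a 2-state Gaussian HMM.

    The HMM is fit genome-wide by EM, deterministically initialized from the
    sign split at 0 (positive DamID ~ lamina contact), with convergence at
    log-likelihood gain < 1e-4 or 300 iterations, then Viterbi-decoded per
    chromosome (per contiguous non-missing segment).  Runs shorter than
    ``min_bins`` are dropped; adjacent LADs separated by fewer than 2 bins
    are merged.  A track with fewer than 2 positive or 2 negative bins skips
    the HMM (an all-negative genome has no LADs; an all-positive one is a
    single LAD per chromosome).

    Returns a DomainSet DataFrame (chrom, start, end, class, cell_type).
    """
    segments = []  # (chrom, offset, values)
    for chrom, v in damid.data.items():
        ok = np.isfinite(v)
        if ok.sum() < 10:
            continue
        for s, e in _runs(ok.astype(int), 1):
            segments.append((chrom, s, v[s:e]))
    rows = []
    cell = cell_type if cell_type is not None else damid.cell_type
    if segments:
        allv = np.concatenate([seg[2] for seg in segments])
        pos, neg = allv[allv >= 0], allv[allv < 0]
        if len(pos) < 2 or len(neg) < 2:
            decoded = [(c, off, (seg >= 0).astype(int)) for c, off, seg in segments]
        else:
            decoded = _hmm_decode(segments, pos, neg)
        for chrom, off, states in decoded:
            for s, e in _runs(states, 1):
                rows.append((chrom, off + s, off + e))
    lads = _merge_and_filter(rows, min_bins=min_bins, max_gap=1)
    df = pd.DataFrame(
        [
            (c, s * damid.bin_size, e * damid.bin_size, "LAD", cell)
            for c, s, e in lads
        ],
        columns=["chrom", "start", "end", "class", "cell_type"],
    )
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def _hmm_decode(segments, pos, neg):
    from hmmlearn.hmm import GaussianHMM

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        hmm = GaussianHMM(
            n_components=2,
            covariance_type="diag",
            n_iter=300,
            tol=1e-4,
            init_params="",
            params="stmc",
            min_covar=1e-6,
        )
        hmm.startprob_ = np.array([0.5, 0.5])
        hmm.transmat_ = np.array([[0.9, 0.1], [0.1, 0.9]])
        hmm.means_ = np.array([[neg.mean()], [pos.mean()]])
        hmm.covars_ = np.maximum(np.array([[neg.var()], [pos.var()]]), 1e-6)
        X = np.concatenate([seg[2] for seg in segments])[:, None]
        lengths = [len(seg[2]) for seg in segments]
        hmm.fit(X, lengths)
        high = int(np.argmax(hmm.means_.ravel()))
        out = []
        for chrom, off, seg in segments:
            states = hmm.predict(seg[:, None])
            out.append((chrom, off, (states == high).astype(int)))
    return out


def _merge_and_filter(rows, min_bins: int, max_gap: int):
    """Merge bin-index runs closer than ``max_gap+1`` bins, drop short ones."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in rows:
        by_chrom.setdefault(c, []).append((s, e))
    out = []
    for c in sorted(by_chrom):
        ivs = sorted(by_chrom[c])
        merged = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s - merged[-1][1] < 2:  # separated by < 2 bins
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for s, e in merged:
            if e - s >= min_bins:
                out.append((c, s, e))
    return out


def _merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Union-merge intervals; overlapping or bookended intervals coalesce."""
    rows = []
    for chrom, grp in df.groupby("chrom"):
        ivs = grp.sort_values("start")[["start", "end"]].to_numpy()
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"]).sort_values(
        ["chrom", "start"]
    ).reset_index(drop=True)


def build_consensus(lad_sets: dict[str, pd.DataFrame], min_reciprocal: float = 0.5) -> pd.DataFrame:
    """Union of LAD calls across cell types with per-cell-type LAD annotation.

    Every consensus domain is a LAD in at least one contributing cell type.
    A consensus domain is annotated LAD in cell type c when some LAD of c
    overlaps it reciprocally by at least ``min_reciprocal`` of both lengths;
    otherwise it is a facultative-iLAD candidate there.

    Returns a DataFrame (chrom, start, end, is_lad_<cell> ... ) with the
    contributing cell types in ``df.attrs['cell_types']``.
    """
    if not lad_sets:
        raise ValueError("need at least one cell type")
    all_lads = pd.concat(
        [df[["chrom", "start", "end"]] for df in lad_sets.values() if len(df)],
        ignore_index=True,
    )
    if all_lads.empty:
        cons = pd.DataFrame(columns=["chrom", "start", "end"])
    else:
        cons = _merge_intervals(all_lads)
    for cell, df in lad_sets.items():
        flags = np.zeros(len(cons), dtype=bool)
        for i, (chrom, cs, ce) in enumerate(zip(cons["chrom"], cons["start"], cons["end"])):
            sub = df[df["chrom"] == chrom]
            for s, e in zip(sub["start"], sub["end"]):
                ov = min(ce, e) - max(cs, s)
                if ov > 0 and ov >= min_reciprocal * (ce - cs) and ov >= min_reciprocal * (e - s):
                    flags[i] = True
                    break
        cons[f"is_lad_{cell}"] = flags
    cons.attrs["cell_types"] = list(lad_sets)
    return cons


def local_enrichment(
    damid: BinnedTrack,
    chrom: str,
    start: int,
    end: int,
    flank_factor: float = 1.0,
    flank_cap: int = 1_000_000,
    exclude: pd.DataFrame | None = None,
) -> float:
    """Domain DamID enrichment relative to its flanks.

    enrichment = mean(domain bins) - mean(flank bins), with flanks of length
    min(flank_factor * domain length, flank_cap) on each side, truncated at
    chromosome ends.  Flank bins falling inside ``exclude`` intervals (other
    consensus domains) or missing are dropped; with no usable flank bin the
    enrichment is undefined (NaN).
    """
    v = damid.data[chrom]
    bs = damid.bin_size
    b0, b1 = start // bs, -(-end // bs)
    dom = v[b0:b1]
    flank_len = int(min(flank_factor * (end - start), flank_cap))
    fb = max(1, flank_len // bs)
    left = np.arange(max(0, b0 - fb), b0)
    right = np.arange(b1, min(len(v), b1 + fb))
    flank_idx = np.concatenate([left, right])
    if exclude is not None and len(flank_idx):
        sub = exclude[exclude["chrom"] == chrom]
        keep = np.ones(len(flank_idx), dtype=bool)
        mids = (flank_idx + 0.5) * bs
        for s, e in zip(sub["start"], sub["end"]):
            if (s, e) == (start, end):
                continue
            keep &= ~((mids >= s) & (mids < e))
        flank_idx = flank_idx[keep]
    flank = v[flank_idx] if len(flank_idx) else np.empty(0)
    flank = flank[np.isfinite(flank)]
    dom = dom[np.isfinite(dom)]
    if len(flank) == 0 or len(dom) == 0:
        return np.nan
    return float(dom.mean() - flank.mean())


def classify_consensus(
    consensus: pd.DataFrame,
    damid_by_celltype: dict[str, BinnedTrack],
    quantile: float = 0.05,
    flank_factor: float = 1.0,
    flank_cap: int = 1_000_000,
) -> dict[str, pd.DataFrame]:
    """Classify each consensus domain per cell type as LAD / p-w-v / v fiLAD.

    In each cell type, domains called LAD there stay LAD; the remaining
    (facultative-iLAD) domains are v fiLADs when their local enrichment is
    below the ``quantile`` level (default 5th percentile, i.e. "lower than
    95% of the LADs") of that cell type's LAD enrichment distribution, else
    p-w-v fiLADs.  Flanks exclude bins inside other consensus domains.

    Returns cell type -> DomainSet DataFrame (chrom, start, end, class,
    enrichment, cell_type); the threshold is stored in ``df.attrs``.
    """
    out = {}
    for cell, damid in damid_by_celltype.items():
        flag_col = f"is_lad_{cell}"
        if flag_col not in consensus.columns:
            raise KeyError(f"consensus lacks annotation column {flag_col}")
        enr = np.array(
            [
                local_enrichment(
                    damid, c, s, e,
                    flank_factor=flank_factor, flank_cap=flank_cap, exclude=consensus,
                )
                for c, s, e in zip(consensus["chrom"], consensus["start"], consensus["end"])
            ]
        )
        is_lad = consensus[flag_col].to_numpy()
        lad_enr = enr[is_lad & np.isfinite(enr)]
        if len(lad_enr) < 20:
            warnings.warn(
                f"{cell}: only {len(lad_enr)} LADs; enrichment threshold is unstable"
            )
        thr = np.quantile(lad_enr, quantile) if len(lad_enr) else np.nan
        cls = np.where(
            is_lad, "LAD", np.where(enr < thr, "v_fiLAD", "pwv_fiLAD")
        )
        df = pd.DataFrame(
            {
                "chrom": consensus["chrom"],
                "start": consensus["start"],
                "end": consensus["end"],
                "class": cls,
                "enrichment": enr,
                "cell_type": cell,
            }
        )
        df.attrs.update(
            enrichment_threshold=float(thr) if np.isfinite(thr) else None,
            quantile=quantile,
            flank_factor=flank_factor,
            flank_cap=flank_cap,
        )
        out[cell] = df
    return out


def clad_score(
    lad_sets: dict[str, pd.DataFrame],
    chrom_sizes: dict[str, int],
    bin_size: int = 100_000,
) -> BinnedTrack:
    """Constitutive-LAD score: cell lines whose LADs cover each bin midpoint.

    Counts run 0..len(lad_sets) (classically 7 cell lines); bins outside the
    LAD union get 0 and are the non-union background.  Midpoint coverage is
    deterministic and never double-counts a boundary bin.
    """
    if not 1 <= len(lad_sets) <= 7:
        raise ValueError("clad_score expects 1-7 cell types")
    data = {
        c: np.zeros(-(-l // bin_size)) for c, l in chrom_sizes.items()
    }
    for df in lad_sets.values():
        for chrom, grp in df.groupby("chrom"):
            if chrom not in data:
                continue
            mids = (np.arange(len(data[chrom])) + 0.5) * bin_size
            covered = np.zeros(len(mids), dtype=bool)
            for s, e in zip(grp["start"], grp["end"]):
                covered |= (mids >= s) & (mids < e)
            data[chrom] += covered
    return BinnedTrack(bin_size=bin_size, data=data, assay="cLAD")
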