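"""Hartigan's dip statistic for unimodality, with Monte-Carlo p-values.

The dip of a sample is the smallest sup-norm distance between its empirical
CDF and any unimodal distribution function (convex to the left of the mode,
concave to the right, an atom allowed at the mode).  It is computed by the
classic iterative construction: maintain a candidate modal interval
[low, high]; fit the greatest convex minorant (GCM) and least concave
majorant (LCM) of the ECDF on it; the largest gap between the two fits
either shrinks the modal interval or certifies the current dip, while the
ECDF's deviations from the GCM below the modal interval and from the LCM
above it accumulate into the dip.  Distances are tracked in ECDF count
units and halved at the end (the nearest unimodal df runs midway through
the band), so the statistic lies in [1/(2n), 1/4] and is invariant under
strictly monotone transforms of the sample.

p-values are calibrated by Monte Carlo against uniform samples of the same
size (the asymptotically least favourable unimodal null), seeded for
reproducibility.
"""

from __future__ import annotations

import numpy as np

__all__ = ["dip_statistic", "dip_pvalue", "dip_bimodality", "uniform_null_dips"]


def dip_statistic(x) -> float:
    """Hartigan's dip statistic of a 1-D sample (n >= 4)."""
    xs = np.sort(np.asarray(x, dtype=float))
    n = len(xs)
    if n < 4:
        raise ValueError("dip_statistic needs n >= 4")
    # 1-based indexing to keep the classic formulation readable
    x = np.concatenate([[np.nan], xs])
    low, high = 1, n
    dip = 1.0  # in ECDF count units; 1 count <-> both-limit jump at a point

    # mn[j]: index of the previous GCM touchpoint when the fit ends at j;
    # mj[k]: next LCM touchpoint when the fit starts at k (whole sample)
    mn = np.empty(n + 1, dtype=np.intp)
    mn[1] = 1
    for j in range(2, n + 1):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            mnmnj = mn[mnj]
            if mnj == 1 or (x[j] - x[mnj]) * (mnj - mnmnj) < (x[mnj] - x[mnmnj]) * (j - mnj):
                break
            mn[j] = mnmnj
    mj = np.empty(n + 2, dtype=np.intp)
    mj[n] = n
    for k in range(n - 1, 0, -1):
        mj[k] = k + 1
        while True:
            mjk = mj[k]
            mjmjk = mj[mjk]
            if mjk == n or (x[k] - x[mjk]) * (mjk - mjmjk) < (x[mjk] - x[mjmjk]) * (k - mjk):
                break
            mj[k] = mjmjk

    gcm = np.empty(n + 2, dtype=np.intp)  # touchpoints high..low
    lcm = np.empty(n + 2, dtype=np.intp)  # touchpoints low..high
    while True:
        i = 1
        gcm[1] = high
        while gcm[i] > low:
            gcm[i + 1] = mn[gcm[i]]
            i += 1
        ig = l_gcm = i
        ix = ig - 1
        i = 1
        lcm[1] = low
        while lcm[i] < high:
            lcm[i + 1] = mj[lcm[i]]
            i += 1
        ih = l_lcm = i
        iv = 2

        # largest distance between the GCM and LCM fits on [low, high]
        d = 0.0
        if l_gcm != 2 or l_lcm != 2:
            while True:
                gcmix, lcmiv = gcm[ix], lcm[iv]
                if gcmix > lcmiv:
                    # the LCM touchpoint lcmiv lies inside GCM segment
                    # (gcm[ix+1], gcm[ix]): gap = upper fit - lower fit there
                    gcmi1 = gcm[ix + 1]
                    dx = (lcmiv - gcmi1 + 1) - (x[lcmiv] - x[gcmi1]) * (gcmix - gcmi1) / (
                        x[gcmix] - x[gcmi1]
                    )
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv - 1
                else:
                    # the GCM touchpoint lies inside LCM segment
                    lcmiv1 = lcm[iv - 1]
                    dx = (x[gcmix] - x[lcmiv1]) * (lcmiv - lcmiv1) / (
                        x[lcmiv] - x[lcmiv1]
                    ) - (gcmix - lcmiv1 - 1)
                    ix -= 1
                    if dx > d:
                        d = dx
                        ig = ix + 1
                        ih = iv
                if ix < 1:
                    ix = 1
                if iv > l_lcm:
                    iv = l_lcm
                if gcm[ix] == lcm[iv]:
                    break
        else:
            d = 1.0  # both fits are single segments: only the point jumps remain
        if d < dip:
            break

        # ECDF deviation from the GCM over [low, gcm[ig]] ...
        dl = 0.0
        for j in range(ig, l_gcm):
            je, jb = gcm[j], gcm[j + 1]
            max_t = 1.0
            if je - jb > 1 and x[je] != x[jb]:
                C = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (jj - jb + 1) - (x[jj] - x[jb]) * C
                    if t > max_t:
                        max_t = t
            if dl < max_t:
                dl = max_t
        # ... and from the LCM over [lcm[ih], high]
        du = 0.0
        for j in range(ih, l_lcm):
            jb, je = lcm[j], lcm[j + 1]
            max_t = 1.0
            if je - jb > 1 and x[je] != x[jb]:
                C = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (x[jj] - x[jb]) * C - (jj - jb - 1)
                    if t > max_t:
                        max_t = t
            if du < max_t:
                du = max_t
        dipnew = max(dl, du)
        if dip < dipnew:
            dip = dipnew
        if low == gcm[ig] and high == lcm[ih]:
            break  # modal interval stopped shrinking
        low, high = gcm[ig], lcm[ih]
    return float(dip / (2 * n))


def uniform_null_dips(n: int, n_boot: int, seed: int | None = None) -> np.ndarray:
    """Dip statistics of ``n_boot`` uniform samples of size n (the MC null)."""
    rng = np.random.default_rng(seed)
    return np.array([dip_statistic(rng.uniform(size=n)) for _ in range(n_boot)])


def dip_pvalue(dip: float, null_dips: np.ndarray) -> float:
    """Monte-Carlo p-value of an observed dip against precomputed null dips."""
    return float((1 + np.sum(null_dips >= dip)) / (1 + len(null_dips)))


def dip_bimodality(sample, n_boot: int = 2000, seed: int | None = None) -> tuple[float, float]:
    """Dip test of unimodality: (dip statistic, Monte-Carlo p-value).

    The p-value is calibrated against ``n_boot`` uniform samples of the same
    size, using the add-one rule (1 + #{null >= dip}) / (1 + n_boot).
    """
    x = np.asarray(sample, dtype=float)
    if len(x) < 4:
        raise ValueError("dip test needs n >= 4")
    d = dip_statistic(x)
    null = uniform_null_dips(len(x), n_boot, seed)
    return d, dip_pvalue(d, null)
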