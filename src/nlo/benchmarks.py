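"""Planted-truth recovery benchmarks for the whole pipeline.

Each function generates synthetic data with known ground truth under the
package's reference study conditions, runs the corresponding analysis stage,
and returns the recovery/accuracy metrics as a flat dict.  The problem sizes
(genome of ~2000-5000 bins of 25 kb, 10-20 seeds, nuclei at 100-150 nm
voxels) are chosen so every benchmark completes in seconds to a couple of
minutes on one CPU while keeping the statistical checks meaningful.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from . import dip as dip_mod
from .domains import build_consensus, call_lads_hmm, classify_consensus
from .geometry import mask_morphology, normalize_nucleus, rim_pole_contrast, tsa_convolve
from .linkage import fit_linear_model
from .peaks import call_peaks, match_peaks, max_filter, optimize_parameters
from .repli import trep_twidth
from .synth import (
    GenomeSpec,
    PlantedDomain,
    PlantedPeak,
    make_damid_track,
    make_nucleus_scene,
    make_repli_profiles,
    make_tsa_replicates,
)

logging.getLogger("hmmlearn.base").setLevel(logging.ERROR)

BIN = 25_000


def _sub_seed(seed: int, k: int) -> int:
    return int(np.random.default_rng([seed, k]).integers(0, 2**31 - 1))


# ---------------------------------------------------------------- peaks


def planted_peak_tracks(seed: int, n_peaks: int = 20, noise_sd: float = 1.0):
    """SON TSA-seq-like replicates: one planted peak every 2-3 Mb, amp 3-6."""
    rng = np.random.default_rng([seed, 9])
    apex_bins, pos = [], 50
    while len(apex_bins) < n_peaks:
        apex_bins.append(pos)
        pos += int(rng.integers(80, 121))
    spec = GenomeSpec({"chr1": (pos + 50) * BIN}, seed=seed)
    peaks = [
        PlantedPeak("chr1", int(b * BIN + BIN // 2), float(rng.uniform(3, 6)), 100_000.0)
        for b in apex_bins
    ]
    r1, r2 = make_tsa_replicates(spec, peaks, rep_noise_sd=noise_sd)
    return r1, r2, apex_bins


def peak_recovery(seed: int = 0, n_seeds: int = 20) -> dict:
    """Sensitivity/precision of the peak caller at replicate-optimized (span, w)."""
    sens, prec = [], []
    for i in range(n_seeds):
        r1, r2, apex_bins = planted_peak_tracks(_sub_seed(seed, i))
        span, w, _ = optimize_parameters(r1, r2, (0.005, 0.01, 0.02), (10, 25, 50), tol=2)
        called = call_peaks(r1, span, w)
        truth = pd.DataFrame({"chrom": "chr1", "apex_bin": apex_bins})
        m = len(match_peaks(called, truth, tol=2))
        sens.append(m / len(truth))
        prec.append(m / max(len(called), 1))
    return {
        "peak_sensitivity": float(np.mean(sens)),
        "peak_precision": float(np.mean(prec)),
        "n_seeds": n_seeds,
    }


def max_filter_vs_oracle(seed: int = 0, n: int = 500, w: int = 7) -> dict:
    v = np.random.default_rng(seed).normal(size=n)
    oracle = np.array([np.max(v[max(0, i - w) : i + w + 1]) for i in range(n)])
    return {"max_filter_oracle_equal": float(np.array_equal(max_filter(v, w), oracle)), "n": n}


# ---------------------------------------------------------------- domains


def planted_domain_tracks(seed: int, n_bins: int = 2500, noise_sd: float = 0.4):
    """Two cell types sharing planted domains: all LADs in A; LAD/p-w-v/v in B."""
    spec = GenomeSpec({"chr1": n_bins * BIN, "chr2": n_bins * BIN}, seed=seed)
    rng = spec.rng(8)
    classes = ["LAD", "pwv_fiLAD", "v_fiLAD"]
    doms = []
    for chrom in spec.chrom_sizes:
        pos, ci = 100, 0
        while pos < n_bins - 220:
            w = int(rng.integers(25, 50))
            doms.append(
                PlantedDomain(
                    chrom, pos * BIN, (pos + w) * BIN, classes[ci % 3], 2.0,
                    per_celltype_class={"A": "LAD", "B": classes[ci % 3]},
                )
            )
            ci += 1
            pos += w + int(rng.integers(50, 90))
    track_a = make_damid_track(spec, doms, noise_sd=noise_sd, autocorr=0.5, cell_type="A")
    spec_b = GenomeSpec(spec.chrom_sizes, seed=_sub_seed(seed, 2))
    track_b = make_damid_track(spec_b, doms, noise_sd=noise_sd, autocorr=0.5, cell_type="B")
    return doms, track_a, track_b


def domain_recovery(seed: int = 0, n_seeds: int = 10) -> dict:
    """HMM boundary accuracy and three-class recovery on planted genomes."""
    boundary_within2 = []
    per_class = {"LAD": [], "pwv_fiLAD": [], "v_fiLAD": []}
    for i in range(n_seeds):
        doms, track_a, track_b = planted_domain_tracks(_sub_seed(seed, 100 + i))
        lads_a = call_lads_hmm(track_a, cell_type="A")
        for d in doms:  # every domain is a LAD in A: check both boundaries
            sub = lads_a[lads_a["chrom"] == d.chrom]
            if len(sub) == 0:
                boundary_within2 += [False, False]
                continue
            boundary_within2.append(abs(sub["start"].to_numpy() - d.start).min() // BIN <= 2)
            boundary_within2.append(abs(sub["end"].to_numpy() - d.end).min() // BIN <= 2)
        lads = {"A": lads_a, "B": call_lads_hmm(track_b, cell_type="B")}
        cons = build_consensus(lads)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            classed = classify_consensus(cons, {"A": track_a, "B": track_b})
        df_b = classed["B"]
        for d in doms:
            ov = df_b[
                (df_b["chrom"] == d.chrom) & (df_b["start"] < d.end) & (df_b["end"] > d.start)
            ]
            if len(ov) == 0:
                continue
            overlap = np.minimum(ov["end"], d.end) - np.maximum(ov["start"], d.start)
            hit = ov.iloc[int(np.argmax(overlap))]
            per_class[d.per_celltype_class["B"]].append(hit["class"] == d.per_celltype_class["B"])
    all_hits = sum(per_class.values(), [])
    return {
        "domain_class_accuracy": float(np.mean(all_hits)),
        "lad_recovery": float(np.mean(per_class["LAD"])),
        "pwv_filad_recovery": float(np.mean(per_class["pwv_fiLAD"])),
        "v_filad_recovery": float(np.mean(per_class["v_fiLAD"])),
        "boundary_within_2bins": float(np.mean(boundary_within2)),
        "n_domains": len(all_hits),
    }


# ---------------------------------------------------------------- scatter


def scatter_rule_agreement(n_grid: int = 100) -> dict:
    """Exhaustive check of the printed line/quadrant/threshold rules."""
    from .scatter import classify_eq_lads, classify_h1_roi, classify_quadrant

    g = np.linspace(-6.0, 4.0, n_grid)
    son, lmnb1 = (a.ravel() for a in np.meshgrid(g, g))
    roi, quad, eq = [], [], []
    for s, l in zip(son, lmnb1):  # straight-line re-evaluation, point by point
        roi.append("ROI_C2" if l < -1.5 * s - 2.2 else "ROI_C1" if l < -1.5 * s - 1.3 else "none")
        quad.append(
            ("C1" if s < -3.0 else "C2") if l >= 0.25 else ("C3" if s < -3.0 else "C4")
        )
        eq.append(
            "EQ_cluster1" if l > 0.75 else "nonEQ_cluster2" if s < 0.98 else "none"
        )
    ok = (
        np.array_equal(classify_h1_roi(son, lmnb1), np.array(roi))
        and np.array_equal(classify_quadrant(son, lmnb1), np.array(quad))
        and np.array_equal(classify_eq_lads(son, lmnb1, np.ones(son.size, bool)), np.array(eq))
    )
    return {"scatter_rule_agreement": float(ok) * 100.0, "n_points": son.size}


# ---------------------------------------------------------------- convolution


def convolution_checks(seed: int = 0) -> dict:
    vox = (125.0, 125.0, 125.0)
    m = np.zeros((25, 25, 25), bool)
    m[12, 12, 12] = True
    f = tsa_convolve(m, vox)
    center = float(f[12, 12, 12])
    one_um = float(f[12, 12, 20])  # 8 voxels x 125 nm = 1 um

    rng = np.random.default_rng(seed)
    mask = rng.uniform(size=(16, 16, 16)) < 0.1
    field = tsa_convolve(mask, vox)
    src = np.argwhere(mask)
    coords = np.indices(mask.shape).reshape(3, -1).T
    d = np.sqrt((((coords[:, None, :] - src[None, :, :]) * (np.array(vox) / 1000.0)) ** 2).sum(-1))
    kv = 5.86 * np.exp(-3.0 * d)
    kv[kv < 0.01 * 5.86] = 0.0
    oracle_err = float(np.abs(field - kv.sum(1).reshape(mask.shape)).max())

    scene = make_nucleus_scene("flat", voxel_nm=150.0, seed=seed, n_speckles=0, n_nucleoli=0)
    rim_ratio = rim_pole_contrast(
        scene.masks["NP"], scene.masks["nucleus"], (150.0,) * 3, (8.0, 4.0, 2.0)
    )
    return {
        "n_voxels": int(np.prod(mask.shape)),
        "kernel_center_value": center,
        "kernel_value_at_1um": one_um,
        "convolution_oracle_max_abs_err": oracle_err,
        "equatorial_rim_over_pole": float(rim_ratio),
    }


# ---------------------------------------------------------------- repli


def trep_roundtrip(seed: int = 0, n_bins: int = 500) -> dict:
    # trep spans the S-phase working range 0.1-0.9; twidth is held at 0.1,
    # a typical quartile width -- near the S-phase boundaries the truncated
    # Gaussian renormalization biases the recovered trep, and the bias grows
    # with twidth (documented in the methods note)
    trep_true = np.linspace(0.1, 0.9, n_bins)
    twidth_true = np.full(n_bins, 0.1)
    clean = make_repli_profiles(n_bins, trep_true, twidth_true)
    trep_c, twidth_c = trep_twidth(clean)
    noisy = make_repli_profiles(
        n_bins, trep_true, twidth_true, counts_per_bin=500, seed=_sub_seed(seed, 6)
    )
    trep_n, twidth_n = trep_twidth(noisy)
    return {
        "trep_max_err_noiseless": float(np.abs(trep_c - trep_true).max()),
        "twidth_max_err_noiseless": float(np.abs(twidth_c - twidth_true).max()),
        "trep_max_err_noisy": float(np.abs(trep_n - trep_true).max()),
        "twidth_max_err_noisy": float(np.abs(twidth_n - twidth_true).max()),
        "n_bins": n_bins,
    }


# ---------------------------------------------------------------- linear model


def linear_model_checks(seed: int = 0, n_seeds: int = 20, n_rows: int = 2000) -> dict:
    truth = {"d_son": 0.8, "d_lmnb1": 0.1, "d_mki67ip": 0.0}
    cover = {k: 0 for k in truth}
    son_largest = 0
    for i in range(n_seeds):
        rng = np.random.default_rng([_sub_seed(seed, 7), i])
        tab = pd.DataFrame({k: rng.normal(size=n_rows) for k in truth})
        tab["d_expr"] = sum(v * tab[k] for k, v in truth.items()) + rng.normal(0, 0.5, n_rows)
        rep = fit_linear_model(tab)
        for k in truth:
            lo, hi = rep["ci95"][k]
            cover[k] += lo <= truth[k] <= hi
        son_largest += rep["coef"]["d_son"] > max(
            rep["coef"]["d_lmnb1"], rep["coef"]["d_mki67ip"]
        )
    rng = np.random.default_rng([_sub_seed(seed, 7), 999])
    tab = pd.DataFrame({k: rng.normal(size=200) for k in truth})
    tab["d_expr"] = 0.8 * tab["d_son"] + 0.1 * tab["d_lmnb1"]
    exact = fit_linear_model(tab)
    noiseless_err = max(abs(exact["coef"][k] - v) for k, v in truth.items())
    return {
        "ci_coverage_min_per_coef": int(min(cover.values())),
        "ci_coverage_seeds": n_seeds,
        "son_coefficient_largest_fraction": son_largest / n_seeds,
        "noiseless_fit_max_coef_err": float(noiseless_err),
    }


# ---------------------------------------------------------------- geometry / dip


def geometry_checks(seed: int = 0) -> dict:
    def sphere(r, pad=5):
        n = 2 * r + 2 * pad + 1
        zz, yy, xx = np.meshgrid(*[np.arange(n) - n // 2] * 3, indexing="ij")
        return zz**2 + yy**2 + xx**2 <= r**2

    out = {}
    for r in (10, 25):
        rep = mask_morphology(sphere(r), (100.0,) * 3)
        r_um = r * 0.1
        out[f"sphere_r{r}_volume_rel_err"] = abs(
            rep["volume_um3"] - 4 / 3 * np.pi * r_um**3
        ) / (4 / 3 * np.pi * r_um**3)
        out[f"sphere_r{r}_area_rel_err"] = abs(
            rep["surface_area_um2"] - 4 * np.pi * r_um**2
        ) / (4 * np.pi * r_um**2)

    rng = np.random.default_rng([seed, 11])
    P = rng.normal(size=(120, 3)) * [2000.0, 800.0, 300.0]
    df = pd.DataFrame({"x_nm": P[:, 0], "y_nm": P[:, 1], "z_nm": P[:, 2]})
    base = normalize_nucleus(df)[["x_norm", "y_norm", "z_norm"]].to_numpy()
    th = float(rng.uniform(0, 2 * np.pi))
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    xy = P[:, :2] @ rot.T
    df2 = pd.DataFrame({"x_nm": xy[:, 0], "y_nm": xy[:, 1], "z_nm": P[:, 2]})
    rotated = normalize_nucleus(df2)[["x_norm", "y_norm", "z_norm"]].to_numpy()
    out["normalization_rotation_max_dev"] = float(np.abs(base - rotated).max())
    out["normalization_bounds_ok"] = float(
        np.allclose(base.min(0), 0, atol=1e-9)
        and np.allclose(base.max(0), [4, 2, 1], atol=1e-9)
    )

    bi_rng = np.random.default_rng([seed, 12])
    bimodal = np.concatenate([bi_rng.normal(100, 10, 100), bi_rng.normal(500, 10, 100)])
    dip_stat, p_bi = dip_mod.dip_bimodality(bimodal, n_boot=2000, seed=_sub_seed(seed, 13))
    null = dip_mod.uniform_null_dips(200, 2000, seed=_sub_seed(seed, 14))
    uni_ps = [
        dip_mod.dip_pvalue(
            dip_mod.dip_statistic(np.random.default_rng([_sub_seed(seed, 15), s]).normal(size=200)),
            null,
        )
        for s in range(20)
    ]
    out["n_sample"] = 200
    out["dip_bimodal_p"] = p_bi
    out["dip_bimodal_stat"] = dip_stat
    out["dip_unimodal_p_gt_0.1_fraction"] = float(np.mean(np.array(uni_ps) > 0.1))
    return out
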