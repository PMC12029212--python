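import logging
import warnings

import numpy as np
import pandas as pd
import pytest

from nlo.synth import GenomeSpec, PlantedDomain, PlantedPeak, make_tsa_replicates
from nlo.tracks import BinnedTrack

logging.getLogger("hmmlearn.base").setLevel(logging.ERROR)
warnings.filterwarnings("ignore", message="Model is not converging")


@pytest.fixture
def small_spec():
    return GenomeSpec({"chr1": 500 * 25_000, "chr2": 300 * 25_000}, seed=11)


def make_track(values, bin_size=25_000, chrom="chr1", **labels) -> BinnedTrack:
    return BinnedTrack(bin_size=bin_size, data={chrom: np.asarray(values, dtype=float)}, **labels)


def planted_peak_genome(seed, n_peaks=20, spacing=(80, 121), noise_sd=1.0):
    """A realistic speckle-peak genome: one peak every ~2-3 Mb, amp 3-6x noise."""
    rng = np.random.default_rng([seed, 9])
    apex_bins, pos = [], 50
    while len(apex_bins) < n_peaks:
        apex_bins.append(pos)
        pos += int(rng.integers(*spacing))
    spec = GenomeSpec({"chr1": (pos + 50) * 25_000}, seed=seed)
    peaks = [
        PlantedPeak("chr1", int(b * 25_000 + 12_500), float(rng.uniform(3, 6)), 100_000.0)
        for b in apex_bins
    ]
    r1, r2 = make_tsa_replicates(spec, peaks, rep_noise_sd=noise_sd)
    return r1, r2, apex_bins


def planted_domain_genome(seed, n_bins_per_chrom=2500, noise_sd=0.4):
    """Two-cell-type genome with per-domain planted LAD / p-w-v / v classes."""
    from nlo.synth import make_damid_track

    spec = GenomeSpec(
        {"chr1": n_bins_per_chrom * 25_000, "chr2": n_bins_per_chrom * 25_000}, seed=seed
    )
    rng = spec.rng(8)
    classes = ["LAD", "pwv_fiLAD", "v_fiLAD"]
    doms = []
    for chrom in spec.chrom_sizes:
        pos, ci = 100, 0
        while pos < n_bins_per_chrom - 220:
            w = int(rng.integers(25, 50))
            cls = classes[ci % 3]
            ci += 1
            doms.append(
                PlantedDomain(
                    chrom, pos * 25_000, (pos + w) * 25_000, cls, 2.0,
                    per_celltype_class={"A": "LAD", "B": cls},
                )
            )
            pos += w + int(rng.integers(50, 90))
    track_a = make_damid_track(spec, doms, noise_sd=noise_sd, autocorr=0.5, cell_type="A")
    spec_b = GenomeSpec(spec.chrom_sizes, seed=seed + 10_000)
    track_b = make_damid_track(spec_b, doms, noise_sd=noise_sd, autocorr=0.5, cell_type="B")
    return doms, track_a, track_b


def match_planted_domain(df: pd.DataFrame, dom) -> pd.Series | None:
    ov = df[(df["chrom"] == dom.chrom) & (df["start"] < dom.end) & (df["end"] > dom.start)]
    if len(ov) == 0:
        return None
    overlap = np.minimum(ov["end"], dom.end) - np.maximum(ov["start"], dom.start)
    return ov.iloc[int(np.argmax(overlap))]
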