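# nlo — nuclear locale organization toolkit

Tools for analysing nuclear genome organization relative to three nuclear
locales: nuclear speckles (SON TSA-seq), the nuclear lamina (LMNB1 TSA-seq
and DamID), and nucleoli (MKI67IP TSA-seq).  TSA-seq scores encode the
estimated cytological distance of each genomic bin to a stained nuclear
structure; lamina DamID log-ratios encode molecular contact with Lamin B1.
`nlo` implements the genomic segmentations, replication-timing statistics,
and 3D-geometry computations this kind of study needs, for people who want
to re-run or adapt them: computational biologists working with TSA-seq /
DamID / multi-fraction Repli-seq tracks, chromatin-tracing (multiplex
FISH) probe tables, or segmented nuclear-body images.

What it computes:

* **Speckle peaks** — SON TSA-seq local maxima via LOESS smoothing
  (span = 0.005) and a centered ±w-bin maximum filter (w = 50 at 25 kb
  bins), with (span, w) optimized by peak agreement between replicates
  (Jaccard over one-to-one matched apexes), and Type I / Type II labels
  from Hi-C subcompartment overlap (A1 → I, A2/B1 → II).
* **LADs and facultative iLADs** — lamina-associated domains from a
  deterministic 2-state Gaussian HMM on DamID log-ratios; a cross-cell-type
  consensus; per cell type the three-class scheme LAD / p-w-v fiLAD /
  v fiLAD driven by local enrichment (domain minus flank mean), with v
  fiLADs below the 5th percentile of the LAD enrichment distribution; and
  the 0–7 cLAD score over 100 kb bins.
* **Scatter-space classes** — the printed SON-vs-LMNB1 rules: ROI lines
  (LMNB1 < −1.5·SON − 1.3 / − 2.2), LAD quadrants around (−3.0, 0.25), the
  equatorial-LAD thresholds (LMNB1 > 0.75 / SON < 0.98), and
  count-thresholded 2D overlay histograms (≥ 10 bins per pixel).
* **Replication timing** — E/L log-ratios, Trep (S-phase coordinate at
  cumulative ½) and Twidth (quartile span) from 16-fraction Repli-seq
  profiles, initiation-zone calling on the earliness track, and
  early → late IZ quartile classes.
* **Function linkage** — per-gene Δ tables across cell types (z-normalized
  TSA changes, log2 FPKM ratios with pseudocount 1), multi-predictor OLS
  with CIs, speckle association fractions (< 250 nm), and Hartigan's dip
  test with Monte-Carlo p-values.
* **3D geometry** — marching-cubes volume/surface/SA-V morphology and
  asymmetric nearest-surface distances of locale masks, the tyramide
  diffusion field B·e^(−R·d) (B = 5.86, R = 3 µm⁻¹), PCA rotation and
  4×2×1 min-max normalization of chromatin-tracing nuclei, equatorial
  polarity metrics, centromere distances, and morphology PCA.
* **Synthetic data** — seeded generators for all of the above with planted
  ground truth (domains, peaks, Trep/Twidth, nuclei, polarity-biased probe
  clouds), written as bedGraph/BED/TSV/TIFF plus JSON truth sidecars.

## Worked example

Plant 20 speckle peaks (one per 2–3 Mb, amplitudes 3–6× the replicate
noise) in two synthetic SON TSA-seq replicates, optimize (span, w) by
replicate agreement, and call peaks:

```python
import pandas as pd
from nlo.benchmarks import planted_peak_tracks
from nlo.peaks import optimize_parameters, call_peaks, match_peaks

rep1, rep2, planted_bins = planted_peak_tracks(seed=1)
span, w, surface = optimize_parameters(rep1, rep2,
                                       span_grid=(0.005, 0.01, 0.02),
                                       w_grid=(10, 25, 50), tol=2)
print("selected span,w:", span, w)

called = call_peaks(rep1, span, w)
truth = pd.DataFrame({"chrom": "chr1", "apex_bin": planted_bins})
m = len(match_peaks(called, truth, tol=2))
print(f"called={len(called)} planted={len(planted_bins)} matched={m} "
      f"sens={m/len(planted_bins):.2f} prec={m/len(called):.2f}")
```

prints

```
selected span,w: 0.01 50
called=20 planted=20 matched=20 sens=1.00 prec=1.00
```

— the optimizer picks a smoothing span of 1% of the chromosome and the
±50-bin window, and every planted apex is recovered within ±2 bins (50 kb)
with no spurious calls.  The head of the peak table:

```
  chrom  apex_bin  apex_bp     score          type
0  chr1        50  1262500  2.437792  unclassified
1  chr1       141  3537500  4.016825  unclassified
2  chr1       247  6187500  3.275438  unclassified
```

(`score` is the LOESS-smoothed apex value; `type` stays unclassified until
a subcompartment annotation is supplied to `classify_peaks`.)

The same workflows are scriptable from the shell via the `nlo` command
(`nlo synth …`, `nlo tracks …`, `nlo peaks …`, `nlo domains …`,
`nlo scatter …`, `nlo repli …`, `nlo link …`, `nlo geom …`); every
subcommand reads and writes plain-text formats (bedGraph, BED, TSV) or
TIFF stacks with JSON headers.

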