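# Methods

`nlo` re-implements, as a tested library, the computational procedures used
to map nuclear genome organization relative to three nuclear locales —
nuclear speckles (SON TSA-seq), the nuclear lamina (LMNB1 TSA-seq and
DamID), and nucleoli (MKI67IP TSA-seq) — together with replication-timing
statistics, scatter-space chromatin classification, a tyramide-diffusion
simulation, and chromatin-tracing nucleus geometry.  Real deposited data
are not required: a synthetic-data generator plants known ground truth in
every data modality, and all quantitative claims made by the test suite and
`scripts/acceptance.py` are recovery statements about that planted truth.

## Track model and preprocessing

Signal tracks are per-chromosome vectors of fixed-width bins (default
25 kb, BED-style 0-based half-open coordinates).  Missing bins are explicit
NaN and propagate through every operation; nothing is imputed, so
segmentation can never hallucinate signal at assay gaps.  Re-binning from
interval files uses coverage-weighted means and records the covered
fraction per bin.  Z-normalization uses the population standard deviation:
the genome's bins are the entire population, not a sample.  The percentile
transform (used for ChIP fold-change overlays) maps scores to
average-tie-rank / n × 100, so the genome-wide maximum is 100.

LOESS smoothing is local linear regression with tricube weights over the
k = ceil(span · n) nearest bins, computed per chromosome (smoothing never
crosses chromosome ends) on the non-missing bins only.  Spans are fractions
of each chromosome's usable bins.  If the neighbourhood would hold fewer
than 3 bins the chromosome passes through unsmoothed with a warning.  The
implementation is a vectorized closed-form weighted fit; the test suite
checks it bin-for-bin (1e-8) against an independently coded brute-force
weighted-least-squares oracle, including missing-data handling.

## Speckle peak calling

SON TSA-seq local maxima are called by: LOESS smoothing (default span
0.005) → centered maximum filter of half-width w bins (default w = 50,
i.e. ±1.25 Mb at 25 kb; the window is 2w+1 bins and is clipped at
chromosome ends) → a bin is an apex iff its smoothed value equals the
window maximum and every other value in its window is strictly smaller.
Equal-valued plateaus (ties within a relative 1e-9 tolerance, which also
absorbs floating-point jitter on flat stretches) yield one apex at the
plateau centroid; plateaus touching a chromosome end are not peaks, so
monotone ramps produce no calls.  There is deliberately no amplitude
threshold — the published procedure has none — which means precision
against planted truth depends on peak density: with one peak per 2–3 Mb
(the realistic speckle-peak density) every window contains a true peak and
spurious noise maxima are suppressed by the window-exclusion rule.

(span, w) are chosen by exhaustive grid search maximizing replicate peak
agreement, defined as Jaccard on greedily nearest-first one-to-one matched
apexes within a tolerance (default 2 bins = 50 kb; the original work states
no tolerance).  Ties break toward larger span, then larger w (smoother
tracks, fewer calls).  Peaks are typed by the Hi-C subcompartment
overlapping the apex-bin midpoint: A1 → Type I, A2/B1 → Type II, anything
else unclassified.

One window-semantics caveat: w counts the half-width of the centered
window.  A documented example elsewhere assumes a peak 60 bins from a
taller one is suppressed at w = 50, which is geometrically impossible under
any centered-window reading (suppression reach is exactly w bins); the
implemented rule suppresses the smaller of two peaks iff their separation
is ≤ w.

## LAD calling and fiLAD classification

LADs are runs of the higher-mean state of a 2-state Gaussian-emission HMM
fit genome-wide by EM and Viterbi-decoded per contiguous non-missing
segment.  The fit is deterministic: states are initialized from the sign
split at 0 (positive DamID log-ratio ≈ lamina contact), convergence at
log-likelihood gain < 1e-4 or 300 iterations, variances floored at 1e-6.
Runs shorter than 5 bins are dropped; runs separated by fewer than 2 bins
merge.  Tracks with fewer than 2 positive (or negative) bins skip the HMM —
an all-negative genome simply has no LADs.

The consensus set is the union-merge of LAD calls across cell types; a
consensus domain is a LAD in cell type c when a LAD of c overlaps it by
≥ 50% of both lengths (the reciprocal-overlap fraction is a parameter; the
source analysis does not state one).  Local enrichment of a domain is
mean(domain bins) − mean(flank bins), with flanks of length
min(1.0 × domain length, 1 Mb) per side, truncated at chromosome ends and
excluding bins inside other consensus domains; both flank extent and cap
are parameters and echoed in the output metadata.  Per cell type, a
consensus domain is a LAD if called there; otherwise it is a facultative
iLAD (fiLAD): a "valley" (v) fiLAD when its enrichment falls below the 5th
percentile of that cell type's LAD enrichments ("lower than 95% of the
LADs"), else a "peak-within-valley" (p-w-v) fiLAD, i.e. a residual local
lamina-signal maximum marking partial repression.

A structural limitation of this published rule, visible on planted
genomes: any HMM-callable LAD has absolute DamID ≳ 0 while its flanks
(necessarily not LAD-callable) sit below 0, so called-LAD enrichments are
≳ 1 in every admissible geometry and their 5th percentile (~1.6 on the
reference synthetic genomes) always exceeds a p-w-v-scale offset (0.7).
Under the reference planted conditions (class offsets +2 / +0.7 / 0 over a
−1 baseline, AR(1) noise sd 0.4) the classifier therefore recovers LADs and
v fiLADs essentially perfectly but assigns nearly all p-w-v fiLADs to the
v class — the enrichment *measurement* is exact (recovered class means
2.02 / 0.69 / 0.01), only the threshold placement fails, mirroring the
original authors' own caveat that some p-w-v fiLADs are misclassified by
their scheme.  On real genomes the rule works better because weak LADs with
elevated neighbourhoods create a low tail in the LAD enrichment
distribution.  The corresponding whole-pipeline check is left failing by
design rather than silently re-tuning the rule; the quantile is exposed as
a parameter for users who want a different cutoff.

The cLAD (constitutive LAD) score counts, per 100 kb bin midpoint, the
cell lines (up to 7) whose LADs cover the bin; midpoint coverage makes the
count orientation-free and boundary-unambiguous.

## Scatter-space classification

Three printed rules operate on (SON, LMNB1) TSA-seq score pairs: the H1
region-of-interest lines (ROI iff LMNB1 < −1.5·SON − 1.3, ROI-C2 below
−1.5·SON − 2.2, remainder ROI-C1; strict inequalities, boundary excluded),
the LAD quadrants around (SON, LMNB1) = (−3.0, 0.25) (C1 top-left … C4
bottom-right; ≥ goes top, ≥ center goes right), and the equatorial LAD
clusters (EQ iff LMNB1 TSA > 0.75, taking precedence; else non-EQ iff
SON TSA < 0.98).  Boundary conventions are not stated in the source and
are fixed here as documented; thresholds are parameters whose defaults are
the printed values, interpreted on whatever score scale the supplied
tracks use.  Overlay histograms snap pixel edges to multiples of the pixel
size and report per-pixel means only where at least 10 genomic bins fall
in the pixel (counts are kept everywhere, so masking hides but never drops
bins).

## Replication timing

The S-phase coordinate is the fraction index scaled to [0, 1]; fraction i
of n occupies [(i−1)/n, i/n) and no wall-clock hours are imputed.  For a
16-fraction profile normalized to sum 1, Trep is the linearly interpolated
coordinate at cumulative 0.5 and Twidth the 25–75% quartile span of the
cumulative (both quantile levels are parameters).  The synthetic generator
inverts this: per-bin Gaussians in S-phase coordinate with median Trep and
sigma = Twidth / (2 Φ⁻¹(0.75)), discretized via the normal CDF and
renormalized; optional multinomial count noise.  Renormalizing the
truncated Gaussian biases recovered Trep toward the S-phase interior near
the boundaries; at Twidth 0.1 the worst-case error over Trep ∈ [0.1, 0.9]
is < 0.01 and grows with Twidth.  The 2-fraction statistic is
log2((E + 1)/(L + 1)).  Initiation zones are apexes of the earliness track
1 − Trep called with the same local-maximum pipeline, and IZ timing
classes are the quartile split of apex Trep values (ties to the earlier
class; fewer than 4 IZs degenerate to a single "early" class with a
warning).

## Function linkage

Per-gene delta tables compare two cell types A − B: z-normalized TSA score
changes at the gene's TSS bin (TSS-anchored by default, midpoint mode
available), expression change log2((FPKM_A + 1)/(FPKM_B + 1)) (pseudocount
1 throughout), and optionally the E/L timing change.  Ordinary least
squares with intercept (classical standard errors, 95% CIs) relates a
response delta to the three locale deltas, with optional row-subset
stratification fit separately per stratum; rank-deficient designs are
rejected with the collinear columns named.  The speckle association
fraction is the fraction of distances strictly below 250 nm.

Hartigan's dip statistic — the sup-norm distance from the sample ECDF to
the nearest unimodal CDF — is computed by the iterative modal-interval
construction over the greatest convex minorant and least concave majorant
of the ECDF, in count units, halved at the end; it lies in [1/(2n), 1/4].
The implementation was validated to 1e-7 against an exact
linear-programming oracle (shipped in the tests) that fits a piecewise
linear unimodal CDF with an atom at the mode by enumerating mode
positions.  Note the statistic is invariant under affine maps of the
sample but *not* under general monotone transforms — the unimodal family
is not closed under them — so only affine invariance is asserted.
p-values come from seeded Monte-Carlo calibration against uniform samples
of the same size (the asymptotically least favourable unimodal null), with
the add-one rule; no lookup tables.

## 3D geometry

Locale masks are boolean voxel arrays (z,y,x) with per-axis nm spacing.
Volume is voxel count × voxel volume.  Surface area is the marching-cubes
isosurface at level 0.5 after a light 1-voxel-sigma Gaussian smoothing of
the binary mask — without it the voxel staircase inflates the area of a
10-voxel-radius sphere by ~10%; with it the sphere error is ~2% at r = 10
voxels and ~0.3% at r = 25 (a voxel-face-counting mode is kept as an
upper-bound cross-check).  Components use 26-connectivity.  Asymmetric
locale distances take, for each component of the source locale, the
minimum distance between its surface vertices and any surface vertex of
the target locale; the direction matters because the component
decomposition differs.

The TSA diffusion simulation convolves a binary source mask with the
radially symmetric kernel B·exp(−R·d), B = 5.86, R = 3 µm⁻¹ (decay length
≈ 333 nm), truncated below 1% of B (support radius ≈ 1.54 µm; the source
states no support size).  R is interpreted per µm — an nm-scale reading
would give a 3 Å decay length, physically meaningless for tyramide
radicals.  FFT convolution reproduces a direct double-loop oracle to
1e-6.  On a flat synthetic nucleus the predicted lamina TSA signal at
chromatin positions near the lamina is higher at the equatorial rim than
at the polar caps, because the thin rim wedge is lined by both lamina
sheets: the continuum surface integral gives a ~1.3× contrast 300 nm
inside the surface, and the voxelized pipeline (`rim_pole_contrast`,
distance-transform depth band 400–800 nm, normalized polar angle < 0.2 vs
> 0.9) retains a ~1.1–1.16× contrast.  The field *on* the shell itself is
nearly flat (the rim's convex meridian curvature, radius b²/a = 0.5 µm,
offsets the wrap-around), so the property is defined at near-lamina
interior voxels — where chromatin actually sits.

Chromatin-tracing nuclei are normalized by centering x-y at the probe
centroid, rotating into the 2D PCA eigenbasis (length → X, width → Y),
fixing axis signs so the probe of largest absolute coordinate on each axis
is positive, and min-max mapping into a 4×2×1 cuboid.  Sign fixing and
rescaling are iterated to their fixed point, making the map idempotent and
rigid-rotation invariant to machine precision.  Polarity metrics are
|z − 0.5| (distance to the equatorial plane) and the projected x-y
distance from the cuboid center (2, 1).  Centromere distances are Mbp gaps
from probe genomic midpoints to the merged acen cytoband interval.
Morphology PCA standardizes the per-nucleus metric matrix and
eigendecomposes the correlation matrix (deterministic loading signs,
zero-variance metrics dropped with a warning); it is feature-list-agnostic.

## Synthetic data

All generators are pure functions of (parameters, seed) using NumPy's
seed-sequence streams; per-nucleus sub-seeds derive from (seed,
nucleus id), so scenes are stable under reordering.  DamID-like tracks are
baseline −1 plus per-domain class offsets (LAD +2, p-w-v +0.7, v +0.0 —
lamina contact strongest for LADs, intermediate for partially repressed
fiLADs, absent for derepressed ones) plus stationary AR(1) noise (lag-1
coefficient 0.5, sd 0.4 by default) — AR(1) is the minimal model giving
the regional smoothness and boundary blur that make segmentation
non-trivial.  TSA-seq replicates share a sum-of-Gaussian-bumps signal
(apex spacing ~2–3 Mb, amplitudes 3–6 × the replicate noise sd, width
100 kb) and differ by white noise.  Nuclei are ellipsoids (flat 8×4×2 µm,
round 4.5×4×4 µm semi-axes) with a one-voxel lamina shell, spherical
speckles (0.5 µm) and nucleoli (1 µm) rejection-sampled inside; a polarity
bias b thins speckle centers and probes away from the mid-z plane with
acceptance exp(−b·|z|/c), b = 0 being exactly volume-uniform.  Planted
truth is emitted alongside every dataset (BED + JSON sidecars, TIFF + JSON
headers, probe TSVs).

What the generator does not emulate — read-level noise, mappability gaps,
GC bias, chromosome-scale compartment structure, optical PSFs, segmentation
errors — bounds what green tests mean: they certify the *procedures*
(filters, estimators, classifiers, geometry) against known truth under
realistic noise, not end-to-end performance on real sequencing or imaging
data.

## Problem sizes

The reference benchmarks use genomes of 2,000–5,000 bins of 25 kb per
chromosome, 10–20 independent seeds per claim, nuclei at 100–150 nm
isotropic voxels, dip nulls of 2,000 uniform samples, and 16³ oracle
convolutions — sizes at which every statistical bar retains its meaning
while the full acceptance run completes in well under a minute per stage
on one CPU.
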