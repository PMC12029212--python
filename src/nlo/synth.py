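"""Synthetic genomes, tracks, Repli-seq profiles, nuclei, and probe clouds.

Every generator is a pure function of its parameters and a seed, and emits
its planted ground truth alongside the data so recovery tests never have to
re-derive it.  The generators emulate the *shape* of the real assays —
regionally autocorrelated lamina DamID log-ratios with domain structure,
smooth speckle TSA-seq with replicate noise, 16-fraction Repli-seq with
known Trep/Twidth, ellipsoidal nuclei with locale masks, polarity-biased
probe clouds — not sequencing reads or microscope optics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tracks import BinnedTrack

__all__ = [
    "GenomeSpec",
    "PlantedDomain",
    "PlantedPeak",
    "NucleusScene",
    "make_damid_track",
    "make_tsa_replicates",
    "make_repli_profiles",
    "make_nucleus_scene",
    "write_track_with_truth",
    "write_scene",
]

CLASS_ORDER = {"LAD": 2, "pwv_fiLAD": 1, "v_fiLAD": 0}


@dataclass
class GenomeSpec:
    """A synthetic genome: chromosome sizes, bin width, and master seed."""

    chrom_sizes: dict[str, int]
    bin_size: int = 25_000
    seed: int = 0

    def __post_init__(self) -> None:
        if any(l <= 0 for l in self.chrom_sizes.values()):
            raise ValueError("chromosome lengths must be positive")
        # truncate to whole bins
        self.chrom_sizes = {
            c: (l // self.bin_size) * self.bin_size for c, l in self.chrom_sizes.items()
        }
        if any(l == 0 for l in self.chrom_sizes.values()):
            raise ValueError("chromosome shorter than one bin")

    def n_bins(self, chrom: str) -> int:
        return self.chrom_sizes[chrom] // self.bin_size

    def empty_track(self, fill: float = 0.0, **labels) -> BinnedTrack:
        return BinnedTrack(
            bin_size=self.bin_size,
            data={c: np.full(self.n_bins(c), fill) for c in self.chrom_sizes},
            **labels,
        )

    def rng(self, *subkeys: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, *subkeys])


@dataclass
class PlantedDomain:
    """A planted lamina domain with its true class per cell type."""

    chrom: str
    start: int
    end: int
    true_class: str = "LAD"
    damid_mean: float = 2.0
    per_celltype_class: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("domain end must exceed start")
        if self.true_class not in CLASS_ORDER:
            raise ValueError(f"unknown domain class {self.true_class!r}")


@dataclass
class PlantedPeak:
    """A planted speckle TSA-seq local maximum (Gaussian bump)."""

    chrom: str
    apex_bp: int
    amplitude: float
    width_bp: float
    true_type: str = "I"

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("peak amplitude must be positive")
        if self.true_type not in ("I", "II"):
            raise ValueError("peak type must be 'I' or 'II'")


def _check_nonoverlapping(domains: list[PlantedDomain]) -> None:
    by_chrom: dict[str, list[PlantedDomain]] = {}
    for d in domains:
        by_chrom.setdefault(d.chrom, []).append(d)
    for chrom, ds in by_chrom.items():
        ds = sorted(ds, key=lambda d: d.start)
        for a, b in zip(ds, ds[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping domains on {chrom}: "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )


def _ar1(rng: np.random.Generator, n: int, sd: float, autocorr: float) -> np.ndarray:
    """Stationary AR(1) noise with lag-1 coefficient ``autocorr`` and sd ``sd``."""
    if not 0 <= autocorr < 1:
        raise ValueError("autocorr must be in [0, 1)")
    if sd == 0 or n == 0:
        return np.zeros(n)
    innov_sd = sd * np.sqrt(1.0 - autocorr**2)
    e = rng.normal(0.0, innov_sd, size=n)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    for t in range(1, n):
        x[t] = autocorr * x[t - 1] + e[t]
    return x


def make_damid_track(
    spec: GenomeSpec,
    domains: list[PlantedDomain],
    noise_sd: float = 0.4,
    autocorr: float = 0.5,
    baseline: float = -1.0,
    class_offsets: dict[str, float] | None = None,
    cell_type: str = "",
) -> BinnedTrack:
    """Lamina DamID-like log-ratio track with planted domains and AR(1) noise.

    Track value = baseline + domain offset + stationary AR(1) noise.  The
    per-domain offset is ``damid_mean`` unless ``cell_type`` is given and the
    domain carries a class for it, in which case ``class_offsets`` maps that
    class to the offset (defaults LAD +2, p-w-v fiLAD +0.7, v fiLAD +0.0 —
    lamina contact strongest for LADs, intermediate for partially repressed
    fiLADs, absent for fully derepressed ones).
    """
    _check_nonoverlapping(domains)
    if class_offsets is None:
        class_offsets = {"LAD": 2.0, "pwv_fiLAD": 0.7, "v_fiLAD": 0.0}
    rng = spec.rng(1)
    data = {}
    for i, chrom in enumerate(spec.chrom_sizes):
        n = spec.n_bins(chrom)
        v = np.full(n, baseline)
        for d in domains:
            if d.chrom != chrom:
                continue
            b0 = d.start // spec.bin_size
            b1 = -(-d.end // spec.bin_size)
            if cell_type and cell_type in d.per_celltype_class:
                off = class_offsets[d.per_celltype_class[cell_type]]
            else:
                off = d.damid_mean
            v[b0:b1] += off
        v += _ar1(rng, n, noise_sd, autocorr)
        data[chrom] = v
    return BinnedTrack(
        bin_size=spec.bin_size, data=data, assay="LMNB1_DamID", cell_type=cell_type
    )


def make_tsa_replicates(
    spec: GenomeSpec,
    peaks: list[PlantedPeak],
    rep_noise_sd: float = 0.5,
    n_reps: int = 2,
    baseline: float = 0.0,
) -> list[BinnedTrack]:
    """Speckle TSA-seq-like replicate tracks with planted Gaussian bumps.

    The signal component (sum of bumps evaluated at bin midpoints) is shared
    across replicates; each replicate adds independent white noise.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    signal = {}
    for chrom in spec.chrom_sizes:
        n = spec.n_bins(chrom)
        mid = (np.arange(n) + 0.5) * spec.bin_size
        v = np.full(n, float(baseline))
        for p in peaks:
            if p.chrom == chrom:
                v += p.amplitude * np.exp(-0.5 * ((mid - p.apex_bp) / p.width_bp) ** 2)
        signal[chrom] = v
    reps = []
    for r in range(n_reps):
        rng = spec.rng(2, r)
        data = {
            c: v + (rng.normal(0.0, rep_noise_sd, size=len(v)) if rep_noise_sd else 0.0)
            for c, v in signal.items()
        }
        reps.append(
            BinnedTrack(bin_size=spec.bin_size, data=data, assay="SON_TSA")
        )
    return reps


def make_repli_profiles(
    n_bins: int,
    trep: np.ndarray,
    twidth: np.ndarray,
    n_fractions: int = 16,
    counts_per_bin: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """16-fraction Repli-seq profiles with known Trep/Twidth per bin.

    Each bin's incorporation profile is a Gaussian in the S-phase coordinate
    (fraction i of n occupies [(i-1)/n, i/n)) with median ``trep`` and sigma
    chosen so the quartile width (25th-75th) equals ``twidth``; the Gaussian
    mass per fraction is computed from the normal CDF and renormalized to
    sum 1.  With ``counts_per_bin`` set, multinomial count noise is added and
    the counts renormalized.

    Returns an array of shape ``(n_bins, n_fractions)`` whose rows sum to 1.
    """
    from scipy.stats import norm

    trep = np.broadcast_to(np.asarray(trep, dtype=float), (n_bins,))
    twidth = np.broadcast_to(np.asarray(twidth, dtype=float), (n_bins,))
    if np.any(twidth <= 0):
        raise ValueError("twidth must be positive")
    iqr_factor = 2.0 * norm.ppf(0.75)  # quartile width of a unit normal
    sigma = twidth / iqr_factor
    edges = np.arange(n_fractions + 1) / n_fractions
    z = (edges[None, :] - trep[:, None]) / sigma[:, None]
    cdf = norm.cdf(z)
    mass = np.diff(cdf, axis=1)
    mass = np.clip(mass, 0.0, None)
    tot = mass.sum(axis=1, keepdims=True)
    if np.any(tot <= 0):
        raise ValueError("degenerate profile: no mass inside S phase")
    mass /= tot
    if counts_per_bin is not None:
        rng = np.random.default_rng([seed, 3])
        counts = np.array([rng.multinomial(counts_per_bin, row) for row in mass], dtype=float)
        mass = counts / counts.sum(axis=1, keepdims=True)
    return mass


@dataclass
class NucleusScene:
    """Voxel masks and probe coordinates for one nucleus.

    ``masks`` (axis order z,y,x): ``nucleus`` is the solid interior used for
    volume/shape morphology, ``NP`` the one-voxel-thick lamina shell,
    ``speckle`` and ``nucleolus`` the nuclear-body masks.  ``voxel_nm`` is
    (z,y,x) spacing; ``truth`` records planted body centers (nm, x/y/z
    relative to the nucleus center) and the polarity bias.
    """

    masks: dict[str, np.ndarray]
    voxel_nm: tuple[float, float, float]
    nucleus_id: int = 0
    probes: pd.DataFrame | None = None
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_nm):
            raise ValueError("voxel_nm must be positive")
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ValueError("masks must share one shape")


def _sample_in_ellipsoid(
    rng: np.random.Generator,
    semi_nm: tuple[float, float, float],
    n: int,
    polarity_bias: float,
    margin_nm: float = 0.0,
    max_tries: int = 200_000,
) -> np.ndarray:
    """Rejection-sample points in an ellipsoid (x,y,z nm, centered at 0).

    ``polarity_bias`` b >= 0 thins points away from the equatorial (mid-z)
    plane with acceptance probability exp(-b*|z|/c); b=0 is volume-uniform.
    """
    a, b_, c = semi_nm
    a, b_, c = a - margin_nm, b_ - margin_nm, c - margin_nm
    if min(a, b_, c) <= 0:
        raise ValueError("margin exceeds ellipsoid semi-axis")
    out = np.empty((n, 3))
    got = 0
    tries = 0
    while got < n:
        m = max(4 * (n - got), 64)
        tries += m
        if tries > max_tries:
            raise RuntimeError("could not place points inside ellipsoid")
        p = rng.uniform(-1, 1, size=(m, 3)) * [a, b_, c]
        keep = (p[:, 0] / a) ** 2 + (p[:, 1] / b_) ** 2 + (p[:, 2] / c) ** 2 <= 1.0
        if polarity_bias > 0:
            keep &= rng.uniform(size=m) < np.exp(-polarity_bias * np.abs(p[:, 2]) / c)
        p = p[keep]
        take = min(len(p), n - got)
        out[got : got + take] = p[:take]
        got += take
    return out


def make_nucleus_scene(
    shape: str = "flat",
    voxel_nm: float = 125.0,
    n_speckles: int = 10,
    n_nucleoli: int = 2,
    polarity_bias: float = 0.0,
    seed: int = 0,
    semi_axes_um: tuple[float, float, float] | None = None,
    speckle_radius_um: float = 0.5,
    nucleolus_radius_um: float = 1.0,
    n_probes: int = 0,
    nucleus_id: int = 0,
) -> NucleusScene:
    """Synthetic nucleus: ellipsoidal interior, lamina shell, nuclear bodies.

    ``shape`` 'flat' (adherent-like, semi-axes 8x4x2 um) or 'round'
    (suspension-like, 4.5x4x4 um); override via ``semi_axes_um`` (x,y,z).
    Speckle/nucleolus centers are sampled inside the nucleus with a margin of
    one body radius; ``polarity_bias`` > 0 concentrates speckles (and probes)
    toward the equatorial z-plane.  A per-nucleus sub-seed derived from
    (seed, nucleus_id) makes each nucleus stable under reordering.
    """
    if voxel_nm <= 0:
        raise ValueError("voxel_nm must be positive")
    if semi_axes_um is None:
        semi_axes_um = (8.0, 4.0, 2.0) if shape == "flat" else (4.5, 4.0, 4.0)
    semi_nm = tuple(1000.0 * s for s in semi_axes_um)  # (x, y, z)
    body_vol = n_speckles * (4 / 3) * np.pi * speckle_radius_um**3 + n_nucleoli * (
        4 / 3
    ) * np.pi * nucleolus_radius_um**3
    nuc_vol = (4 / 3) * np.pi * np.prod(semi_axes_um)
    if body_vol > 0.5 * nuc_vol:
        raise ValueError("locale volume exceeds packable nuclear volume")
    rng = np.random.default_rng([seed, nucleus_id])

    pad = 2
    nx, ny, nz = (int(np.ceil(2 * s / voxel_nm)) + 2 * pad for s in semi_nm)
    zc, yc, xc = np.meshgrid(
        (np.arange(nz) + 0.5) * voxel_nm - nz * voxel_nm / 2,
        (np.arange(ny) + 0.5) * voxel_nm - ny * voxel_nm / 2,
        (np.arange(nx) + 0.5) * voxel_nm - nx * voxel_nm / 2,
        indexing="ij",
    )
    r2 = (xc / semi_nm[0]) ** 2 + (yc / semi_nm[1]) ** 2 + (zc / semi_nm[2]) ** 2
    nucleus = r2 <= 1.0
    from scipy.ndimage import binary_erosion

    shell = nucleus & ~binary_erosion(nucleus)

    def ball_mask(centers: np.ndarray, radius_nm: float) -> np.ndarray:
        m = np.zeros_like(nucleus)
        for cx, cy, cz in centers:
            d2 = (xc - cx) ** 2 + (yc - cy) ** 2 + (zc - cz) ** 2
            m |= d2 <= radius_nm**2
        return m

    sp_centers = (
        _sample_in_ellipsoid(rng, semi_nm, n_speckles, polarity_bias, 1000 * speckle_radius_um)
        if n_speckles
        else np.empty((0, 3))
    )
    nuc_centers = (
        _sample_in_ellipsoid(rng, semi_nm, n_nucleoli, 0.0, 1000 * nucleolus_radius_um)
        if n_nucleoli
        else np.empty((0, 3))
    )
    masks = {
        "nucleus": nucleus,
        "NP": shell,
        "speckle": ball_mask(sp_centers, 1000 * speckle_radius_um),
        "nucleolus": ball_mask(nuc_centers, 1000 * nucleolus_radius_um),
    }
    probes = None
    if n_probes:
        pts = _sample_in_ellipsoid(rng, semi_nm, n_probes, polarity_bias)
        probes = pd.DataFrame(
            {
                "probe_id": [f"p{nucleus_id}_{i}" for i in range(n_probes)],
                "chrom": "chr1",
                "start": np.arange(n_probes) * 100_000,
                "end": np.arange(1, n_probes + 1) * 100_000,
                "nucleus_id": nucleus_id,
                "x_nm": pts[:, 0],
                "y_nm": pts[:, 1],
                "z_nm": pts[:, 2],
            }
        )
    truth = {
        "shape": shape,
        "semi_axes_um": list(semi_axes_um),
        "speckle_centers_nm": sp_centers.tolist(),
        "nucleolus_centers_nm": nuc_centers.tolist(),
        "polarity_bias": polarity_bias,
        "speckle_radius_um": speckle_radius_um,
        "nucleolus_radius_um": nucleolus_radius_um,
    }
    return NucleusScene(
        masks=masks,
        voxel_nm=(voxel_nm, voxel_nm, voxel_nm),
        nucleus_id=nucleus_id,
        probes=probes,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# sidecar writers


def write_track_with_truth(track: BinnedTrack, truth, out_prefix) -> None:
    """Write a synthetic track as bedGraph plus its planted truth sidecars.

    ``truth`` may be a list of PlantedDomain or PlantedPeak; it is written
    both as BED (intervals / apex bins) and as a JSON sidecar.
    """
    from .tracks import write_bedgraph

    write_bedgraph(track, f"{out_prefix}.bedgraph")
    rows = []
    js = []
    for t in truth:
        if isinstance(t, PlantedDomain):
            rows.append((t.chrom, t.start, t.end, t.true_class))
            js.append(
                {
                    "chrom": t.chrom,
                    "start": t.start,
                    "end": t.end,
                    "true_class": t.true_class,
                    "damid_mean": t.damid_mean,
                    "per_celltype_class": t.per_celltype_class,
                }
            )
        elif isinstance(t, PlantedPeak):
            b = t.apex_bp // track.bin_size
            rows.append((t.chrom, b * track.bin_size, (b + 1) * track.bin_size, t.true_type))
            js.append(
                {
                    "chrom": t.chrom,
                    "apex_bp": t.apex_bp,
                    "amplitude": t.amplitude,
                    "width_bp": t.width_bp,
                    "true_type": t.true_type,
                }
            )
        else:
            raise TypeError(f"unsupported truth record {type(t)}")
    with open(f"{out_prefix}.truth.bed", "w") as fh:
        for chrom, s, e, name in sorted(rows):
            fh.write(f"{chrom}\t{s}\t{e}\t{name}\n")
    with open(f"{out_prefix}.truth.json", "w") as fh:
        json.dump(js, fh, indent=1)


def write_scene(scene: NucleusScene, out_prefix) -> None:
    """Write a nucleus as multi-page TIFFs plus a JSON header and probe TSV."""
    import tifffile

    for name, mask in scene.masks.items():
        tifffile.imwrite(f"{out_prefix}.{name}.tiff", mask.astype(np.uint8))
    header = {
        "voxel_nm": list(scene.voxel_nm),
        "axis_order": "z,y,x",
        "nucleus_id": scene.nucleus_id,
        "truth": scene.truth,
    }
    with open(f"{out_prefix}.json", "w") as fh:
        json.dump(header, fh, indent=1)
    if scene.probes is not None:
        scene.probes.to_csv(f"{out_prefix}.probes.tsv", sep="\t", index=False)
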