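"""Synthetic ULP-WGS data: bin-count generation under the tumor/normal
admixture model, binomial down-sampling, serial and exact-tumor-fraction
mixtures, spike-in constructions and a simulated healthy-donor panel.

The generator emulates ~0.1x coverage cfDNA sequencing on the hg19
autosomes binned at 1 Mb (~1.5 million reads genome-wide): per-bin
expected intensity follows the two/three-component admixture model, a
unimodal GC bias curve multiplies the intensity, and counting noise is
Poisson.  An optional gamma (negative-binomial) overdispersion knob adds
extra per-bin variance for emulating noisier libraries;
``OVERDISPERSION_ULP`` is calibrated so that tumor-free log2 ratios
spread to about 0.2 at 0.1x.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np

from .bins_io import BinGrid, CoverageTrack, build_bin_grid
from .normalize import ReferencePanel, build_reference, loess_correct

# hg19 autosome lengths (GRCh37)
HG19_AUTOSOMES: dict[str, int] = {
    "chr1": 249250621, "chr2": 243199373, "chr3": 198022430, "chr4": 191154276,
    "chr5": 180915260, "chr6": 171115067, "chr7": 159138663, "chr8": 146364022,
    "chr9": 141213431, "chr10": 135534747, "chr11": 135006516, "chr12": 133851895,
    "chr13": 115169878, "chr14": 107349540, "chr15": 102531392, "chr16": 90354753,
    "chr17": 81195210, "chr18": 78077248, "chr19": 59128983, "chr20": 63025520,
    "chr21": 48129895, "chr22": 51304566,
}

READS_PER_01X = 1_500_000          # ~0.1x genome-wide coverage

# serial-mixture benchmark design: 16 tumor proportions x 12 coverages
SERIAL_PROPORTIONS = tuple(round(0.01 + 0.02 * i, 2) for i in range(11)) + (
    0.25, 0.30, 0.35, 0.40, 0.45,
)
SERIAL_COVERAGES = (0.01, 0.05, 0.10, 0.20, 0.30, 0.40, 0.50, 0.60, 0.70, 0.80, 0.90, 1.00)
OVERDISPERSION_ULP = 0.0173        # optional extra count CV^2; sd(l) ~ 0.2 at 0.1x
GENOME_SEED = 7_919                # fixes per-bin GC/mappability annotation
PANEL_SEED = 104_729               # fixes the default 27-donor panel
SOURCE_TUMOR_PURITY = 0.78         # purity of the default high-burden source


def autosome_grid(bin_width: int = 1_000_000) -> BinGrid:
    """The hg19 autosome bin grid used throughout the simulations."""
    return build_bin_grid(HG19_AUTOSOMES, bin_width)


def genome_tracks(grid: BinGrid, seed: int = GENOME_SEED) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic per-bin GC fraction and mappability annotation.

    GC is drawn around 0.41 +/- 0.05 (clipped to [0.30, 0.60]); ~3% of
    bins get degraded mappability in [0.5, 0.9) and the rest sit in
    [0.95, 1].  These are genome properties, so they are fixed by their
    own seed and shared between samples and the donor panel.
    """
    rng = np.random.default_rng(seed)
    gc = np.clip(rng.normal(0.41, 0.05, grid.n_bins), 0.30, 0.60)
    mapp = rng.uniform(0.95, 1.0, grid.n_bins)
    low = rng.random(grid.n_bins) < 0.03
    mapp[low] = rng.uniform(0.5, 0.9, int(low.sum()))
    return gc, mapp


def quadratic_gc_bias(gc: np.ndarray, peak: float = 0.45, magnitude: float = 0.2) -> np.ndarray:
    """Unimodal coverage bias peaking at ``peak``, spanning roughly
    1 +/- ``magnitude`` over the simulated GC range."""
    curve = (1.0 + magnitude) - (2.0 * magnitude / 0.15**2) * (gc - peak) ** 2
    return np.clip(curve, 1.0 - magnitude, 1.0 + magnitude)


@dataclass
class SimProfile:
    """Ground-truth integer copy number per bin (2 = no event)."""

    grid: BinGrid
    copy_number: np.ndarray
    subclonal_fraction: np.ndarray | None = None   # per-bin s (0 = clonal)

    def __post_init__(self) -> None:
        self.copy_number = np.asarray(self.copy_number, dtype=int)
        if len(self.copy_number) != self.grid.n_bins:
            raise ValueError("copy_number length must equal number of bins")
        if np.any(self.copy_number < 0):
            raise ValueError("copy numbers must be non-negative")

    @property
    def ploidy(self) -> float:
        return float(self.copy_number[self.grid.valid].mean())

    def events(self) -> list[tuple[str, int, int, int]]:
        """Reconstruct (chrom, start, end, copies) event list from the profile."""
        out: list[tuple[str, int, int, int]] = []
        c = self.copy_number
        g = self.grid
        start = 0
        for j in range(1, g.n_bins + 1):
            if j == g.n_bins or c[j] != c[j - 1] or g.chrom[j] != g.chrom[j - 1]:
                if c[start] != 2:
                    out.append((str(g.chrom[start]), int(g.start[start]),
                                int(g.end[j - 1]), int(c[start])))
                start = j
        return out


def neutral_profile(grid: BinGrid) -> SimProfile:
    return SimProfile(grid=grid, copy_number=np.full(grid.n_bins, 2))


def high_burden_profile(grid: BinGrid) -> SimProfile:
    """A heavy-SCNA metastatic-breast-cancer-like tumor profile.

    Arm- and chromosome-scale events at mixed amplitudes (gains at 3, 4
    and 5 copies, one-copy losses), balanced so that the mean copy number
    is exactly 2; about a third of the genome is altered.  Used as the
    serial-mixture tumor source (a ~0.78-purity sample profile).
    """
    c = np.full(grid.n_bins, 2)

    def bins_of(chrom: str) -> np.ndarray:
        return np.flatnonzero(grid.chrom_mask(chrom))

    b = bins_of("chr1"); c[b[145:]] = 3            # 1q gain
    c[bins_of("chr10")] = 3                        # whole-10 gain
    b = bins_of("chr8"); c[b[48:]] = 4; c[b[:48]] = 1    # 8q amp, 8p loss
    b = bins_of("chr17"); c[b[25:]] = 4; c[b[:25]] = 1   # 17q amp, 17p loss
    b = bins_of("chr20"); c[b[:25]] = 5            # focal-ish 20p high-level amp
    for chrom in ("chr4", "chr9", "chr13", "chr22"):
        c[bins_of(chrom)] = 1                      # large losses
    # balance to mean copy exactly 2 with a loss block at the start of chr5
    excess = int((c - 2).sum())
    if excess > 0:
        c[bins_of("chr5")[:excess]] = 1
    elif excess < 0:
        c[bins_of("chr5")[:(-excess)]] = 3
    return SimProfile(grid=grid, copy_number=c)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_counts(
    profile: SimProfile,
    tf: float,
    total_reads: float = READS_PER_01X,
    gc: np.ndarray | None = None,
    mappability: np.ndarray | None = None,
    gc_bias: Callable[[np.ndarray], np.ndarray] | None = quadratic_gc_bias,
    overdispersion: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> CoverageTrack:
    """Draw a binned read-count track for a tumor/normal admixture.

    Per-bin intensity is proportional to ``2n + (1-n)(2 s_t + (1-s_t) c_t)``
    with ``n = 1 - tf``, multiplied by the GC bias curve and mappability,
    normalized to ``total_reads``, then Poisson-sampled with optional
    gamma overdispersion.  Reproducible under ``seed``.
    """
    if not (0.0 <= tf <= 1.0):
        raise ValueError("tumor fraction must lie in [0, 1]")
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    rng = _rng(seed)
    grid = profile.grid
    if gc is None or mappability is None:
        g0, m0 = genome_tracks(grid)
        gc = g0 if gc is None else gc
        mappability = m0 if mappability is None else mappability
    n = 1.0 - tf
    c = profile.copy_number.astype(float)
    s = (
        profile.subclonal_fraction
        if profile.subclonal_fraction is not None
        else np.zeros(grid.n_bins)
    )
    intensity = 2.0 * n + (1.0 - n) * (2.0 * s + (1.0 - s) * c)
    intensity = intensity * mappability
    if gc_bias is not None:
        intensity = intensity * gc_bias(gc)
    intensity[~grid.valid] = 0.0
    mean = intensity / intensity.sum() * float(total_reads)
    if overdispersion > 0:
        shape = 1.0 / overdispersion
        mean = mean * rng.gamma(shape, 1.0 / shape, grid.n_bins)
    counts = rng.poisson(mean)
    return CoverageTrack(grid=grid, raw=counts.astype(float), gc=gc, mappability=mappability)


def downsample(
    track: CoverageTrack, keep_probability: float, seed: int | np.random.Generator = 0
) -> CoverageTrack:
    """Per-read binomial thinning: each bin count -> Binomial(count, p)."""
    if not (0.0 <= keep_probability <= 1.0):
        raise ValueError("keep probability must lie in [0, 1]")
    rng = _rng(seed)
    counts = rng.binomial(track.raw.astype(np.int64), keep_probability)
    return CoverageTrack(
        grid=track.grid, raw=counts.astype(float), gc=track.gc,
        mappability=track.mappability,
    )


def serial_mixture(
    tumor: CoverageTrack,
    normal: CoverageTrack,
    tumor_prop: float,
    coverage_fraction: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> CoverageTrack:
    """Bin-wise sum of thinned tumor and normal tracks.

    A fraction ``tumor_prop`` of the mixture's reads comes from the tumor
    track and ``1 - tumor_prop`` from the normal track; the total is
    ``coverage_fraction`` times the mean source depth.  The two tracks
    must share a grid.
    """
    if tumor.grid.n_bins != normal.grid.n_bins or not np.array_equal(
        tumor.grid.chrom, normal.grid.chrom
    ):
        raise ValueError("tumor and normal tracks are on different grids")
    if not (0.0 <= tumor_prop <= 1.0):
        raise ValueError("tumor proportion must lie in [0, 1]")
    rng = _rng(seed)
    target = coverage_fraction * 0.5 * (tumor.total_reads + normal.total_reads)
    p_t = tumor_prop * target / tumor.total_reads if tumor.total_reads else 0.0
    p_n = (1.0 - tumor_prop) * target / normal.total_reads if normal.total_reads else 0.0
    if p_t > 1.0 or p_n > 1.0:
        raise ValueError("requested mixture exceeds available source reads")
    mix_t = downsample(tumor, p_t, rng)
    mix_n = downsample(normal, p_n, rng)
    return CoverageTrack(
        grid=tumor.grid, raw=mix_t.raw + mix_n.raw, gc=tumor.gc,
        mappability=tumor.mappability,
    )


@dataclass(frozen=True)
class MixtureSpec:
    """Bookkeeping for an exact-tumor-fraction mixture."""

    tumor_reads: float
    normal_reads: float
    wes_purity: float

    @property
    def expected_tf(self) -> float:
        total = self.tumor_reads + self.normal_reads
        return self.tumor_reads / total * self.wes_purity if total else 0.0


def exact_tf_mixture(
    ct: CoverageTrack,
    hd: CoverageTrack,
    target_tf: float,
    wes_purity: float,
    total_reads: float = READS_PER_01X,
    seed: int | np.random.Generator = 0,
) -> tuple[CoverageTrack, MixtureSpec]:
    """Mixture with an exact expected tumor fraction at ~0.1x total:
    CT_reads = total * TF / purity, HD_reads = total - CT_reads."""
    if target_tf > wes_purity:
        raise ValueError("target tumor fraction cannot exceed the source purity")
    rng = _rng(seed)
    ct_reads = float(total_reads) * target_tf / wes_purity
    hd_reads = float(total_reads) - ct_reads
    if ct_reads > ct.total_reads:
        raise ValueError("tumor source has insufficient reads for this mixture")
    if hd_reads > hd.total_reads:
        raise ValueError("donor source has insufficient reads for this mixture")
    mix_ct = downsample(ct, ct_reads / ct.total_reads if ct.total_reads else 0.0, rng)
    mix_hd = downsample(hd, hd_reads / hd.total_reads if hd.total_reads else 0.0, rng)
    track = CoverageTrack(
        grid=ct.grid, raw=mix_ct.raw + mix_hd.raw, gc=ct.gc, mappability=ct.mappability
    )
    return track, MixtureSpec(tumor_reads=ct_reads, normal_reads=hd_reads, wes_purity=wes_purity)


def spike_in(
    neutral: CoverageTrack,
    events: Sequence[tuple[str, int, int, Literal["gain", "loss"]]],
    tf: float,
    seed: int | np.random.Generator = 0,
) -> CoverageTrack:
    """Spike single-copy gains/losses into a copy-neutral track at tumor
    fraction ``tf``.

    Event bins are rescaled by (2(1-tf) + c*tf)/2 with c = 3 (gain) or 1
    (loss).  Losses thin the existing counts binomially; gains add a
    Poisson increment on top of them, so the neutral track's own noise
    structure is carried into the spiked profile.
    """
    if not (0.0 <= tf <= 1.0):
        raise ValueError("tumor fraction must lie in [0, 1]")
    rng = _rng(seed)
    grid = neutral.grid
    counts = neutral.raw.astype(np.int64).copy()
    touched = np.zeros(grid.n_bins, dtype=bool)
    for chrom, start, end, kind in events:
        hit = (grid.chrom == chrom) & (grid.start < end) & (grid.end > start)
        if np.any(touched & hit):
            raise ValueError("spike-in events overlap")
        touched |= hit
        if kind == "gain":
            factor = (2.0 * (1.0 - tf) + 3.0 * tf) / 2.0
            counts[hit] = counts[hit] + rng.poisson((factor - 1.0) * counts[hit])
        elif kind == "loss":
            factor = (2.0 * (1.0 - tf) + 1.0 * tf) / 2.0
            counts[hit] = rng.binomial(counts[hit], factor)
        else:
            raise ValueError(f"unknown event kind {kind!r}")
    return CoverageTrack(
        grid=grid, raw=counts.astype(float), gc=neutral.gc, mappability=neutral.mappability
    )


def serial_mixture_specs() -> list[tuple[float, float]]:
    """The (tumor proportion, coverage fraction) pairs of the full serial
    down-sampling design (16 x 12 = 192 mixtures)."""
    return [(p, c) for p in SERIAL_PROPORTIONS for c in SERIAL_COVERAGES]


def donor_panel(
    grid: BinGrid,
    n_donors: int = 27,
    total_reads: float = READS_PER_01X,
    seed: int = PANEL_SEED,
    overdispersion: float = 0.0,
) -> ReferencePanel:
    """Simulated healthy-donor reference: per-bin median of GC/mappability-
    corrected coverage across ``n_donors`` tumor-free tracks with fixed
    derived seeds."""
    profile = neutral_profile(grid)
    seeds = np.random.SeedSequence(seed).spawn(n_donors)
    tracks = []
    for ss in seeds:
        raw = simulate_counts(
            profile, tf=0.0, total_reads=total_reads,
            overdispersion=overdispersion, seed=np.random.default_rng(ss),
        )
        tracks.append(loess_correct(raw))
    return build_reference(tracks)
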