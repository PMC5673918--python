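"""Bin-count normalization: GC/mappability LOESS correction, sex inference,
male chrX rescaling, healthy-donor reference normalization and log2 copy
ratios.

The correction model is multiplicative: two sequential LOESS fits (read
count vs GC fraction, then vs mappability score) estimate the expected
coverage bias, the counts are divided by the fitted curve, and the result
is centred so that the median corrected autosomal coverage equals 1.
Curve fitting uses autosomes only; the correction is applied to every bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .bins_io import BinGrid, CoverageTrack, _strip_chr

logger = logging.getLogger(__name__)

GC_LOESS_SPAN = 0.3
MAP_LOESS_SPAN = 0.99
MIN_MAPPABILITY = 0.9
MIN_AUTOSOMAL_BINS = 100

CHRY_READ_PROPORTION = 0.001   # male criterion 1: uncorrected chrY read share
CHRX_MEDIAN_LOG_RATIO = -0.5   # male criterion 2: median corrected chrX log2 ratio


@dataclass
class ReferencePanel:
    """Per-bin median corrected coverage across healthy-donor samples (h_t)."""

    grid: BinGrid
    h: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        if len(self.h) != self.grid.n_bins:
            raise ValueError("h length must equal number of bins")
        if self.n_samples < 1:
            raise ValueError("panel must contain at least one sample")

    def to_dataframe(self) -> pd.DataFrame:
        df = self.grid.to_dataframe()
        df["h"] = self.h
        return df

    def write_tsv(self, path: str) -> None:
        self.to_dataframe().assign(n_samples=self.n_samples).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def read_tsv(cls, path: str) -> "ReferencePanel":
        df = pd.read_csv(path, sep="\t")
        grid = BinGrid(
            chrom=df["chrom"].to_numpy(dtype=object),
            start=df["start"].to_numpy(dtype=np.int64),
            end=df["end"].to_numpy(dtype=np.int64),
            valid=df["valid"].to_numpy(dtype=bool),
            bin_width=int((df["end"] - df["start"]).max()),
        )
        return cls(grid=grid, h=df["h"].to_numpy(dtype=float),
                   n_samples=int(df["n_samples"].iloc[0]))


@dataclass
class LogRatioTrack:
    """Log2 copy ratios l_t = log2(r_t / h_t), defined on valid bins."""

    grid: BinGrid
    l: np.ndarray

    def __post_init__(self) -> None:
        self.l = np.asarray(self.l, dtype=float)
        if len(self.l) != self.grid.n_bins:
            raise ValueError("log ratio length must equal number of bins")

    @property
    def valid(self) -> np.ndarray:
        return self.grid.valid & np.isfinite(self.l)

    def values(self, mask: np.ndarray | None = None) -> np.ndarray:
        m = self.valid if mask is None else (self.valid & mask)
        return self.l[m]


def _loess_predict(x: np.ndarray, y: np.ndarray, x_new: np.ndarray, span: float) -> np.ndarray:
    """LOESS fit of y on x evaluated at x_new (linear interpolation between
    fitted points, clamped at the range ends)."""
    fit = lowess(y, x, frac=span, return_sorted=True)
    return np.interp(x_new, fit[:, 0], fit[:, 1])


def loess_correct(
    track: CoverageTrack,
    gc_span: float = GC_LOESS_SPAN,
    map_span: float = MAP_LOESS_SPAN,
    min_mappability: float = MIN_MAPPABILITY,
    min_bins: int = MIN_AUTOSOMAL_BINS,
) -> CoverageTrack:
    """Correct raw bin counts for GC and mappability bias.

    Two LOESS fits are applied sequentially: (1) counts vs GC fraction,
    then (2) GC-corrected counts vs mappability.  Fitting uses valid
    autosomal bins with mappability >= ``min_mappability`` and positive
    counts; low-mappability bins are flagged invalid in the output.  The
    corrected track is divided by its valid autosomal median, so a
    copy-neutral sample is centred at 1.
    """
    if track.gc is None:
        raise ValueError("track has no GC annotation")
    grid = track.grid
    mapp = track.mappability
    valid = grid.valid.copy()
    if mapp is not None:
        valid &= np.nan_to_num(mapp, nan=0.0) >= min_mappability
    fit_mask = valid & grid.autosome_mask & (track.raw > 0) & np.isfinite(track.gc)
    if fit_mask.sum() < min_bins:
        raise ValueError(
            f"only {int(fit_mask.sum())} valid autosomal bins for curve fitting "
            f"(minimum {min_bins})"
        )

    corrected = track.raw.astype(float).copy()
    fit_gc = _loess_predict(
        track.gc[fit_mask], corrected[fit_mask], track.gc, gc_span
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        corrected = np.where(fit_gc > 0, corrected / fit_gc, np.nan)

    if mapp is not None and np.nanstd(mapp[fit_mask]) > 0:
        fit_map = _loess_predict(
            mapp[fit_mask], corrected[fit_mask], mapp, map_span
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            corrected = np.where(fit_map > 0, corrected / fit_map, np.nan)

    center = np.nanmedian(corrected[fit_mask])
    if not np.isfinite(center) or center <= 0:
        raise ValueError("degenerate corrected coverage (non-positive median)")
    corrected = corrected / center
    valid &= np.isfinite(corrected) & (corrected > 0)
    return CoverageTrack(
        grid=grid.with_valid(valid),
        raw=track.raw,
        gc=track.gc,
        mappability=mapp,
        corrected=corrected,
        skipped_reads=track.skipped_reads,
    )


def _sex_chrom_mask(grid: BinGrid, letter: str) -> np.ndarray:
    return np.array([_strip_chr(str(c)) == letter for c in grid.chrom])


def infer_sex(track: CoverageTrack) -> str:
    """Classify the sample as male or female from chrY read share and the
    median corrected chrX log2 ratio.

    Male requires both: uncorrected chrY reads > 0.1% of total reads, and
    median corrected chrX log2 ratio below -0.5.  Returns ``"female"``
    (with a warning) when the grid lacks sex chromosomes.
    """
    y_mask = _sex_chrom_mask(track.grid, "Y")
    x_mask = _sex_chrom_mask(track.grid, "X") & track.grid.valid
    if not y_mask.any() or not x_mask.any():
        logger.warning("grid lacks chrX/chrY bins; defaulting to female")
        return "female"
    total = track.raw.sum()
    y_prop = track.raw[y_mask].sum() / total if total > 0 else 0.0
    if y_prop <= CHRY_READ_PROPORTION:
        return "female"
    if track.corrected is None:
        raise ValueError("infer_sex requires corrected counts (run loess_correct)")
    with np.errstate(divide="ignore"):
        x_log = np.log2(track.corrected[x_mask])
    if np.nanmedian(x_log) < CHRX_MEDIAN_LOG_RATIO:
        return "male"
    return "female"


def rescale_male_chrX(track: CoverageTrack) -> CoverageTrack:
    """Divide corrected chrX coverage by its median (male samples), so the
    rescaled chrX median equals 1."""
    if track.corrected is None:
        raise ValueError("rescale requires corrected counts")
    x_mask = _sex_chrom_mask(track.grid, "X") & track.grid.valid
    x_vals = track.corrected[x_mask]
    x_vals = x_vals[np.isfinite(x_vals)]
    if x_vals.size == 0:
        raise ValueError("no valid chrX bins to rescale")
    med = np.median(x_vals)
    if med <= 0:
        raise ValueError("non-positive chrX median")
    corrected = track.corrected.copy()
    corrected[x_mask] = corrected[x_mask] / med
    return CoverageTrack(
        grid=track.grid, raw=track.raw, gc=track.gc,
        mappability=track.mappability, corrected=corrected,
        skipped_reads=track.skipped_reads,
    )


def build_reference(panel: list[CoverageTrack]) -> ReferencePanel:
    """Per-bin median of corrected coverage across healthy-donor tracks."""
    if not panel:
        raise ValueError("empty panel")
    grid = panel[0].grid
    mat = []
    valid = grid.valid.copy()
    for tr in panel:
        if tr.grid.n_bins != grid.n_bins or not np.array_equal(tr.grid.chrom, grid.chrom):
            raise ValueError("all panel tracks must share the same grid")
        if tr.corrected is None:
            raise ValueError("panel tracks must be corrected (run loess_correct)")
        mat.append(tr.corrected)
        valid &= tr.grid.valid
    h = np.nanmedian(np.vstack(mat), axis=0)
    valid &= np.isfinite(h) & (h > 0)
    return ReferencePanel(grid=grid.with_valid(valid), h=h, n_samples=len(panel))


def self_reference(track: CoverageTrack) -> ReferencePanel:
    """Degraded mode used when no donor panel is available: a flat reference
    at the sample's own valid autosomal median corrected coverage."""
    logger.warning("no donor panel supplied; normalizing against the sample's own median")
    med = np.nanmedian(track.corrected[track.grid.valid & track.grid.autosome_mask])
    h = np.full(track.grid.n_bins, med)
    return ReferencePanel(grid=track.grid, h=h, n_samples=1)


def log2_ratio(track: CoverageTrack, ref: ReferencePanel) -> LogRatioTrack:
    """l_t = log2(corrected_t / h_t); invalid in either input stays invalid."""
    if track.corrected is None:
        raise ValueError("track must be corrected before computing log ratios")
    if track.grid.n_bins != ref.grid.n_bins:
        raise ValueError("track and reference are on different grids")
    valid = track.grid.valid & ref.grid.valid
    l = np.full(track.grid.n_bins, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        l[valid] = np.log2(track.corrected[valid] / ref.h[valid])
    valid &= np.isfinite(l)
    return LogRatioTrack(grid=track.grid.with_valid(valid), l=l)
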