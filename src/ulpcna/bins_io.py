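"""Genome bin grids, per-bin read counting, gap masking and WIG/TSV round-trips.

The analysis operates on non-overlapping fixed-width windows ("bins",
default 1 Mb) tiled across each chromosome.  Coordinates are 0-based
half-open internally; WIG output uses the 1-based fixedStep dialect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH = 1_000_000

_SEX_CHROM_NAMES = {"X", "Y"}


def _strip_chr(name: str) -> str:
    return name[3:] if name.startswith("chr") else name


def is_autosome(name: str) -> bool:
    base = _strip_chr(name)
    return base not in _SEX_CHROM_NAMES and base != "M" and base != "MT"


@dataclass(frozen=True)
class BinGrid:
    """Fixed-width tiling of a genome.

    Bins within a chromosome are contiguous, sorted and non-overlapping;
    every bin has width ``bin_width`` except possibly the last bin of a
    chromosome, which is truncated at the chromosome end.
    """

    chrom: np.ndarray          # str per bin
    start: np.ndarray          # int64, 0-based inclusive
    end: np.ndarray            # int64, exclusive
    valid: np.ndarray          # bool mask
    bin_width: int = DEFAULT_BIN_WIDTH

    def __post_init__(self) -> None:
        if len(self.chrom) == 0:
            raise ValueError("bin grid must contain at least one bin")
        if not (len(self.chrom) == len(self.start) == len(self.end) == len(self.valid)):
            raise ValueError("grid arrays must have equal length")

    @property
    def n_bins(self) -> int:
        return len(self.chrom)

    @property
    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(str(c), None)
        return list(seen)

    def chrom_mask(self, name: str) -> np.ndarray:
        return self.chrom == name

    @property
    def autosome_mask(self) -> np.ndarray:
        return np.array([is_autosome(str(c)) for c in self.chrom])

    def with_valid(self, valid: np.ndarray) -> "BinGrid":
        return replace(self, valid=np.asarray(valid, dtype=bool))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chrom, "start": self.start, "end": self.end, "valid": self.valid}
        )


@dataclass
class CoverageTrack:
    """Per-bin coverage with optional GC/mappability annotation.

    ``raw`` holds read counts; ``corrected`` is filled by the
    normalization step (bias-corrected, median-centred coverage) and is
    defined on valid bins only.
    """

    grid: BinGrid
    raw: np.ndarray
    gc: np.ndarray | None = None
    mappability: np.ndarray | None = None
    corrected: np.ndarray | None = None
    skipped_reads: int = 0

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        if len(self.raw) != self.grid.n_bins:
            raise ValueError("raw counts length must equal number of bins")
        if np.any(self.raw < 0):
            raise ValueError("raw counts must be non-negative")
        for name in ("gc", "mappability", "corrected"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if len(arr) != self.grid.n_bins:
                    raise ValueError(f"{name} length must equal number of bins")
                setattr(self, name, arr)

    @property
    def total_reads(self) -> float:
        return float(self.raw.sum())

    def to_dataframe(self) -> pd.DataFrame:
        df = self.grid.to_dataframe()
        df["reads"] = self.raw
        if self.gc is not None:
            df["gc"] = self.gc
        if self.mappability is not None:
            df["mappability"] = self.mappability
        if self.corrected is not None:
            df["corrected"] = self.corrected
        return df


def build_bin_grid(
    chrom_sizes: Mapping[str, int], bin_width: int = DEFAULT_BIN_WIDTH
) -> BinGrid:
    """Tile each chromosome left-to-right with ``bin_width`` windows.

    The final bin of a chromosome is truncated at the chromosome end.
    """
    if not chrom_sizes:
        raise ValueError("empty chromosome size map")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    for name, size in chrom_sizes.items():
        if size <= 0:
            raise ValueError(f"chromosome {name} has non-positive length {size}")
        for s in range(0, int(size), bin_width):
            chroms.append(str(name))
            starts.append(s)
            ends.append(min(s + bin_width, int(size)))
    return BinGrid(
        chrom=np.array(chroms, dtype=object),
        start=np.array(starts, dtype=np.int64),
        end=np.array(ends, dtype=np.int64),
        valid=np.ones(len(chroms), dtype=bool),
        bin_width=bin_width,
    )


def count_reads_in_bins(
    read_positions: Iterable[Tuple[str, int]], grid: BinGrid
) -> CoverageTrack:
    """Count reads per bin from a stream of (chromosome, position) pairs.

    Each read increments exactly one bin: the bin containing its
    position.  Reads on chromosomes absent from the grid, or beyond the
    chromosome end, are skipped and tallied in ``skipped_reads``.
    """
    offsets: dict[str, tuple[int, int]] = {}
    chrom_end: dict[str, int] = {}
    i = 0
    for name in grid.chromosomes:
        mask = grid.chrom_mask(name)
        idx = np.flatnonzero(mask)
        offsets[name] = (int(idx[0]), int(idx[-1]))
        chrom_end[name] = int(grid.end[idx[-1]])
    counts = np.zeros(grid.n_bins, dtype=np.int64)
    skipped = 0
    width = grid.bin_width
    for chrom, pos in read_positions:
        info = offsets.get(chrom)
        if info is None or pos < 0 or pos >= chrom_end[chrom]:
            skipped += 1
            continue
        first, last = info
        t = first + pos // width
        if t > last:  # can only happen with malformed grids
            skipped += 1
            continue
        counts[t] += 1
    if skipped:
        logger.info("count_reads_in_bins: skipped %d reads outside the grid", skipped)
    return CoverageTrack(grid=grid, raw=counts.astype(float), skipped_reads=skipped)


def count_bam_in_bins(bam_path: str, grid: BinGrid) -> CoverageTrack:
    """Count primary, non-duplicate aligned reads from a coordinate-sorted BAM/SAM.

    A read is assigned to the bin containing its leftmost aligned
    position; duplicates, secondary/supplementary alignments and
    unmapped reads are excluded.
    """
    import pysam  # optional dependency, imported lazily

    def positions() -> Iterator[Tuple[str, int]]:
        with pysam.AlignmentFile(bam_path) as bam:
            for read in bam.fetch(until_eof=True):
                if (
                    read.is_unmapped
                    or read.is_secondary
                    or read.is_supplementary
                    or read.is_duplicate
                ):
                    continue
                yield read.reference_name, read.reference_start

    return count_reads_in_bins(positions(), grid)


def mask_gaps(
    grid: BinGrid,
    gap_regions: Sequence[Tuple[str, int, int]],
    flank: int = DEFAULT_BIN_WIDTH,
) -> BinGrid:
    """Invalidate bins overlapping assembly gaps (centromeres etc.).

    A bin is masked when it overlaps ``[gap_start - flank, gap_end + flank)``,
    i.e. the gap itself plus one bin-width of flanking sequence on each
    side by default.  Idempotent; masks from multiple gaps are unioned.
    """
    valid = grid.valid.copy()
    for chrom, gs, ge in gap_regions:
        lo = gs - flank
        hi = ge + flank
        hit = (grid.chrom == chrom) & (grid.start < hi) & (grid.end > lo)
        valid[hit] = False
    return grid.with_valid(valid)


def read_gaps_bed(path: str) -> list[Tuple[str, int, int]]:
    """Read gap intervals from a BED file (first three columns)."""
    gaps: list[Tuple[str, int, int]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            gaps.append((parts[0], int(parts[1]), int(parts[2])))
    return gaps


# ---------------------------------------------------------------------------
# fixedStep WIG round-trip

def _format_value(v: float) -> str:
    if np.isnan(v):
        return "NA"
    if float(v).is_integer():
        return str(int(v))
    return repr(float(v))


def write_wig(path: str, grid: BinGrid, values: np.ndarray, name: str = "track") -> None:
    """Write per-bin values as fixedStep WIG (one block per chromosome).

    Positions are 1-based per the WIG convention; integer values are
    written without a decimal point so integer counts round-trip
    bit-exactly.
    """
    values = np.asarray(values, dtype=float)
    if len(values) != grid.n_bins:
        raise ValueError("values length must equal number of bins")
    with open(path, "w") as fh:
        fh.write(f'track type=wiggle_0 name="{name}"\n')
        for chrom in grid.chromosomes:
            idx = np.flatnonzero(grid.chrom_mask(chrom))
            fh.write(
                f"fixedStep chrom={chrom} start={int(grid.start[idx[0]]) + 1} "
                f"step={grid.bin_width} span={grid.bin_width}\n"
            )
            for t in idx:
                fh.write(_format_value(values[t]) + "\n")


def read_wig(path: str) -> Tuple[BinGrid, np.ndarray]:
    """Read a fixedStep WIG written by :func:`write_wig` back into a grid + values."""
    chroms: list[str] = []
    starts: list[int] = []
    values: list[float] = []
    step = None
    cur_chrom = None
    cur_pos = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("track"):
                continue
            if line.startswith("fixedStep"):
                fields = dict(kv.split("=") for kv in line.split()[1:])
                cur_chrom = fields["chrom"]
                cur_pos = int(fields["start"]) - 1
                step = int(fields["step"])
                continue
            if cur_chrom is None or step is None:
                raise ValueError("WIG data line before fixedStep header")
            chroms.append(cur_chrom)
            starts.append(cur_pos)
            values.append(np.nan if line == "NA" else float(line))
            cur_pos += step
    if step is None:
        raise ValueError("no fixedStep blocks found")
    start_arr = np.array(starts, dtype=np.int64)
    grid = BinGrid(
        chrom=np.array(chroms, dtype=object),
        start=start_arr,
        end=start_arr + step,
        valid=np.ones(len(chroms), dtype=bool),
        bin_width=step,
    )
    return grid, np.array(values, dtype=float)


def read_chrom_sizes(path: str) -> dict[str, int]:
    """Read a UCSC-style two-column chrom.sizes file."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            name, size = line.split()[:2]
            sizes[name] = int(size)
    return sizes
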