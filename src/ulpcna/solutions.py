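"""Solution assembly: Viterbi paths to segments, genome-fraction summaries,
restart selection with the subclonality filters and the zero-tumor-fraction
rule, and SEG/TSV output.

Selection logic across EM restarts: candidates in which more than half the
genome is called subclonal, or more than 70% of altered segments are
subclonal, are treated as unidentifiable and excluded; among the remainder
the maximum penalized objective F wins.  A winning solution whose altered
fraction is below 5% of bins with no event reaching 50 bins is reported as
tumor fraction zero (no reliable copy-number signal).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .bins_io import BinGrid
from .hmm_core import CopyState, EMResult, decode_path
from .normalize import LogRatioTrack

logger = logging.getLogger(__name__)

MAX_SUBCLONAL_GENOME = 0.5     # candidates above are not selected
MAX_SUBCLONAL_CALLS = 0.7
F_TIE_TOLERANCE = 0.05         # candidates within this of max-F count as tied
ZERO_TF_ALTERED_FRACTION = 0.05
ZERO_TF_LARGEST_EVENT = 50     # bins
DETECTION_THRESHOLD = 0.03     # tumor-presence cut-off on estimated TF
WES_ELIGIBILITY_THRESHOLD = 0.10


@dataclass
class Segment:
    chrom: str
    start: int
    end: int
    n_bins: int
    state: CopyState
    median_l: float


@dataclass
class Solution:
    tumor_fraction: float
    ploidy: float
    normal_fraction: float
    subclone_fraction: float          # s: tumor fraction NOT carrying subclonal events
    segments: list[Segment]
    path: np.ndarray                  # state indices over decode bins
    bin_index: np.ndarray             # grid indices of decode bins
    fraction_altered: float
    fraction_subclonal_genome: float
    fraction_calls_subclonal: float
    largest_event_bins: int
    F: float
    init: tuple[float, float]
    states: list[CopyState]
    flags: list[str] = field(default_factory=list)


def path_to_segments(
    path: np.ndarray,
    grid: BinGrid,
    l: LogRatioTrack,
    states: Sequence[CopyState],
    bin_index: np.ndarray | None = None,
) -> list[Segment]:
    """Run-length encode a decoded state path into segments.

    Segments never cross chromosome boundaries; consecutive segments on a
    chromosome therefore have distinct states, and concatenating the
    per-segment states (repeated n_bins times) reproduces the path.
    """
    path = np.asarray(path)
    if bin_index is None:
        bin_index = np.arange(grid.n_bins)
    if len(path) != len(bin_index):
        raise ValueError("path and bin index lengths differ")
    segments: list[Segment] = []
    start_j = 0
    for j in range(1, len(path) + 1):
        boundary = (
            j == len(path)
            or path[j] != path[j - 1]
            or grid.chrom[bin_index[j]] != grid.chrom[bin_index[j - 1]]
        )
        if not boundary:
            continue
        idx = bin_index[start_j:j]
        vals = l.l[idx]
        segments.append(
            Segment(
                chrom=str(grid.chrom[idx[0]]),
                start=int(grid.start[idx[0]]),
                end=int(grid.end[idx[-1]]),
                n_bins=int(j - start_j),
                state=states[int(path[start_j])],
                median_l=float(np.nanmedian(vals)),
            )
        )
        start_j = j
    return segments


SUBCLONE_DEGENERATE_EPS = 0.2


def effective_path(
    path: np.ndarray,
    states: Sequence[CopyState],
    s: float,
    eps: float = SUBCLONE_DEGENERATE_EPS,
) -> np.ndarray:
    """Collapse degenerate subclonal calls onto their effective state.

    When the fitted subclone parameter sits at an endpoint the subclonal
    states duplicate other states and Viterbi labels split arbitrarily
    between the twins: at s <= eps a subclonal event is carried by nearly
    every tumor cell (a prevalence of 0.8 or more is operationally clonal
    at 1 Mb ULP resolution), and at s >= 1 - eps by almost
    none (operationally absent, i.e. copy neutral).  Remapping before
    segmentation keeps the genome-fraction summaries and the subclonality
    filters meaningful; mid-range s is left untouched.
    """
    if not any(st.subclonal for st in states) or eps < s < 1.0 - eps:
        return path
    mapping = np.arange(len(states))
    for idx, st in enumerate(states):
        if not st.subclonal:
            continue
        target = st.copies if s <= eps else 2
        for jdx, other in enumerate(states):
            if not other.subclonal and other.copies == target:
                mapping[idx] = jdx
                break
    return mapping[path]


def summarize_solution(em: EMResult, grid: BinGrid, l: LogRatioTrack) -> Solution:
    """Decode an EM fit and compute the genome-fraction summaries used by
    the selection rules."""
    path = effective_path(decode_path(em, l), em.states, em.params.s)
    bin_index = np.flatnonzero(em.decode_mask)
    segments = path_to_segments(path, grid, l, em.states, bin_index)
    copies = np.array([st.copies for st in em.states])
    subclonal = np.array([st.subclonal for st in em.states])
    altered_bin = (copies[path] != 2) | subclonal[path]
    n_valid = len(path)
    fraction_altered = float(altered_bin.sum() / n_valid) if n_valid else 0.0
    fraction_subclonal_genome = float(subclonal[path].sum() / n_valid) if n_valid else 0.0
    altered_segs = [s for s in segments if s.state.copies != 2 or s.state.subclonal]
    sub_segs = [s for s in altered_segs if s.state.subclonal]
    # subclonal share of CNA calls, counted over bins (segment-based
    # alternative kept for reference in the flags-free segment list)
    n_altered = int(altered_bin.sum())
    fraction_calls_subclonal = (
        float(subclonal[path].sum() / n_altered) if n_altered else 0.0
    )
    largest = max((s.n_bins for s in altered_segs), default=0)
    return Solution(
        tumor_fraction=em.params.tumor_fraction,
        ploidy=em.params.phi,
        normal_fraction=em.params.n,
        subclone_fraction=em.params.s,
        segments=segments,
        path=path,
        bin_index=bin_index,
        fraction_altered=fraction_altered,
        fraction_subclonal_genome=fraction_subclonal_genome,
        fraction_calls_subclonal=fraction_calls_subclonal,
        largest_event_bins=largest,
        F=em.F,
        init=em.init,
        states=em.states,
    )


def select_solution(
    candidates: Sequence[Solution],
    max_subclonal_genome: float = MAX_SUBCLONAL_GENOME,
    max_subclonal_calls: float = MAX_SUBCLONAL_CALLS,
    zero_tf_altered: float = ZERO_TF_ALTERED_FRACTION,
    zero_tf_event_bins: int = ZERO_TF_LARGEST_EVENT,
    f_tie_tolerance: float = F_TIE_TOLERANCE,
) -> Solution:
    """Pick the final solution across restarts.

    Candidates failing the subclonality filters are excluded; the maximum-F
    survivor wins (if every candidate is filtered, fall back to the overall
    maximum-F candidate, flagged).  Whole-genome ploidy rescalings are
    observationally equivalent without allelic data (e.g. an all-neutral
    diploid genome and an "everything 4-copy" tetraploid one produce the
    same likelihood), so candidates whose F lies within ``f_tie_tolerance``
    of the maximum are treated as tied and broken by parsimony: fewest
    altered bins, then largest normal fraction.  The winner is reported
    with tumor fraction zero when its altered fraction and largest event
    are both below the no-signal thresholds.
    """
    if not candidates:
        raise ValueError("no candidate solutions")
    passing = [
        c for c in candidates
        if c.fraction_subclonal_genome <= max_subclonal_genome
        and c.fraction_calls_subclonal <= max_subclonal_calls
    ]
    flags: list[str] = []
    pool = passing
    if not pool:
        pool = list(candidates)
        flags.append("all_candidates_subclonal_filtered")
    f_max = max(c.F for c in pool)
    tied = [c for c in pool if c.F >= f_max - f_tie_tolerance]
    best = min(tied, key=lambda c: (c.fraction_altered, -c.normal_fraction))
    chosen = replace(best, flags=list(best.flags) + flags)
    if (
        chosen.fraction_altered < zero_tf_altered
        and chosen.largest_event_bins < zero_tf_event_bins
    ):
        chosen = replace(
            chosen,
            tumor_fraction=0.0,
            flags=chosen.flags + ["zero_tf_low_alteration"],
        )
    return chosen


def detect_tumor(solution: Solution, threshold: float = DETECTION_THRESHOLD) -> bool:
    """Tumor DNA is called present when the estimated tumor fraction reaches
    the threshold (0.03 for presence, 0.10 for WES eligibility)."""
    return solution.tumor_fraction >= threshold


# ---------------------------------------------------------------------------
# output writers

def segments_to_dataframe(solution: Solution, sample: str = "sample") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample": sample,
            "chrom": [s.chrom for s in solution.segments],
            "start": [s.start + 1 for s in solution.segments],  # 1-based SEG output
            "end": [s.end for s in solution.segments],
            "n_bins": [s.n_bins for s in solution.segments],
            "median_log2_ratio": [s.median_l for s in solution.segments],
            "state": [s.state.label for s in solution.segments],
        }
    )


def write_seg(path: str, solution: Solution, sample: str = "sample") -> None:
    segments_to_dataframe(solution, sample).to_csv(path, sep="\t", index=False)


def bins_to_dataframe(
    solution: Solution, grid: BinGrid, l: LogRatioTrack, sample: str = "sample"
) -> pd.DataFrame:
    idx = solution.bin_index
    return pd.DataFrame(
        {
            "sample": sample,
            "chrom": grid.chrom[idx],
            "start": grid.start[idx] + 1,
            "end": grid.end[idx],
            "log2_ratio": l.l[idx],
            "state": [solution.states[g].label for g in solution.path],
            "copies": [solution.states[g].copies for g in solution.path],
            "subclonal": [solution.states[g].subclonal for g in solution.path],
        }
    )


def params_to_dataframe(solution: Solution, sample: str = "sample") -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample": sample,
                "tumor_fraction": solution.tumor_fraction,
                "ploidy": solution.ploidy,
                "normal_fraction": solution.normal_fraction,
                "subclone_fraction": solution.subclone_fraction,
                "fraction_altered": solution.fraction_altered,
                "fraction_subclonal_genome": solution.fraction_subclonal_genome,
                "largest_event_bins": solution.largest_event_bins,
                "F": solution.F,
                "init_n0": solution.init[0],
                "init_phi0": solution.init[1],
                "flags": ";".join(solution.flags),
            }
        ]
    )
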