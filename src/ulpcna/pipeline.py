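"""End-to-end driver: raw bin counts -> normalization -> HMM restarts ->
selected solution.  Thin glue over the individual modules; this is what
the CLI and the benchmark scripts call."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .bins_io import CoverageTrack
from .hmm_core import (
    DEFAULT_N0_GRID,
    DEFAULT_PHI0_GRID,
    EMResult,
    default_hyperparams,
    default_state_space,
    run_restarts,
)
from .normalize import (
    LogRatioTrack,
    ReferencePanel,
    infer_sex,
    loess_correct,
    log2_ratio,
    rescale_male_chrX,
    self_reference,
)
from .solutions import Solution, select_solution, summarize_solution

logger = logging.getLogger(__name__)


@dataclass
class AnalysisResult:
    solution: Solution
    log_ratios: LogRatioTrack
    candidates: list[Solution]
    restarts: list[EMResult]
    sex: str


def normalize_track(
    track: CoverageTrack,
    panel: ReferencePanel | None = None,
) -> tuple[LogRatioTrack, str]:
    """GC/mappability correction, sex handling and reference normalization."""
    corrected = loess_correct(track)
    sex = infer_sex(corrected)
    if sex == "male":
        corrected = rescale_male_chrX(corrected)
    ref = panel if panel is not None else self_reference(corrected)
    return log2_ratio(corrected, ref), sex


def analyze_track(
    track: CoverageTrack,
    panel: ReferencePanel | None = None,
    include_subclonal: bool = True,
    n0_grid: Sequence[float] = DEFAULT_N0_GRID,
    phi0_grid: Sequence[float] = DEFAULT_PHI0_GRID,
    **em_kwargs,
) -> AnalysisResult:
    """Full analysis of one binned sample; returns the selected solution
    along with all restart candidates."""
    l, sex = normalize_track(track, panel)
    states = default_state_space(include_subclonal)
    hyper = default_hyperparams(l, states)
    restarts = run_restarts(
        l, hyper=hyper, states=states, n0_grid=n0_grid, phi0_grid=phi0_grid, **em_kwargs
    )
    candidates = [summarize_solution(em, l.grid, l) for em in restarts]
    solution = select_solution(candidates)
    return AnalysisResult(
        solution=solution, log_ratios=l, candidates=candidates,
        restarts=restarts, sex=sex,
    )
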