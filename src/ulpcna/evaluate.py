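"""Benchmark metrics: bin-level CNA precision/recall/F-measure, tumor
detection sensitivity/specificity with exact binomial confidence intervals,
and tumor-fraction error statistics."""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist


@dataclass(frozen=True)
class DirectionMetrics:
    precision: float | None
    recall: float | None
    f_measure: float | None
    tp: int
    fp: int
    fn: int


def _direction(pred_pos: np.ndarray, truth_pos: np.ndarray) -> DirectionMetrics:
    tp = int(np.sum(pred_pos & truth_pos))
    fp = int(np.sum(pred_pos & ~truth_pos))
    fn = int(np.sum(~pred_pos & truth_pos))
    precision = tp / (tp + fp) if (tp + fp) else None
    recall = tp / (tp + fn) if (tp + fn) else None
    if precision and recall:
        f = 2 * precision * recall / (precision + recall)
    elif precision is not None and recall is not None:
        f = 0.0
    else:
        f = None
    return DirectionMetrics(precision, recall, f, tp, fp, fn)


def cna_metrics(
    pred_copies: np.ndarray,
    truth_copies: np.ndarray,
    valid: np.ndarray | None = None,
) -> dict[str, DirectionMetrics]:
    """Precision/recall/F per direction on integer copy numbers.

    A bin is a gain positive when its copy number exceeds 2 and a loss
    positive when below 2; subclonal predictions count per their copy
    number.  Metrics are computed on valid bins only; recall is reported
    as missing when the truth has no positives in that direction.
    """
    pred = np.asarray(pred_copies)
    truth = np.asarray(truth_copies)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth must have equal length")
    if valid is not None:
        pred = pred[valid]
        truth = truth[valid]
    return {
        "gain": _direction(pred > 2, truth > 2),
        "loss": _direction(pred < 2, truth < 2),
    }


def clopper_pearson(successes: int, trials: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval via Beta quantiles."""
    if trials <= 0:
        raise ValueError("trials must be positive")
    if not (0 <= successes <= trials):
        raise ValueError("successes must lie in [0, trials]")
    a = (1.0 - level) / 2.0
    lower = 0.0 if successes == 0 else float(beta_dist.ppf(a, successes, trials - successes + 1))
    upper = 1.0 if successes == trials else float(
        beta_dist.ppf(1.0 - a, successes + 1, trials - successes)
    )
    return lower, upper


@dataclass(frozen=True)
class RateWithCI:
    rate: float | None
    successes: int
    trials: int
    ci_lower: float | None
    ci_upper: float | None


def _rate(successes: int, trials: int, level: float = 0.95) -> RateWithCI:
    if trials == 0:
        return RateWithCI(None, 0, 0, None, None)
    lo, hi = clopper_pearson(successes, trials, level)
    return RateWithCI(successes / trials, successes, trials, lo, hi)


def detection_table(
    estimated_tf: np.ndarray,
    truth_tf: np.ndarray,
    threshold: float = 0.03,
    level: float = 0.95,
) -> dict[str, RateWithCI]:
    """Sensitivity/specificity of tumor detection at an estimated-TF cut-off.

    Positives are samples whose true tumor fraction exceeds ``threshold``;
    negatives are the rest.  A positive is detected when the estimate is
    at or above the threshold; a negative is correctly classified when the
    estimate is below it.
    """
    est = np.asarray(estimated_tf, dtype=float)
    tru = np.asarray(truth_tf, dtype=float)
    if est.shape != tru.shape:
        raise ValueError("estimate and truth must have equal length")
    pos = tru > threshold
    neg = ~pos
    sens = _rate(int(np.sum(est[pos] >= threshold)), int(pos.sum()), level)
    spec = _rate(int(np.sum(est[neg] < threshold)), int(neg.sum()), level)
    return {"sensitivity": sens, "specificity": spec}


def tf_error_stats(
    estimated: np.ndarray, expected: np.ndarray
) -> tuple[float, float, pd.DataFrame]:
    """Per-sample |estimated - expected| tumor-fraction deviations with the
    max and the median across samples."""
    est = np.asarray(estimated, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if est.shape != exp.shape:
        raise ValueError("estimate and expected must have equal length")
    dev = np.abs(est - exp)
    table = pd.DataFrame({"expected": exp, "estimated": est, "deviation": dev})
    return float(dev.max()), float(np.median(dev)), table
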