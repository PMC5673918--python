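"""Theoretical power for detecting somatic SNVs in WES of cfDNA, used to
calibrate sequencing depth from the ULP-WGS tumor-fraction estimate.

A clonal heterozygous SSNV at tumor fraction ``alpha``, multiplicity ``M``
(chromosome copies carrying the variant), reference-bias skew ``w`` and
tumor ploidy ``phi`` is expected at allele fraction

    p = alpha * M * w / (alpha * phi + 2 (1 - alpha))

and power at locus coverage N is the binomial probability of observing at
least 3 variant reads, P(X >= 3 | N, p).  Defaults (M = 1, w = 1, phi = 2)
describe an unamplified, unskewed heterozygous site.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom

MIN_VARIANT_READS = 3


@dataclass(frozen=True)
class PowerQuery:
    alpha: float
    M: int = 1
    w: float = 1.0
    phi: float = 2.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("tumor fraction must lie in [0, 1]")
        if self.M < 1 or self.w <= 0 or self.phi <= 0:
            raise ValueError("M must be >= 1 and w, phi positive")


def expected_vaf(alpha: float, M: int = 1, w: float = 1.0, phi: float = 2.0) -> float:
    """Expected variant allele fraction of a clonal SSNV in cfDNA."""
    q = PowerQuery(alpha, M, w, phi)
    den = q.alpha * q.phi + 2.0 * (1.0 - q.alpha)
    if den <= 0:
        raise ValueError("zero denominator in expected VAF")
    return q.alpha * q.M * q.w / den


def power_ge3(N: int, p: float) -> float:
    """P(X >= 3) for X ~ Binomial(N, p): power to see >= 3 variant reads."""
    if N < 0:
        raise ValueError("coverage must be non-negative")
    if not (0.0 <= p <= 1.0):
        raise ValueError("allele fraction must lie in [0, 1]")
    return float(binom.sf(MIN_VARIANT_READS - 1, N, p))


def required_coverage(p: float, target_power: float = 0.9) -> int:
    """Smallest integer coverage N with power_ge3(N, p) >= target_power."""
    if p <= 0:
        raise ValueError("allele fraction must be positive")
    if not (0.0 < target_power < 1.0):
        raise ValueError("target power must lie in (0, 1)")
    hi = MIN_VARIANT_READS
    while power_ge3(hi, p) < target_power:
        hi *= 2
        if hi > 10_000_000:
            raise RuntimeError("required coverage exceeds 1e7; check inputs")
    lo = hi // 2
    while lo < hi:
        mid = (lo + hi) // 2
        if power_ge3(mid, p) >= target_power:
            hi = mid
        else:
            lo = mid + 1
    return hi


def power_grid(
    alphas: np.ndarray, coverages: np.ndarray, M: int = 1, w: float = 1.0, phi: float = 2.0
) -> pd.DataFrame:
    """Power table over (tumor fraction, locus coverage) pairs."""
    rows = []
    for a in np.atleast_1d(alphas):
        p = expected_vaf(float(a), M, w, phi)
        for N in np.atleast_1d(coverages):
            rows.append(
                {"tumor_fraction": float(a), "coverage": int(N),
                 "expected_vaf": p, "power": power_ge3(int(N), p)}
            )
    return pd.DataFrame(rows)
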