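"""Paired-proportion statistics for with/without clinical-check comparisons.

The analysis compares the same respondents scored twice — once on the plain
ITQ and once with clinical-check gating — so every comparison is a paired
comparison of proportions.  The workhorse is McNemar's Z on the discordant
pairs: ``b`` respondents positive without gating and negative with it, ``c``
the reverse.  For monotone predicates (item, cluster, CPTSD and
either-disorder endorsement) gating can only remove cases, so ``c = 0`` and
the uncorrected Z collapses to ``sqrt(b)``.

Relative (percentage) decreases are computed from the rounded percentages as
reported, ``100 * (E% - CC%) / E%``; a count-based variant is available
behind a flag.

Also here: Cronbach's alpha for scale reliability and the normal-approximation
sample size for estimating a prevalence to a given margin of error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "PairedCounts",
    "TestResult",
    "RateSummary",
    "ReliabilityResult",
    "PowerSpec",
    "percentage_decrease",
    "paired_discordant_counts",
    "mcnemar_z",
    "cronbach_alpha",
    "required_sample_size",
    "round_half_up",
]


class NoDiscordanceError(ZeroDivisionError):
    """McNemar's test is undefined when there are no discordant pairs."""


class UndefinedStatisticError(ZeroDivisionError):
    """A statistic's denominator is zero (no endorsement / no variance)."""


def round_half_up(x: float, ndigits: int) -> float:
    """Round with ties away from zero, matching conventional table display."""
    q = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * q + 0.5) / q, x)


@dataclass(frozen=True)
class PairedCounts:
    """2x2 paired classification counts for one predicate, without vs with gating."""

    b: int  # positive without, negative with (losses under gating)
    c: int  # negative without, positive with (gains under gating)
    n11: int = 0  # positive in both
    n00: int = 0  # negative in both

    def __post_init__(self) -> None:
        if min(self.b, self.c, self.n11, self.n00) < 0:
            raise ValueError("paired counts must be non-negative")

    @property
    def n(self) -> int:
        return self.b + self.c + self.n11 + self.n00

    @property
    def n_without(self) -> int:
        return self.n11 + self.b

    @property
    def n_with(self) -> int:
        return self.n11 + self.c


@dataclass(frozen=True)
class TestResult:
    z: float
    p: float
    corrected: bool


@dataclass(frozen=True)
class RateSummary:
    """One report row: endorsement with and without checks, decrease, test."""

    label: str
    n_total: int
    n_without: int
    pct_without: float
    n_with: int
    pct_with: float
    decrease_n: int
    decrease_pct: float | None
    test: TestResult | None


@dataclass(frozen=True)
class ReliabilityResult:
    alpha: float
    k: int
    n: int


@dataclass(frozen=True)
class PowerSpec:
    p: float
    confidence: float
    margin: float
    z: float
    n_required: int


def percentage_decrease(pct_without: float, pct_with: float) -> float:
    """Relative decrease ``100 * (E% - CC%) / E%`` on reported percentages.

    Inputs are the percentages as displayed (one decimal), so the output
    reproduces published decrease columns cell for cell.  Scale-invariant:
    proportions in [0, 1] give the same answer as percentages.
    """
    if pct_without == 0:
        raise UndefinedStatisticError("decrease undefined when the base rate is zero")
    return 100.0 * (pct_without - pct_with) / pct_without


def count_decrease(n_without: int, n_with: int, n_total: int) -> float:
    """Count-basis variant: decrease computed from raw counts, not rounded %."""
    if n_without == 0:
        raise UndefinedStatisticError("decrease undefined when the base count is zero")
    del n_total  # counts cancel; kept for a uniform signature
    return 100.0 * (n_without - n_with) / n_without


def paired_discordant_counts(
    before: Sequence[bool] | np.ndarray, after: Sequence[bool] | np.ndarray
) -> PairedCounts:
    """Cross-tabulate per-respondent booleans evaluated without vs with gating."""
    b_arr = np.asarray(before, dtype=bool)
    a_arr = np.asarray(after, dtype=bool)
    if b_arr.shape != a_arr.shape or b_arr.ndim != 1:
        raise ValueError(f"length mismatch: {b_arr.shape} vs {a_arr.shape}")
    return PairedCounts(
        b=int(np.sum(b_arr & ~a_arr)),
        c=int(np.sum(~b_arr & a_arr)),
        n11=int(np.sum(b_arr & a_arr)),
        n00=int(np.sum(~b_arr & ~a_arr)),
    )


def mcnemar_z(counts: PairedCounts, corrected: bool) -> TestResult:
    """McNemar's Z on discordant pairs.

    Uncorrected: ``z = (b - c) / sqrt(b + c)`` (reported as |z|).  With
    continuity correction: ``z = (|b - c| - 1) / sqrt(b + c)``, floored at 0.
    Two-sided p from the standard normal.
    """
    b, c = counts.b, counts.c
    if b + c == 0:
        raise NoDiscordanceError("no discordant pairs; McNemar's test is undefined")
    if corrected:
        z = max(abs(b - c) - 1, 0) / math.sqrt(b + c)
    else:
        z = abs(b - c) / math.sqrt(b + c)
    p = 2.0 * sps.norm.sf(z)
    return TestResult(z=z, p=min(p, 1.0), corrected=corrected)


def cronbach_alpha(scores) -> ReliabilityResult:
    """Cronbach's alpha: ``(k / (k - 1)) * (1 - sum(item var) / var(total))``.

    ``scores`` is an (n respondents x k items) table; variances are computed
    with the n - 1 denominator.
    """
    x = np.asarray(scores, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 respondents and 2 items")
    n, k = x.shape
    total_var = float(np.var(x.sum(axis=1), ddof=1))
    if total_var == 0:
        raise UndefinedStatisticError("total score has zero variance")
    item_var = float(np.var(x, axis=0, ddof=1).sum())
    alpha = (k / (k - 1)) * (1.0 - item_var / total_var)
    return ReliabilityResult(alpha=alpha, k=k, n=n)


def required_sample_size(p: float, confidence: float, margin: float) -> PowerSpec:
    """Sample size to estimate a prevalence ``p`` within ``margin`` (half-width).

    Normal approximation: ``n = ceil(z^2 * p * (1 - p) / margin^2)`` with ``z``
    the two-sided normal quantile for the confidence level.
    """
    if not 0 < p < 1:
        raise ValueError(f"prevalence must be in (0, 1), got {p}")
    if not 0 < margin < 1:
        raise ValueError(f"margin must be in (0, 1), got {margin}")
    if not 0 < confidence < 1:
        raise ValueError(f"confidence must be in (0, 1), got {confidence}")
    z = float(sps.norm.ppf(0.5 + confidence / 2.0))
    n = math.ceil(z * z * p * (1.0 - p) / (margin * margin))
    return PowerSpec(p=p, confidence=confidence, margin=margin, z=z, n_required=n)
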