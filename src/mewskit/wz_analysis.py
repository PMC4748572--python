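"""Warning-zone threshold audit.

Stratifies patients by their maximum score, tabulates event (IHCA) rates per
stratum with exact binomial confidence intervals, tests strata against a
reference with an uncorrected chi-squared or Fisher's exact test, and selects
the lowest threshold whose strata are all significantly elevated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "StratumSummary",
    "TestResult",
    "ThresholdDecision",
    "clopper_pearson",
    "stratify",
    "chi2_2x2",
    "fisher_2x2",
    "select_wz",
]

Sidedness = Literal["one", "two"]


@dataclass(frozen=True)
class StratumSummary:
    """One row of the stratified event table: a score value (or pooled top
    bin) with its patient count, event count, percentage rate, and exact
    95% binomial CI."""

    score: int
    pooled: bool
    n_patients: int
    n_events: int
    rate: float      # percent
    ci_low: float    # percent
    ci_high: float   # percent

    @property
    def label(self) -> str:
        return f">={self.score}" if self.pooled else str(self.score)


@dataclass(frozen=True)
class TestResult:
    """Outcome of a 2x2 test; ``statistic`` is None for the exact test and a
    degenerate (zero-margin) table is flagged rather than raised."""

    p_value: float
    method: Literal["chi2", "fisher"]
    sidedness: Sidedness
    statistic: Optional[float] = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value out of [0,1]: {self.p_value}")


@dataclass(frozen=True)
class ThresholdDecision:
    """Selected warning-zone threshold with its audit trail.

    ``threshold`` is None when no candidate satisfies the selection rule.
    ``tests`` maps each tested stratum label to its TestResult against the
    reference stratum of the winning (or last evaluated) candidate.
    """

    threshold: Optional[int]
    reference_label: Optional[str]
    alpha: float
    method: Literal["chi2", "fisher"]
    tests: dict[str, TestResult] = field(default_factory=dict)

    @property
    def found(self) -> bool:
        return self.threshold is not None


def clopper_pearson(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial CI for k successes in n trials,
    returned as proportions in [0, 1]."""
    if not (0 <= k <= n) or n < 1:
        raise ValueError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    a = 1.0 - conf
    lo = 0.0 if k == 0 else stats.beta.ppf(a / 2, k, n - k + 1)
    hi = 1.0 if k == n else stats.beta.ppf(1 - a / 2, k + 1, n - k)
    return float(lo), float(hi)


def stratify(
    patient_max_scores: Sequence[int],
    event_flags: Sequence[bool],
    top_bin: int = 9,
) -> list[StratumSummary]:
    """Stratified event table: one row per observed score below ``top_bin``
    plus one pooled row for scores >= top_bin.

    Patient and event totals are conserved across the returned strata.
    """
    scores = np.asarray(patient_max_scores, dtype=int)
    flags = np.asarray(event_flags, dtype=bool)
    if scores.shape != flags.shape:
        raise ValueError(
            f"length mismatch: {scores.shape[0]} scores vs {flags.shape[0]} event flags"
        )
    if top_bin < 1:
        raise ValueError(f"top_bin must be >= 1, got {top_bin}")
    if scores.size and scores.min() < 0:
        raise ValueError("scores must be non-negative")

    out: list[StratumSummary] = []
    below = sorted(set(scores[scores < top_bin].tolist()))
    groups: list[tuple[int, bool, np.ndarray]] = [
        (s, False, scores == s) for s in below
    ]
    top_mask = scores >= top_bin
    if top_mask.any():
        groups.append((top_bin, True, top_mask))
    for score, pooled, mask in groups:
        n = int(mask.sum())
        k = int(flags[mask].sum())
        lo, hi = clopper_pearson(k, n)
        out.append(
            StratumSummary(
                score=score,
                pooled=pooled,
                n_patients=n,
                n_events=k,
                rate=100.0 * k / n,
                ci_low=100.0 * lo,
                ci_high=100.0 * hi,
            )
        )
    return out


def _check_2x2(events_a: int, n_a: int, events_b: int, n_b: int) -> None:
    if n_a < 1 or n_b < 1:
        raise ValueError("both groups need at least one subject")
    if not (0 <= events_a <= n_a and 0 <= events_b <= n_b):
        raise ValueError("event counts must satisfy 0 <= events <= n in each group")


def _degenerate(events_a: int, n_a: int, events_b: int, n_b: int) -> bool:
    total_events = events_a + events_b
    return total_events == 0 or total_events == n_a + n_b


def chi2_2x2(events_a: int, n_a: int, events_b: int, n_b: int) -> TestResult:
    """Pearson chi-squared on the 2x2 event/non-event table, no continuity
    correction, two-sided p from chi2(1).

    A zero-margin table returns statistic 0, p 1 with ``degenerate=True``.
    """
    _check_2x2(events_a, n_a, events_b, n_b)
    if _degenerate(events_a, n_a, events_b, n_b):
        return TestResult(p_value=1.0, method="chi2", sidedness="two",
                          statistic=0.0, degenerate=True)
    table = np.array(
        [[events_a, n_a - events_a], [events_b, n_b - events_b]], dtype=float
    )
    res = stats.chi2_contingency(table, correction=False)
    return TestResult(
        p_value=float(res.pvalue),
        method="chi2",
        sidedness="two",
        statistic=float(res.statistic),
    )


def fisher_2x2(
    events_a: int, n_a: int, events_b: int, n_b: int, sidedness: Sidedness = "one"
) -> TestResult:
    """Fisher's exact test on the 2x2 table.

    One-sided: hypergeometric tail probability that group-b events are >=
    the observed count given the fixed margins.  Two-sided: total
    probability of tables no more likely than the observed one.
    """
    _check_2x2(events_a, n_a, events_b, n_b)
    if sidedness not in ("one", "two"):
        raise ValueError(f"sidedness must be 'one' or 'two', got {sidedness!r}")
    if _degenerate(events_a, n_a, events_b, n_b):
        return TestResult(p_value=1.0, method="fisher", sidedness=sidedness,
                          degenerate=True)
    table = [[events_a, n_a - events_a], [events_b, n_b - events_b]]
    # P(b-events >= observed) == P(a-events <= observed) at fixed margins,
    # which is scipy's 'less' alternative on the a-cell.
    alternative = "less" if sidedness == "one" else "two-sided"
    res = stats.fisher_exact(table, alternative=alternative)
    return TestResult(p_value=float(min(res.pvalue, 1.0)), method="fisher",
                      sidedness=sidedness)


def select_wz(
    strata: Sequence[StratumSummary],
    alpha: float = 0.05,
    method: Literal["chi2", "fisher"] = "chi2",
) -> ThresholdDecision:
    """Smallest threshold t such that *every* stratum at or above t has a
    significantly higher event rate than the stratum immediately below t.

    Candidates are scanned in increasing score order; the reference is the
    stratum preceding the candidate.  Default test: uncorrected chi-squared
    (two-sided) with a directionality check; ``method='fisher'`` uses the
    one-sided exact test.  Returns a decision with ``threshold=None`` when
    no candidate qualifies.
    """
    if len(strata) < 2:
        raise ValueError("need at least two strata")
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    ordered = sorted(strata, key=lambda s: s.score)
    if any(s.pooled for s in ordered[:-1]):
        raise ValueError("only the top stratum may be pooled")

    last_tests: dict[str, TestResult] = {}
    last_ref: Optional[str] = None
    for i in range(1, len(ordered)):
        ref = ordered[i - 1]
        tests: dict[str, TestResult] = {}
        ok = True
        for s in ordered[i:]:
            if method == "chi2":
                t = chi2_2x2(ref.n_events, ref.n_patients, s.n_events, s.n_patients)
            else:
                t = fisher_2x2(ref.n_events, ref.n_patients, s.n_events, s.n_patients,
                               sidedness="one")
            tests[s.label] = t
            higher = s.rate > ref.rate
            if not (higher and t.p_value < alpha):
                ok = False
        last_tests, last_ref = tests, ref.label
        if ok:
            return ThresholdDecision(
                threshold=ordered[i].score,
                reference_label=ref.label,
                alpha=alpha,
                method=method,
                tests=tests,
            )
    return ThresholdDecision(
        threshold=None, reference_label=last_ref, alpha=alpha, method=method,
        tests=last_tests,
    )
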