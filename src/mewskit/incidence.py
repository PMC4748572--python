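"""Admission-denominated incidence analysis.

Rates per 1000 admissions, calendar-month series with mean +/- SD control
limits, period background summaries (age, sex, leading diagnoses), and the
before/after outcome comparison backed by the 2x2 tests in
:mod:`mewskit.wz_analysis`.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from mewskit.wz_analysis import TestResult, chi2_2x2

__all__ = [
    "PeriodSummary",
    "MonthlyPoint",
    "ComparisonResult",
    "round_half_up",
    "rate_per_1000",
    "monthly_series",
    "control_limits",
    "compare_periods",
    "cohort_summary",
]

Outcome = Literal["ihca", "death"]

ADMISSION_COLUMNS = (
    "admission_id", "admit_date", "discharge_date", "age", "sex",
    "diagnosis", "dnr", "period",
)
EVENT_COLUMNS = ("admission_id", "event_type", "event_date")


def round_half_up(value: float, decimals: int) -> float:
    """Decimal round-half-up (5.205 -> 5.21 at 2 decimals)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def rate_per_1000(events: int, admissions: int, decimals: Optional[int] = 2) -> float:
    """Events per 1000 admissions, rounded half-up to ``decimals`` places
    (``decimals=None`` returns the unrounded value)."""
    if admissions < 1:
        raise ValueError(f"admissions must be >= 1, got {admissions}")
    if events < 0:
        raise ValueError(f"events must be >= 0, got {events}")
    raw = 1000.0 * events / admissions
    return raw if decimals is None else round_half_up(raw, decimals)


@dataclass(frozen=True)
class PeriodSummary:
    """Aggregates for one study period (admission counts, outcomes, and
    Table-3-style background)."""

    label: str
    admissions: int
    ihca: int
    deaths: int
    age_mean: Optional[float] = None
    age_sd: Optional[float] = None
    male_fraction: Optional[float] = None
    top_diagnoses: tuple[tuple[str, int, float], ...] = ()  # (name, count, percent)

    def __post_init__(self) -> None:
        if self.admissions < 1:
            raise ValueError("a period needs at least one admission")
        if self.ihca < 0 or self.deaths < 0:
            raise ValueError("counts must be non-negative")

    @property
    def ihca_rate_per_1000(self) -> float:
        return rate_per_1000(self.ihca, self.admissions, decimals=None)

    @property
    def mortality_rate_per_1000(self) -> float:
        return rate_per_1000(self.deaths, self.admissions, decimals=None)


@dataclass(frozen=True)
class MonthlyPoint:
    """One calendar month: admissions, WZ patients, IHCAs, per-1000 rate.

    ``rate_per_1000`` is None for months with zero admissions.  A month's
    WZ count may be smaller than its IHCA count: an arrest can occur with
    no prior warning-zone score.
    """

    month: str  # "YYYY-MM"
    admissions: int
    wz_count: int
    ihca: int
    rate_per_1000: Optional[float]


@dataclass(frozen=True)
class ComparisonResult:
    """Before/after comparison of one outcome."""

    outcome: Outcome
    label_a: str
    label_b: str
    rate_a: float  # per 1000, unrounded
    rate_b: float
    rate_ratio: Optional[float]  # b/a; None when rate_a == 0
    test: TestResult
    alpha: float
    significant: bool


def _month_str(ts: pd.Timestamp) -> str:
    return f"{ts.year:04d}-{ts.month:02d}"


def monthly_series(
    admissions: pd.DataFrame,
    events: pd.DataFrame,
    wz_flags: Mapping[str, bool] | Sequence[str],
    window: tuple[str, str],
) -> list[MonthlyPoint]:
    """One point per calendar month in the half-open window [start, end).

    An admission (and its events) is attributed to the month of the
    admission date.  Every IHCA event must reference a known admission;
    orphans raise with the offending ids.  Months with no admissions appear
    with ``rate_per_1000=None``.
    """
    adm = admissions.copy()
    adm["admit_date"] = pd.to_datetime(adm["admit_date"])
    start = pd.Timestamp(window[0])
    end = pd.Timestamp(window[1])
    if not start < end:
        raise ValueError(f"empty window {window!r}")
    adm = adm[(adm["admit_date"] >= start) & (adm["admit_date"] < end)]

    known = set(adm["admission_id"])
    ihca = events[events["event_type"] == "ihca"]
    orphans = sorted(set(ihca["admission_id"]) - set(admissions["admission_id"]))
    if orphans:
        raise ValueError(f"events reference unknown admissions: {orphans[:10]}")
    ihca = ihca[ihca["admission_id"].isin(known)]

    if isinstance(wz_flags, Mapping):
        wz_ids = {k for k, v in wz_flags.items() if v}
    else:
        wz_ids = set(wz_flags)

    adm_month = adm.set_index("admission_id")["admit_date"].map(_month_str)
    months = pd.period_range(start, end, freq="M")
    # pd.period_range is end-inclusive; drop the boundary month of a
    # half-open window that ends on the first of a month.
    months = [p for p in months if pd.Timestamp(p.start_time) < end]

    points: list[MonthlyPoint] = []
    for p in months:
        key = f"{p.year:04d}-{p.month:02d}"
        ids = set(adm_month[adm_month == key].index)
        n_adm = len(ids)
        n_ihca = int(ihca["admission_id"].isin(ids).sum())
        n_wz = len(ids & wz_ids)
        rate = rate_per_1000(n_ihca, n_adm, decimals=None) if n_adm else None
        points.append(MonthlyPoint(month=key, admissions=n_adm, wz_count=n_wz,
                                   ihca=n_ihca, rate_per_1000=rate))
    return points


def control_limits(monthly_rates: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and sample SD (n-1) of a monthly rate series."""
    rates = [r for r in monthly_rates if r is not None]
    if len(rates) < 2:
        raise ValueError("need at least two monthly rates")
    arr = np.asarray(rates, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1))


def compare_periods(
    period_a: PeriodSummary,
    period_b: PeriodSummary,
    outcome: Outcome = "ihca",
    alpha: float = 0.05,
) -> ComparisonResult:
    """Uncorrected chi-squared comparison of one outcome between periods."""
    if outcome not in ("ihca", "death"):
        raise ValueError(f"outcome must be 'ihca' or 'death', got {outcome!r}")
    ea, eb = (
        (period_a.ihca, period_b.ihca)
        if outcome == "ihca"
        else (period_a.deaths, period_b.deaths)
    )
    test = chi2_2x2(ea, period_a.admissions, eb, period_b.admissions)
    rate_a = rate_per_1000(ea, period_a.admissions, decimals=None)
    rate_b = rate_per_1000(eb, period_b.admissions, decimals=None)
    return ComparisonResult(
        outcome=outcome,
        label_a=period_a.label,
        label_b=period_b.label,
        rate_a=rate_a,
        rate_b=rate_b,
        rate_ratio=(rate_b / rate_a) if rate_a > 0 else None,
        test=test,
        alpha=alpha,
        significant=bool(test.p_value < alpha),
    )


def cohort_summary(
    admissions: pd.DataFrame,
    events: pd.DataFrame,
    label: str,
    top_n: int = 5,
) -> PeriodSummary:
    """Background summary of one period: counts, age mean +/- SD, male
    percentage, and the ``top_n`` admission diagnoses with percentages."""
    if admissions.empty:
        raise ValueError("admissions table is empty")
    n = len(admissions)
    ids = set(admissions["admission_id"])
    ev = events[events["admission_id"].isin(ids)]
    n_ihca = int((ev["event_type"] == "ihca").sum())
    n_death = int((ev["event_type"] == "death").sum())

    ages = pd.to_numeric(admissions["age"], errors="raise")
    counts = admissions["diagnosis"].value_counts()
    top = tuple(
        (str(name), int(cnt), 100.0 * cnt / n)
        for name, cnt in counts.head(top_n).items()
    )
    age_sd = float(ages.std(ddof=1)) if n > 1 else 0.0
    return PeriodSummary(
        label=label,
        admissions=n,
        ihca=n_ihca,
        deaths=n_death,
        age_mean=float(ages.mean()),
        age_sd=age_sd,
        male_fraction=float((admissions["sex"] == "M").mean()),
        top_diagnoses=top,
    )
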