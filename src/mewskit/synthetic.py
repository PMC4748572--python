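"""Synthetic inpatient-cohort generation.

No patient-level data accompany the score audit, so this module fabricates a
cohort whose *aggregates* match the published ones: admission volume of an
acute-care hospital (~840-1000/month), a warning-zone fraction giving ~51
WZ patients/month, stratum-conditional cardiac-arrest probabilities taken
from the audit table (1/556, 4/289, 2/114, 2/56), and Table-3-style
demographics.  Trajectory microstructure (Markov persistence of severity,
geometric length of stay, band-consistent vital draws) is generator policy,
not a claim about the source data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from functools import lru_cache
from typing import Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from mewskit.scoring import (
    NUMERIC_PARAMETERS,
    PARAMETERS,
    PHYSIOLOGICAL_RANGES,
    ScoreTable,
    VitalObservation,
    load_score_table,
)

__all__ = [
    "HazardModel",
    "CohortParams",
    "Trajectory",
    "default_hazard_from_table2",
    "sample_vitals_for_score",
    "sample_trajectories",
    "generate_cohort",
]

STRATA = ("le6", "7", "8", "ge9")

#: Within-stratum split of maximum totals 0..5 for the low-score mass
#: (generator policy; decaying toward high scores).
_LOW_TOTAL_SPLIT = (0.30, 0.24, 0.18, 0.13, 0.09, 0.06)
#: Geometric decay of maximum totals 9, 10, ... within the pooled top bin.
_TOP_TOTAL_DECAY = 0.5


def stratum_of(total: int) -> str:
    """Stratum key for a total score: 'le6', '7', '8', or 'ge9'."""
    if total <= 6:
        return "le6"
    if total == 7:
        return "7"
    if total == 8:
        return "8"
    return "ge9"


@dataclass(frozen=True)
class HazardModel:
    """Per-admission outcome probabilities conditional on the admission's
    maximum score stratum, plus the baseline distribution of maxima."""

    ihca_probs: Mapping[str, float]
    death_prob: float
    stratum_weights: Mapping[str, float]
    #: probability mass of a maximum total of exactly 6 within the 'le6'
    #: stratum (the audit's reference row); the rest spreads over 0-5.
    exact6_within_le6: float = 0.0654

    def __post_init__(self) -> None:
        if set(self.ihca_probs) != set(STRATA):
            raise ValueError(f"ihca_probs must cover strata {STRATA}")
        if set(self.stratum_weights) != set(STRATA):
            raise ValueError(f"stratum_weights must cover strata {STRATA}")
        for p in (*self.ihca_probs.values(), self.death_prob, self.exact6_within_le6):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability out of [0,1]: {p}")
        if any(w < 0 for w in self.stratum_weights.values()):
            raise ValueError("stratum weights must be non-negative")
        if sum(self.stratum_weights.values()) <= 0:
            raise ValueError("stratum weights must have positive mass")

    def normalized_weights(self) -> np.ndarray:
        w = np.array([self.stratum_weights[s] for s in STRATA], dtype=float)
        return w / w.sum()


def default_hazard_from_table2() -> HazardModel:
    """Hazard model calibrated to the published score audit.

    IHCA probabilities are the audit's stratum rates (1/556 for scores <= 6,
    4/289 at 7, 2/114 at 8, 2/56 pooled at >= 9); the death probability
    reproduces ~35.4 in-hospital deaths per 1000 admissions.  Stratum
    weights keep the audit's 556/289/114/56 proportions for scores 6-9+ and
    add a low-score mass sized so the warning-zone fraction matches ~51 WZ
    patients per ~998 monthly admissions (920 over 18 months).
    """
    low_mass = 7946  # 459/(459+556+low) == 920/17961
    return HazardModel(
        ihca_probs={"le6": 1 / 556, "7": 4 / 289, "8": 2 / 114, "ge9": 2 / 56},
        death_prob=636 / 17961,
        stratum_weights={"le6": 556 + low_mass, "7": 289, "8": 114, "ge9": 56},
        exact6_within_le6=556 / (556 + low_mass),
    )


@dataclass(frozen=True)
class CohortParams:
    """Generator settings for one synthetic period."""

    n_admissions: int = 17961
    months: int = 18
    start_month: str = "2013-10"
    monthly_weights: Optional[Sequence[float]] = None  # uniform when None
    los_mean: float = 6.0        # geometric length of stay, days, >= 1
    age_mean: float = 59.3
    age_sd: float = 28.0         # truncated at 0
    male_fraction: float = 0.544
    diagnosis_freqs: Mapping[str, float] = field(
        default_factory=lambda: {
            "pneumonia": 0.065,
            "angina": 0.044,
            "urinary tract infection": 0.024,
            "congestive heart failure": 0.021,
            "acute gastroenteritis": 0.020,
            "other": 0.826,
        }
    )
    dnr_fraction: float = 0.05
    persistence: float = 0.6     # per-day probability of staying in stratum
    extra_obs_prob: float = 0.5  # chance of a second (lower) daily observation
    period_label: str = "after"
    id_prefix: str = "A"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_admissions < 1:
            raise ValueError("n_admissions must be >= 1")
        if self.months < 1:
            raise ValueError("months must be >= 1")
        if self.los_mean < 1.0:
            raise ValueError("mean length of stay must be >= 1 day")
        for name in ("male_fraction", "dnr_fraction", "persistence", "extra_obs_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.age_sd <= 0:
            raise ValueError("age_sd must be positive")
        freqs = self.diagnosis_freqs
        if not freqs or any(f < 0 for f in freqs.values()):
            raise ValueError("diagnosis frequencies must be non-negative and non-empty")
        if abs(sum(freqs.values()) - 1.0) > 1e-6:
            raise ValueError("diagnosis frequencies must sum to 1")
        if self.monthly_weights is not None:
            if len(self.monthly_weights) != self.months:
                raise ValueError("monthly_weights length must equal months")
            if any(w <= 0 for w in self.monthly_weights):
                raise ValueError("monthly weights must be positive")
        datetime.strptime(self.start_month, "%Y-%m")


# ---------------------------------------------------------------------------
# Inverse scoring: draw vitals that reproduce a requested total.

@lru_cache(maxsize=None)
def _decompositions(
    point_values: tuple[tuple[int, ...], ...], target: int
) -> tuple[tuple[int, ...], ...]:
    """All per-parameter point assignments summing to ``target``."""
    out = tuple(
        combo
        for combo in itertools.product(*point_values)
        if sum(combo) == target
    )
    return out


def _band_bounds(table: ScoreTable, parameter: str, band_idx: int) -> tuple[float, float]:
    lo_range, hi_range = PHYSIOLOGICAL_RANGES[parameter]
    g = table.granularity[parameter]
    bands = table.bands[parameter]
    lo = lo_range if band_idx == 0 else bands[band_idx - 1].upper + g
    hi = hi_range if np.isinf(bands[band_idx].upper) else bands[band_idx].upper
    return lo, hi


def sample_vitals_for_score(
    target_total: int,
    table: ScoreTable,
    rng: np.random.Generator,
    patient_id: str = "synthetic",
    timestamp: Optional[datetime] = None,
) -> VitalObservation:
    """Draw an observation whose MEWS total is exactly ``target_total``.

    A per-parameter point decomposition is drawn uniformly over all feasible
    decompositions, then each vital uniformly within a band carrying those
    points (uniform over bands when several share the value).
    """
    if not (0 <= target_total <= table.max_total):
        raise ValueError(
            f"target total {target_total} infeasible (table maximum {table.max_total})"
        )
    decomps = _decompositions(table.point_signature, target_total)
    if not decomps:
        raise ValueError(f"no point decomposition reaches total {target_total}")
    combo = decomps[rng.integers(len(decomps))]
    assigned = dict(zip(PARAMETERS, combo))

    values: dict[str, object] = {}
    for name in NUMERIC_PARAMETERS:
        pts = assigned[name]
        candidates = table.bands_by_points[name][pts]
        band_idx = candidates[rng.integers(len(candidates))]
        lo, hi = _band_bounds(table, name, band_idx)
        g = table.granularity[name]
        n_steps = int(round((hi - lo) / g))
        step = int(rng.integers(n_steps + 1))
        # keep values exactly on the granularity grid (0.1 degC safe)
        values[name] = round((lo + step * g) / g) * g if g < 1 else lo + step * g

    levels = [c for c, p in table.consciousness_points.items()
              if p == assigned["consciousness"]]
    values["consciousness"] = levels[rng.integers(len(levels))]
    flags = [f for f, p in table.concern_points.items() if p == assigned["concern"]]
    values["concern"] = bool(flags[rng.integers(len(flags))])

    return VitalObservation(
        patient_id=patient_id,
        timestamp=timestamp or datetime(2000, 1, 1, 8, 0),
        sbp=float(values["sbp"]),
        hr=float(values["hr"]),
        rr=float(values["rr"]),
        temp=float(values["temp"]),
        consciousness=values["consciousness"],
        concern=values["concern"],
    )


# ---------------------------------------------------------------------------
# Trajectories and cohort tables.

@dataclass(frozen=True)
class Trajectory:
    """One synthetic admission before outcome draws: demographics, the
    daily maximum-total path, and the realized vital observations."""

    admission_id: str
    admit_date: datetime
    los: int
    age: float
    sex: str
    diagnosis: str
    dnr: bool
    max_total: int
    daily_totals: tuple[int, ...]
    observations: tuple[VitalObservation, ...]

    @property
    def stratum(self) -> str:
        return stratum_of(self.max_total)

    @property
    def discharge_date(self) -> datetime:
        return self.admit_date + timedelta(days=self.los)


def _draw_max_total(hazard: HazardModel, rng: np.random.Generator) -> int:
    s = STRATA[rng.choice(len(STRATA), p=hazard.normalized_weights())]
    if s == "7":
        return 7
    if s == "8":
        return 8
    if s == "ge9":
        decay = _TOP_TOTAL_DECAY ** np.arange(7)  # totals 9..15
        return 9 + int(rng.choice(7, p=decay / decay.sum()))
    if rng.random() < hazard.exact6_within_le6:
        return 6
    split = np.asarray(_LOW_TOTAL_SPLIT)
    return int(rng.choice(6, p=split / split.sum()))


def _daily_total_path(
    max_total: int, los: int, persistence: float, rng: np.random.Generator
) -> list[int]:
    """Markov path over totals 0..max_total with one forced peak day, so the
    admission's maximum daily total is exactly ``max_total``."""
    peak = int(rng.integers(los))
    path = []
    state = int(rng.integers(min(max_total, 3) + 1))
    for _ in range(los):
        path.append(state)
        if rng.random() >= persistence:
            step = -1 if rng.random() < 0.6 else 1  # drift toward recovery
            state = int(np.clip(state + step, 0, max_total))
    path[peak] = max_total
    return path


def _sample_one_trajectory(
    idx: int,
    params: CohortParams,
    hazard: HazardModel,
    table: ScoreTable,
    month_starts: Sequence[datetime],
    month_p: np.ndarray,
    rng: np.random.Generator,
) -> Trajectory:
    m = int(rng.choice(len(month_starts), p=month_p))
    month_start = month_starts[m]
    next_month = (month_start.replace(day=28) + timedelta(days=4)).replace(day=1)
    days_in_month = (next_month - month_start).days
    admit = month_start + timedelta(days=int(rng.integers(days_in_month)))

    los = int(rng.geometric(1.0 / params.los_mean))
    age = float(rng.normal(params.age_mean, params.age_sd))
    while age < 0:
        age = float(rng.normal(params.age_mean, params.age_sd))
    sex = "M" if rng.random() < params.male_fraction else "F"
    diagnoses = list(params.diagnosis_freqs)
    diag_p = np.array([params.diagnosis_freqs[d] for d in diagnoses], dtype=float)
    diagnosis = diagnoses[int(rng.choice(len(diagnoses), p=diag_p / diag_p.sum()))]
    dnr = bool(rng.random() < params.dnr_fraction)

    max_total = _draw_max_total(hazard, rng)
    path = _daily_total_path(max_total, los, params.persistence, rng)

    admission_id = f"{params.id_prefix}{idx:06d}"
    observations: list[VitalObservation] = []
    for day, total in enumerate(path):
        base = admit + timedelta(days=day, hours=8)
        observations.append(
            sample_vitals_for_score(
                total, table, rng, patient_id=admission_id, timestamp=base
            )
        )
        if rng.random() < params.extra_obs_prob:
            lower = int(rng.integers(total + 1))
            observations.append(
                sample_vitals_for_score(
                    lower, table, rng,
                    patient_id=admission_id,
                    timestamp=base + timedelta(hours=8),
                )
            )
    return Trajectory(
        admission_id=admission_id,
        admit_date=admit,
        los=los,
        age=age,
        sex=sex,
        diagnosis=diagnosis,
        dnr=dnr,
        max_total=max_total,
        daily_totals=tuple(path),
        observations=tuple(observations),
    )


def sample_trajectories(
    params: CohortParams,
    hazard: HazardModel,
    seed: Optional[int] = None,
    table: Optional[ScoreTable] = None,
) -> Iterator[Trajectory]:
    """Yield reproducible admission trajectories (no outcome draws).

    Each admission consumes an independent substream spawned from ``seed``,
    so trajectories are identical regardless of consumption order.
    """
    if seed is None:
        seed = params.seed
    if seed is None:
        raise ValueError("a seed is required (argument or CohortParams.seed)")
    table = table or load_score_table()
    start = datetime.strptime(params.start_month, "%Y-%m")
    month_starts = []
    cur = start
    for _ in range(params.months):
        month_starts.append(cur)
        cur = (cur.replace(day=28) + timedelta(days=4)).replace(day=1)
    if params.monthly_weights is None:
        month_p = np.full(params.months, 1.0 / params.months)
    else:
        w = np.asarray(params.monthly_weights, dtype=float)
        month_p = w / w.sum()

    children = np.random.SeedSequence(seed).spawn(params.n_admissions)
    for i in range(params.n_admissions):
        rng = np.random.default_rng(children[i])
        yield _sample_one_trajectory(
            i, params, hazard, table, month_starts, month_p, rng
        )


def generate_cohort(
    params: CohortParams,
    hazard: Optional[HazardModel] = None,
    seed: Optional[int] = None,
    table: Optional[ScoreTable] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (admissions, vitals, events) tables for one period.

    IHCA events are per-admission Bernoulli draws at the probability of the
    admission's maximum-score stratum, dated to a day spent at that stratum;
    deaths are independent draws dated to discharge.  Identical
    (params, hazard, seed) yield identical tables.
    """
    hazard = hazard or default_hazard_from_table2()
    if seed is None:
        seed = params.seed
    if seed is None:
        raise ValueError("a seed is required (argument or CohortParams.seed)")
    # outcome draws use a dedicated child stream per admission
    outcome_children = np.random.SeedSequence((seed, 1)).spawn(params.n_admissions)

    adm_rows, vital_rows, event_rows = [], [], []
    for i, traj in enumerate(sample_trajectories(params, hazard, seed, table)):
        adm_rows.append(
            {
                "admission_id": traj.admission_id,
                "admit_date": traj.admit_date.date().isoformat(),
                "discharge_date": traj.discharge_date.date().isoformat(),
                "age": round(traj.age, 1),
                "sex": traj.sex,
                "diagnosis": traj.diagnosis,
                "dnr": int(traj.dnr),
                "period": params.period_label,
            }
        )
        for obs in traj.observations:
            vital_rows.append(
                {
                    "patient_id": obs.patient_id,
                    "timestamp": obs.timestamp.isoformat(),
                    "sbp": obs.sbp,
                    "hr": obs.hr,
                    "rr": obs.rr,
                    "temp": obs.temp,
                    "consciousness": obs.consciousness.value,
                    "concern": int(obs.concern),
                }
            )
        rng = np.random.default_rng(outcome_children[i])
        if rng.random() < hazard.ihca_probs[traj.stratum]:
            stratum_days = [
                d for d, t in enumerate(traj.daily_totals)
                if stratum_of(t) == traj.stratum
            ]
            day = stratum_days[int(rng.integers(len(stratum_days)))]
            event_rows.append(
                {
                    "admission_id": traj.admission_id,
                    "event_type": "ihca",
                    "event_date": (traj.admit_date + timedelta(days=day)).date().isoformat(),
                }
            )
        if rng.random() < hazard.death_prob:
            event_rows.append(
                {
                    "admission_id": traj.admission_id,
                    "event_type": "death",
                    "event_date": traj.discharge_date.date().isoformat(),
                }
            )

    admissions = pd.DataFrame(adm_rows)
    vitals = pd.DataFrame(vital_rows)
    events = pd.DataFrame(
        event_rows, columns=["admission_id", "event_type", "event_date"]
    )
    return admissions, vitals, events
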