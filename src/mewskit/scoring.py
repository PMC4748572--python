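"""Vital-sign banding and MEWS computation.

The score table is configuration: each numeric parameter (systolic blood
pressure, heart rate, respiratory rate, temperature) carries an ordered list
of inclusive upper bounds with 0–3 points each, the last band open; the
consciousness (AVPU) and concern items are categorical point maps.  A total
is the sum of the six per-parameter points.  The built-in default table
gives a maximum total of 15.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property
from datetime import datetime
from decimal import Decimal, ROUND_HALF_UP
from enum import Enum
from typing import Mapping, Optional, Sequence

__all__ = [
    "Consciousness",
    "VitalObservation",
    "ScoreBand",
    "ScoreTable",
    "MewsResult",
    "ScoreTableError",
    "ObservationError",
    "NUMERIC_PARAMETERS",
    "PARAMETERS",
    "PHYSIOLOGICAL_RANGES",
    "DEFAULT_TABLE_CONFIG",
    "load_score_table",
    "score_parameter",
    "compute_mews",
    "daily_max_mews",
    "is_warning",
]


class ScoreTableError(ValueError):
    """Raised for an invalid score-table configuration."""


class ObservationError(ValueError):
    """Raised for an invalid or unscorable vital-sign observation."""


class Consciousness(str, Enum):
    """AVPU consciousness scale."""

    ALERT = "alert"
    VOICE = "voice"
    PAIN = "pain"
    UNRESPONSIVE = "unresponsive"


NUMERIC_PARAMETERS = ("sbp", "hr", "rr", "temp")
PARAMETERS = NUMERIC_PARAMETERS + ("consciousness", "concern")

#: Accepted physiological ranges (inclusive) for numeric vitals.
PHYSIOLOGICAL_RANGES: Mapping[str, tuple[float, float]] = {
    "sbp": (0.0, 400.0),
    "hr": (0.0, 350.0),
    "rr": (0.0, 100.0),
    "temp": (20.0, 45.0),
}

#: Measurement granularity used to round values before band lookup.
GRANULARITY: Mapping[str, float] = {"sbp": 1.0, "hr": 1.0, "rr": 1.0, "temp": 0.1}

#: Built-in banding rubric.  Bands are (inclusive upper bound, points);
#: ``null``/inf upper means the open top band.  Numeric alignment follows the
#: Subbe-style MEWS convention.
DEFAULT_TABLE_CONFIG: dict = {
    "sbp": [
        {"upper": 70, "points": 3},
        {"upper": 80, "points": 2},
        {"upper": 100, "points": 1},
        {"upper": 199, "points": 0},
        {"upper": None, "points": 2},
    ],
    "hr": [
        {"upper": 40, "points": 2},
        {"upper": 50, "points": 1},
        {"upper": 100, "points": 0},
        {"upper": 110, "points": 1},
        {"upper": 129, "points": 2},
        {"upper": None, "points": 3},
    ],
    "rr": [
        {"upper": 8, "points": 2},
        {"upper": 14, "points": 0},
        {"upper": 20, "points": 1},
        {"upper": 29, "points": 2},
        {"upper": None, "points": 3},
    ],
    "temp": [
        {"upper": 35.0, "points": 2},
        {"upper": 38.4, "points": 0},
        {"upper": None, "points": 2},
    ],
    "consciousness": {"alert": 0, "voice": 1, "pain": 2, "unresponsive": 3},
    "concern": {"no": 0, "yes": 1},
    "missing_policy": "zero",
}


def _round_half_up(value: float, granularity: float) -> float:
    """Round ``value`` to the nearest multiple of ``granularity``, half away
    from zero, using decimal arithmetic so 0.1-steps are exact."""
    q = Decimal(str(granularity))
    return float((Decimal(repr(value)) / q).quantize(Decimal(1), rounding=ROUND_HALF_UP) * q)


@dataclass(frozen=True)
class VitalObservation:
    """One timestamped vital-sign set for one patient.

    Any vital may be ``None`` (missing).  Numeric vitals outside their
    physiological range raise :class:`ObservationError` at construction.
    """

    patient_id: str
    timestamp: datetime
    sbp: Optional[float] = None
    hr: Optional[float] = None
    rr: Optional[float] = None
    temp: Optional[float] = None
    consciousness: Optional[Consciousness] = None
    concern: Optional[bool] = None

    def __post_init__(self) -> None:
        for name in NUMERIC_PARAMETERS:
            value = getattr(self, name)
            if value is None:
                continue
            lo, hi = PHYSIOLOGICAL_RANGES[name]
            if not (lo <= value <= hi):
                raise ObservationError(
                    f"{name}={value!r} outside physiological range [{lo}, {hi}]"
                )
        if self.consciousness is not None and not isinstance(
            self.consciousness, Consciousness
        ):
            object.__setattr__(
                self, "consciousness", Consciousness(self.consciousness)
            )

    @property
    def missing(self) -> tuple[str, ...]:
        """Names of parameters not recorded in this observation."""
        return tuple(p for p in PARAMETERS if getattr(self, p) is None)


@dataclass(frozen=True)
class ScoreBand:
    """One band of a numeric parameter: inclusive upper bound and points."""

    upper: float  # math.inf for the open top band
    points: int

    def __post_init__(self) -> None:
        if self.points not in (0, 1, 2, 3):
            raise ScoreTableError(f"band points must be 0-3, got {self.points}")


@dataclass(frozen=True)
class ScoreTable:
    """Validated banding rubric for all six parameters."""

    bands: Mapping[str, tuple[ScoreBand, ...]]
    consciousness_points: Mapping[Consciousness, int]
    concern_points: Mapping[bool, int]
    granularity: Mapping[str, float] = field(default_factory=lambda: dict(GRANULARITY))
    missing_policy: str = "zero"  # "zero" | "strict"

    def __post_init__(self) -> None:
        for name in NUMERIC_PARAMETERS:
            if name not in self.bands:
                raise ScoreTableError(f"no bands configured for parameter {name!r}")
            bands = self.bands[name]
            if not bands:
                raise ScoreTableError(f"empty band list for parameter {name!r}")
            n_open = sum(1 for b in bands if math.isinf(b.upper))
            if n_open != 1:
                raise ScoreTableError(
                    f"parameter {name!r} must have exactly one open band, found {n_open}"
                )
            if not math.isinf(bands[-1].upper):
                raise ScoreTableError(
                    f"parameter {name!r}: the open band must come last"
                )
            uppers = [b.upper for b in bands]
            if any(u2 <= u1 for u1, u2 in zip(uppers, uppers[1:])):
                raise ScoreTableError(
                    f"parameter {name!r}: band upper bounds must strictly increase "
                    f"(got {uppers}) — overlapping or gapped bands"
                )
        if set(self.consciousness_points) != set(Consciousness):
            raise ScoreTableError("consciousness map must cover alert/voice/pain/unresponsive")
        if set(self.concern_points) != {False, True}:
            raise ScoreTableError("concern map must cover yes and no")
        for m in (self.consciousness_points, self.concern_points):
            for v in m.values():
                if not isinstance(v, int) or not (0 <= v <= 3):
                    raise ScoreTableError(f"categorical points must be integers 0-3, got {v}")
        if self.missing_policy not in ("zero", "strict"):
            raise ScoreTableError(f"unknown missing policy {self.missing_policy!r}")

    def max_points(self, parameter: str) -> int:
        if parameter in NUMERIC_PARAMETERS:
            return max(b.points for b in self.bands[parameter])
        if parameter == "consciousness":
            return max(self.consciousness_points.values())
        if parameter == "concern":
            return max(self.concern_points.values())
        raise KeyError(parameter)

    @cached_property
    def max_total(self) -> int:
        """Greatest achievable total score (15 with the default table)."""
        return sum(self.max_points(p) for p in PARAMETERS)

    @cached_property
    def point_signature(self) -> tuple[tuple[int, ...], ...]:
        """Achievable point values per parameter, in PARAMETERS order."""
        return tuple(self.point_values(p) for p in PARAMETERS)

    @cached_property
    def bands_by_points(self) -> Mapping[str, Mapping[int, tuple[int, ...]]]:
        """For each numeric parameter, band indices grouped by point value."""
        out: dict[str, dict[int, tuple[int, ...]]] = {}
        for name in NUMERIC_PARAMETERS:
            groups: dict[int, list[int]] = {}
            for i, b in enumerate(self.bands[name]):
                groups.setdefault(b.points, []).append(i)
            out[name] = {k: tuple(v) for k, v in groups.items()}
        return out

    def point_values(self, parameter: str) -> tuple[int, ...]:
        """Distinct point values achievable for one parameter, ascending."""
        if parameter in NUMERIC_PARAMETERS:
            vals = {b.points for b in self.bands[parameter]}
        elif parameter == "consciousness":
            vals = set(self.consciousness_points.values())
        else:
            vals = set(self.concern_points.values())
        return tuple(sorted(vals))


@dataclass(frozen=True)
class MewsResult:
    """Per-parameter points, their total, and scoring metadata."""

    points: Mapping[str, int]
    total: int
    missing_parameters: tuple[str, ...]
    timestamp: datetime
    patient_id: str

    def __post_init__(self) -> None:
        if self.total != sum(self.points.values()):
            raise ValueError("total must equal the sum of per-parameter points")


def _parse_bands(name: str, raw: Sequence[Mapping]) -> tuple[ScoreBand, ...]:
    bands = []
    for entry in raw:
        try:
            upper = entry["upper"]
            points = entry["points"]
        except (KeyError, TypeError) as exc:
            raise ScoreTableError(
                f"parameter {name!r}: each band needs 'upper' and 'points' ({entry!r})"
            ) from exc
        upper = math.inf if upper is None else float(upper)
        bands.append(ScoreBand(upper=upper, points=int(points)))
    return tuple(bands)


def load_score_table(config: Optional[Mapping] = None) -> ScoreTable:
    """Build a validated :class:`ScoreTable` from a configuration mapping.

    ``None`` or an empty mapping yields the built-in default table.  A partial
    configuration overrides individual parameters and keeps defaults for the
    rest.  Raises :class:`ScoreTableError` for overlapping/gapped bands,
    out-of-range points, or malformed categorical maps.
    """
    merged = dict(DEFAULT_TABLE_CONFIG)
    if config:
        unknown = set(config) - set(DEFAULT_TABLE_CONFIG)
        if unknown:
            raise ScoreTableError(f"unknown score-table keys: {sorted(unknown)}")
        merged.update(config)

    bands = {name: _parse_bands(name, merged[name]) for name in NUMERIC_PARAMETERS}

    raw_consciousness = merged["consciousness"]
    try:
        consciousness_points = {
            Consciousness(level): int(pts) for level, pts in raw_consciousness.items()
        }
    except ValueError as exc:
        raise ScoreTableError(f"bad consciousness map: {exc}") from exc

    # YAML 1.1 loads bare no/yes as booleans; accept both spellings.
    raw_concern = {
        {False: "no", True: "yes"}.get(k, k): v for k, v in merged["concern"].items()
    }
    if set(raw_concern) != {"no", "yes"}:
        raise ScoreTableError("concern map must have exactly the keys 'no' and 'yes'")
    concern_points = {False: int(raw_concern["no"]), True: int(raw_concern["yes"])}

    return ScoreTable(
        bands=bands,
        consciousness_points=consciousness_points,
        concern_points=concern_points,
        missing_policy=merged["missing_policy"],
    )


def score_parameter(value, parameter: str, table: ScoreTable) -> int:
    """Points for one parameter value under ``table``.

    Numeric values are rounded half-up to the parameter's granularity and
    mapped to the unique band whose inclusive upper bound contains them.
    ``value=None`` follows the table's missing policy ("zero" scores 0,
    "strict" raises).
    """
    if parameter not in PARAMETERS:
        raise KeyError(f"unknown parameter {parameter!r}")
    if value is None:
        if table.missing_policy == "strict":
            raise ObservationError(f"missing value for {parameter!r} under strict policy")
        return 0
    if parameter == "consciousness":
        return table.consciousness_points[Consciousness(value)]
    if parameter == "concern":
        return table.concern_points[bool(value)]

    lo, hi = PHYSIOLOGICAL_RANGES[parameter]
    if not (lo <= value <= hi):
        raise ObservationError(
            f"{parameter}={value!r} outside physiological range [{lo}, {hi}]"
        )
    rounded = _round_half_up(float(value), table.granularity[parameter])
    for band in table.bands[parameter]:
        if rounded <= band.upper + 1e-9:
            return band.points
    raise AssertionError("open band guarantees coverage")  # pragma: no cover


def compute_mews(observation: VitalObservation, table: ScoreTable) -> MewsResult:
    """Score one observation: per-parameter points summed to a total.

    Missing parameters are recorded in ``missing_parameters``; if *all six*
    are missing no score is computable and :class:`ObservationError` is
    raised regardless of the missing policy.
    """
    missing = observation.missing
    if len(missing) == len(PARAMETERS):
        raise ObservationError(
            f"all parameters missing for patient {observation.patient_id!r} "
            f"at {observation.timestamp.isoformat()} — no score computable"
        )
    points = {
        p: score_parameter(getattr(observation, p), p, table) for p in PARAMETERS
    }
    return MewsResult(
        points=points,
        total=sum(points.values()),
        missing_parameters=missing,
        timestamp=observation.timestamp,
        patient_id=observation.patient_id,
    )


def daily_max_mews(
    observations: Sequence[VitalObservation], table: ScoreTable
) -> MewsResult:
    """Highest-score observation of one patient-day.

    All observations must share a patient id and calendar date.  Ties on the
    total are broken by the earliest timestamp.
    """
    if not observations:
        raise ObservationError("daily_max_mews requires at least one observation")
    patients = {o.patient_id for o in observations}
    if len(patients) > 1:
        raise ObservationError(f"observations span multiple patients: {sorted(patients)}")
    days = {o.timestamp.date() for o in observations}
    if len(days) > 1:
        raise ObservationError(f"observations span multiple days: {sorted(map(str, days))}")
    results = [compute_mews(o, table) for o in observations]
    return max(results, key=lambda r: (r.total, -r.timestamp.timestamp()))


def is_warning(total: int, threshold: int) -> bool:
    """True iff ``total`` is in the warning zone (total >= threshold)."""
    if total < 0:
        raise ValueError(f"total must be >= 0, got {total}")
    if threshold < 1:
        raise ValueError(f"threshold must be >= 1, got {threshold}")
    return total >= threshold
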