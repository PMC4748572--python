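"""Readers, writers, run manifests, and the end-to-end pipeline driver.

All tabular interchange is comma-separated UTF-8 with ISO-8601 dates and
"." decimals; empty fields mean missing.  Report rounding happens here, at
the writer layer — internal values stay at full precision.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

import mewskit
from mewskit import incidence as inc
from mewskit import wz_analysis as wz
from mewskit.scoring import (
    Consciousness,
    ScoreTable,
    VitalObservation,
    daily_max_mews,
    is_warning,
    load_score_table,
)

__all__ = [
    "RunManifest",
    "read_vitals",
    "read_admissions",
    "read_events",
    "read_score_table_file",
    "write_strata_report",
    "write_monthly_report",
    "daily_max_table",
    "run_pipeline",
]

VITALS_COLUMNS = (
    "patient_id", "timestamp", "sbp", "hr", "rr", "temp", "consciousness", "concern",
)
_CONSCIOUSNESS_TOKENS = {c.value for c in Consciousness}


class InputError(ValueError):
    """A malformed input file (message carries the row number)."""


@dataclass(frozen=True)
class RunManifest:
    """Provenance record emitted once per CLI run; sufficient to re-run."""

    command: str
    inputs: Mapping[str, str]  # path -> sha256
    config: Mapping
    seed: Optional[int]
    version: str
    timestamp: str

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


def build_manifest(
    command: str,
    input_paths: Sequence[Path | str],
    config: Mapping,
    seed: Optional[int] = None,
) -> RunManifest:
    checksums = {}
    for p in input_paths:
        p = Path(p)
        checksums[str(p)] = hashlib.sha256(p.read_bytes()).hexdigest()
    return RunManifest(
        command=command,
        inputs=checksums,
        config=dict(config),
        seed=seed,
        version=mewskit.__version__,
        timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
    )


def _missing_float(raw: str) -> Optional[float]:
    raw = raw.strip()
    return None if raw == "" else float(raw)


def read_vitals(path: Path | str) -> list[VitalObservation]:
    """Typed, validated vital observations; errors carry 1-based data row
    numbers.  Empty fields are missing vitals."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = set(VITALS_COLUMNS) - set(df.columns)
    if missing_cols:
        raise InputError(f"{path}: missing columns {sorted(missing_cols)}")
    out: list[VitalObservation] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        try:
            ts = datetime.fromisoformat(row.timestamp.strip())
        except ValueError as exc:
            raise InputError(
                f"{path}: row {row_no}: unparseable timestamp {row.timestamp!r}"
            ) from exc
        raw_consciousness = row.consciousness.strip()
        if raw_consciousness and raw_consciousness not in _CONSCIOUSNESS_TOKENS:
            raise InputError(
                f"{path}: row {row_no}: unknown consciousness token "
                f"{raw_consciousness!r}; allowed: {sorted(_CONSCIOUSNESS_TOKENS)}"
            )
        raw_concern = row.concern.strip()
        if raw_concern not in ("", "0", "1"):
            raise InputError(
                f"{path}: row {row_no}: concern must be 0, 1 or empty, got {raw_concern!r}"
            )
        try:
            obs = VitalObservation(
                patient_id=row.patient_id.strip(),
                timestamp=ts,
                sbp=_missing_float(row.sbp),
                hr=_missing_float(row.hr),
                rr=_missing_float(row.rr),
                temp=_missing_float(row.temp),
                consciousness=(
                    Consciousness(raw_consciousness) if raw_consciousness else None
                ),
                concern=None if raw_concern == "" else raw_concern == "1",
            )
        except ValueError as exc:
            raise InputError(f"{path}: row {row_no}: {exc}") from exc
        out.append(obs)
    return out


def read_admissions(path: Path | str) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, dtype={"admission_id": str})
    missing = set(inc.ADMISSION_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing columns {sorted(missing)}")
    for col in ("admit_date", "discharge_date"):
        try:
            df[col] = pd.to_datetime(df[col], format="ISO8601")
        except ValueError as exc:
            raise InputError(f"{path}: bad {col}: {exc}") from exc
    bad_sex = set(df["sex"].unique()) - {"M", "F"}
    if bad_sex:
        raise InputError(f"{path}: sex must be M or F, found {sorted(bad_sex)}")
    if not df["dnr"].isin((0, 1)).all():
        raise InputError(f"{path}: dnr must be 0 or 1")
    return df


def read_events(path: Path | str) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, dtype={"admission_id": str})
    missing = set(inc.EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing columns {sorted(missing)}")
    bad = set(df["event_type"].unique()) - {"ihca", "death"}
    if bad:
        raise InputError(f"{path}: event_type must be ihca or death, found {sorted(bad)}")
    df["event_date"] = pd.to_datetime(df["event_date"], format="ISO8601")
    return df


def read_score_table_file(path: Path | str) -> ScoreTable:
    """Score table from a YAML or JSON document."""
    text = Path(path).read_text()
    config = yaml.safe_load(text)
    return load_score_table(config or {})


def daily_max_table(
    observations: Sequence[VitalObservation],
    table: ScoreTable,
    threshold: int = 7,
) -> pd.DataFrame:
    """Per-patient-day maxima: columns patient_id, date, total, warning."""
    groups: dict[tuple[str, str], list[VitalObservation]] = {}
    for obs in observations:
        groups.setdefault((obs.patient_id, obs.timestamp.date().isoformat()), []).append(obs)
    rows = []
    for (pid, day), group in sorted(groups.items()):
        res = daily_max_mews(group, table)
        rows.append(
            {
                "patient_id": pid,
                "date": day,
                "total": res.total,
                "warning": int(is_warning(res.total, threshold)),
            }
        )
    return pd.DataFrame(rows, columns=["patient_id", "date", "total", "warning"])


def patient_max_scores(daily: pd.DataFrame) -> pd.DataFrame:
    """Reduce a daily-max table to one maximum score per patient."""
    return (
        daily.groupby("patient_id", as_index=False)["total"].max()
        .rename(columns={"total": "max_score"})
    )


def write_strata_report(
    strata: Sequence[wz.StratumSummary],
    path: Path,
    decision: Optional[wz.ThresholdDecision] = None,
) -> None:
    rows = []
    for s in strata:
        p = None
        if decision is not None and s.label in decision.tests:
            p = decision.tests[s.label].p_value
        rows.append(
            {
                "score": s.label,
                "n": s.n_patients,
                "events": s.n_events,
                "rate_pct": inc.round_half_up(s.rate, 2),
                "ci_low": inc.round_half_up(s.ci_low, 2),
                "ci_high": inc.round_half_up(s.ci_high, 2),
                "p_vs_reference": "" if p is None else f"{p:.4g}",
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_monthly_report(points: Sequence[inc.MonthlyPoint], path: Path) -> None:
    rows = [
        {
            "month": p.month,
            "admissions": p.admissions,
            "wz_count": p.wz_count,
            "ihca": p.ihca,
            "rate_per_1000": (
                "" if p.rate_per_1000 is None else inc.round_half_up(p.rate_per_1000, 2)
            ),
        }
        for p in points
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Umbrella pipeline


def run_pipeline(config: Mapping, out_dir: Path | str) -> dict:
    """Score -> stratify -> select threshold -> monthly incidence -> compare.

    ``config`` names per-period input files::

        periods:
          before: {admissions: a.csv, vitals: v.csv, events: e.csv}
          after:  {admissions: ..., vitals: ..., events: ...}
        audit_period: before     # period used for the threshold audit
        threshold: 7             # warning-zone threshold for reports
        alpha: 0.05
        top_bin: 9
        score_table: table.yaml  # optional

    Writes stratum report, threshold decision, per-period monthly series,
    comparison report, and a manifest; returns the bundle as a dict.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        period_cfg = config["periods"]
        labels = list(period_cfg)
        if len(labels) != 2:
            raise InputError(f"need exactly two periods, got {labels}")
    except KeyError as exc:
        raise InputError("config must define 'periods'") from exc

    table = (
        read_score_table_file(config["score_table"])
        if config.get("score_table")
        else load_score_table()
    )
    alpha = float(config.get("alpha", 0.05))
    threshold = int(config.get("threshold", 7))
    top_bin = int(config.get("top_bin", 9))
    audit_period = config.get("audit_period", labels[0])

    input_paths = []
    periods: dict[str, dict] = {}
    for label in labels:
        cfg = period_cfg[label]
        for key in ("admissions", "vitals", "events"):
            if key not in cfg:
                raise InputError(f"period {label!r}: missing input {key!r}")
            if not Path(cfg[key]).exists():
                raise InputError(f"period {label!r}: missing input file {cfg[key]}")
            input_paths.append(cfg[key])
        stage = f"read[{label}]"
        try:
            admissions = read_admissions(cfg["admissions"])
            vitals = read_vitals(cfg["vitals"])
            events = read_events(cfg["events"])
            stage = f"score[{label}]"
            daily = daily_max_table(vitals, table, threshold=threshold)
            max_scores = patient_max_scores(daily)
            stage = f"incidence[{label}]"
            summary = inc.cohort_summary(admissions, events, label)
            wz_ids = set(max_scores.loc[max_scores["max_score"] >= threshold, "patient_id"])
            window = (
                admissions["admit_date"].min().strftime("%Y-%m-01"),
                (admissions["admit_date"].max() + pd.offsets.MonthBegin(1)).strftime(
                    "%Y-%m-%d"
                ),
            )
            monthly = inc.monthly_series(admissions, events, wz_ids, window)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage} failed: {exc}") from exc
        periods[label] = {
            "summary": summary,
            "daily": daily,
            "max_scores": max_scores,
            "monthly": monthly,
            "admissions": admissions,
            "events": events,
        }
        write_monthly_report(monthly, out_dir / f"monthly_{label}.csv")
        daily.to_csv(out_dir / f"daily_scores_{label}.csv", index=False)

    # threshold audit on the designated period
    try:
        audit = periods[audit_period]
    except KeyError:
        raise InputError(f"audit_period {audit_period!r} is not a configured period")
    adm = audit["admissions"]
    ihca_ids = set(
        audit["events"].loc[audit["events"]["event_type"] == "ihca", "admission_id"]
    )
    scores = audit["max_scores"]
    strata = wz.stratify(
        scores["max_score"].tolist(),
        [pid in ihca_ids for pid in scores["patient_id"]],
        top_bin=top_bin,
    )
    decision = wz.select_wz(strata, alpha=alpha) if len(strata) >= 2 else None
    write_strata_report(strata, out_dir / "strata.csv", decision)
    if decision is not None:
        (out_dir / "threshold_decision.json").write_text(
            json.dumps(
                {
                    "threshold": decision.threshold,
                    "reference": decision.reference_label,
                    "alpha": decision.alpha,
                    "method": decision.method,
                    "p_values": {k: t.p_value for k, t in decision.tests.items()},
                },
                indent=2,
            )
            + "\n"
        )

    a, b = (periods[label]["summary"] for label in labels)
    comparisons = {
        outcome: inc.compare_periods(a, b, outcome=outcome, alpha=alpha)
        for outcome in ("ihca", "death")
    }
    comparison_payload = {
        outcome: {
            "rate_a_per_1000": inc.round_half_up(c.rate_a, 2),
            "rate_b_per_1000": inc.round_half_up(c.rate_b, 2),
            "rate_ratio": None if c.rate_ratio is None else round(c.rate_ratio, 4),
            "p_value": c.test.p_value,
            "significant": c.significant,
            "alpha": c.alpha,
        }
        for outcome, c in comparisons.items()
    }
    (out_dir / "comparison.json").write_text(
        json.dumps(comparison_payload, indent=2) + "\n"
    )

    manifest = build_manifest("run", input_paths, dict(config), config.get("seed"))
    manifest.write(out_dir / "manifest.json")
    return {
        "strata": strata,
        "decision": decision,
        "periods": periods,
        "comparisons": comparisons,
        "out_dir": out_dir,
    }
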