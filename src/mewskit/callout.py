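"""Callout-algorithm state machine and cohort-level simulation.

A ward patient is ``monitoring`` until the daily maximum score reaches the
warning zone.  A non-DNR patient then triggers the full alert cascade
(physician + ICU nurses notified, ward treatment started); a DNR patient
has the pathway terminated instead.  Alerted patients who keep
deteriorating are transferred to the ICU and leave the ward at-risk pool.
The simulator layers an optional post-alert hazard reduction (theta) on the
stratum-conditional arrest probabilities to model the intervention effect.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np

from mewskit.incidence import PeriodSummary
from mewskit.scoring import ScoreTable, daily_max_mews, is_warning, load_score_table
from mewskit.synthetic import (
    CohortParams,
    HazardModel,
    Trajectory,
    default_hazard_from_table2,
    sample_trajectories,
    stratum_of,
)

__all__ = [
    "CalloutState",
    "CalloutAction",
    "InterventionParams",
    "CalloutStateError",
    "step_callout",
    "simulate_study",
]


class CalloutState(str, Enum):
    MONITORING = "monitoring"
    ALERTED = "alerted"
    INITIAL_TREATMENT = "initial_treatment"
    ICU_TRANSFERRED = "icu_transferred"
    TERMINATED_DNR = "terminated_dnr"
    ARRESTED = "arrested"
    DISCHARGED = "discharged"


#: States in which no further warning-zone processing occurs.
ABSORBING_STATES = frozenset(
    {
        CalloutState.ICU_TRANSFERRED,
        CalloutState.TERMINATED_DNR,
        CalloutState.ARRESTED,
        CalloutState.DISCHARGED,
    }
)


class CalloutAction(str, Enum):
    ALERT_RAISED = "alert_raised"
    PHYSICIAN_NOTIFIED = "physician_notified"
    ICU_NURSES_NOTIFIED = "icu_nurses_notified"
    TREATMENT_STARTED = "treatment_started"
    ICU_TRANSFER = "icu_transfer"
    DNR_TERMINATION = "dnr_termination"


ALERT_CASCADE = (
    CalloutAction.ALERT_RAISED,
    CalloutAction.PHYSICIAN_NOTIFIED,
    CalloutAction.ICU_NURSES_NOTIFIED,
    CalloutAction.TREATMENT_STARTED,
)


class CalloutStateError(RuntimeError):
    """step_callout invoked on an absorbing state."""


@dataclass(frozen=True)
class InterventionParams:
    """Post-alert effect: ``theta`` multiplies the daily arrest hazard from
    the first alert onward; ``deterioration_escalation_prob`` is the per-day
    chance an alerted patient is escalated to ICU transfer."""

    theta: float = 1.0
    deterioration_escalation_prob: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.theta <= 1.0):
            raise ValueError(f"theta must be in (0,1], got {self.theta}")
        if not (0.0 <= self.deterioration_escalation_prob <= 1.0):
            raise ValueError("deterioration_escalation_prob must be in [0,1]")


def step_callout(
    state: CalloutState,
    daily_total: int,
    dnr_flag: bool,
    threshold: int,
    deteriorating: bool = False,
) -> tuple[CalloutState, tuple[CalloutAction, ...]]:
    """One daily transition of the callout state machine.

    ``deteriorating`` is the caller's judgement that an already-alerted
    patient kept worsening despite ward treatment (triggers ICU transfer).
    Calling on an absorbing state raises :class:`CalloutStateError`.
    """
    if daily_total < 0:
        raise ValueError(f"daily_total must be >= 0, got {daily_total}")
    if state in ABSORBING_STATES:
        raise CalloutStateError(f"no transitions out of absorbing state {state.value!r}")

    if state is CalloutState.MONITORING:
        if not is_warning(daily_total, threshold):
            return CalloutState.MONITORING, ()
        if dnr_flag:
            return CalloutState.TERMINATED_DNR, (CalloutAction.DNR_TERMINATION,)
        return CalloutState.ALERTED, ALERT_CASCADE

    # ALERTED / INITIAL_TREATMENT: continued ward treatment
    if deteriorating:
        return CalloutState.ICU_TRANSFERRED, (CalloutAction.ICU_TRANSFER,)
    return CalloutState.ALERTED, ()


def _per_day_hazard(p_admission: float, n_days: int) -> float:
    """Daily hazard h with 1-(1-h)^n_days == p_admission."""
    if n_days < 1:
        raise ValueError("need at least one at-risk day")
    return 1.0 - (1.0 - p_admission) ** (1.0 / n_days)


def simulate_study(
    cohort_params: CohortParams,
    hazard_model: Optional[HazardModel] = None,
    intervention: InterventionParams = InterventionParams(),
    intervention_on: bool = False,
    seed: Optional[int] = None,
    threshold: int = 7,
    table: Optional[ScoreTable] = None,
    label: Optional[str] = None,
) -> tuple[PeriodSummary, list[dict]]:
    """Generate a cohort and run daily scoring plus the callout machine.

    Each admission's vital observations are rescored day by day with the
    scoring module; the daily maxima drive the state machine.  The
    admission-level arrest probability of the maximum-score stratum is
    spread over the days spent at that stratum and, when the intervention
    is on, multiplied by ``intervention.theta`` from the first alert onward
    (DNR patients never receive the intervention).  ICU-transferred
    patients leave the ward at-risk pool.  Returns the period aggregate
    and a deterministic per-admission event log.
    """
    hazard_model = hazard_model or default_hazard_from_table2()
    table = table or load_score_table()
    if seed is None:
        seed = cohort_params.seed
    if seed is None:
        raise ValueError("a seed is required (argument or CohortParams.seed)")

    sim_children = np.random.SeedSequence((seed, 2)).spawn(cohort_params.n_admissions)
    log: list[dict] = []
    n_ihca = 0
    n_deaths = 0
    ages: list[float] = []
    n_male = 0
    diag_counts: dict[str, int] = {}

    for i, traj in enumerate(
        sample_trajectories(cohort_params, hazard_model, seed, table)
    ):
        rng = np.random.default_rng(sim_children[i])
        daily_totals = _rescored_daily_totals(traj, table)
        stratum = stratum_of(max(daily_totals))
        hazard_days = {
            d for d, t in enumerate(daily_totals) if stratum_of(t) == stratum
        }
        h = _per_day_hazard(hazard_model.ihca_probs[stratum], len(hazard_days))

        state = CalloutState.MONITORING
        alerted = False
        arrested = False
        for day, total in enumerate(daily_totals):
            if state not in ABSORBING_STATES:
                deteriorating = (
                    state is CalloutState.ALERTED
                    and rng.random() < intervention.deterioration_escalation_prob
                )
                state, actions = step_callout(
                    state, total, traj.dnr, threshold, deteriorating=deteriorating
                )
                for action in actions:
                    log.append(
                        {
                            "admission_id": traj.admission_id,
                            "day": day,
                            "daily_total": total,
                            "record": action.value,
                        }
                    )
                if CalloutAction.ALERT_RAISED in actions:
                    alerted = True
            if state is CalloutState.ICU_TRANSFERRED:
                break  # out of the ward at-risk pool
            if day in hazard_days:
                eff = h
                if intervention_on and alerted and not traj.dnr:
                    eff *= intervention.theta
                if rng.random() < eff:
                    arrested = True
                    state = CalloutState.ARRESTED
                    log.append(
                        {
                            "admission_id": traj.admission_id,
                            "day": day,
                            "daily_total": total,
                            "record": "ihca",
                        }
                    )
                    break
        if arrested:
            n_ihca += 1
        if rng.random() < hazard_model.death_prob:
            n_deaths += 1
            log.append(
                {
                    "admission_id": traj.admission_id,
                    "day": traj.los,
                    "daily_total": -1,
                    "record": "death",
                }
            )
        ages.append(traj.age)
        n_male += traj.sex == "M"
        diag_counts[traj.diagnosis] = diag_counts.get(traj.diagnosis, 0) + 1

    n = cohort_params.n_admissions
    top = sorted(diag_counts.items(), key=lambda kv: (-kv[1], kv[0]))[:5]
    arr = np.asarray(ages)
    summary = PeriodSummary(
        label=label or cohort_params.period_label,
        admissions=n,
        ihca=n_ihca,
        deaths=n_deaths,
        age_mean=float(arr.mean()),
        age_sd=float(arr.std(ddof=1)) if n > 1 else 0.0,
        male_fraction=n_male / n,
        top_diagnoses=tuple((d, c, 100.0 * c / n) for d, c in top),
    )
    return summary, log


def _rescored_daily_totals(traj: Trajectory, table: ScoreTable) -> list[int]:
    """Daily maximum totals recomputed from the trajectory's observations
    via the scoring module (round-trip with the generator)."""
    by_day: dict[int, list] = {}
    for obs in traj.observations:
        day = (obs.timestamp.date() - traj.admit_date.date()).days
        by_day.setdefault(day, []).append(obs)
    return [
        daily_max_mews(by_day[d], table).total for d in sorted(by_day)
    ]
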