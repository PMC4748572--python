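import numpy as np
import pandas as pd
import pytest

from mewskit.scoring import load_score_table
from mewskit.wz_analysis import stratify

#: Published audit counts: (score, n_patients, n_events); top bin pools >= 9.
AUDIT_COUNTS = ((6, 556, 1), (7, 289, 4), (8, 114, 2), (9, 56, 2))


@pytest.fixture(scope="session")
def default_table():
    return load_score_table()


def audit_scores_and_flags():
    """Patient-level max scores and event flags realizing the audit counts."""
    scores, flags = [], []
    for score, n, k in AUDIT_COUNTS:
        scores.extend([score] * n)
        flags.extend([True] * k + [False] * (n - k))
    return scores, flags


@pytest.fixture(scope="session")
def audit_strata():
    scores, flags = audit_scores_and_flags()
    return stratify(scores, flags, top_bin=9)


@pytest.fixture
def rng():
    return np.random.default_rng(20160209)


def make_admissions(rows):
    """Admissions table from (id, admit, discharge, age, sex, diagnosis, dnr,
    period) tuples."""
    return pd.DataFrame(
        rows,
        columns=[
            "admission_id", "admit_date", "discharge_date", "age", "sex",
            "diagnosis", "dnr", "period",
        ],
    ).assign(
        admit_date=lambda d: pd.to_datetime(d["admit_date"]),
        discharge_date=lambda d: pd.to_datetime(d["discharge_date"]),
    )


def make_events(rows):
    df = pd.DataFrame(rows, columns=["admission_id", "event_type", "event_date"])
    df["event_date"] = pd.to_datetime(df["event_date"])
    return df
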