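from datetime import datetime

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mewskit.scoring import (
    NUMERIC_PARAMETERS,
    PARAMETERS,
    PHYSIOLOGICAL_RANGES,
    Consciousness,
    ObservationError,
    ScoreTableError,
    VitalObservation,
    compute_mews,
    daily_max_mews,
    is_warning,
    load_score_table,
    score_parameter,
)

T0 = datetime(2014, 3, 1, 8, 0)


def obs(sbp=120.0, hr=75.0, rr=12.0, temp=36.8,
        consciousness=Consciousness.ALERT, concern=False,
        patient_id="p1", timestamp=T0):
    return VitalObservation(
        patient_id=patient_id, timestamp=timestamp, sbp=sbp, hr=hr, rr=rr,
        temp=temp, consciousness=consciousness, concern=concern,
    )


class TestLoadScoreTable:
    def test_default_max_total_is_15(self, default_table):
        assert default_table.max_total == 15

    def test_two_open_bands_rejected(self):
        bad = [{"upper": 70, "points": 3}, {"upper": None, "points": 2},
               {"upper": None, "points": 0}]
        with pytest.raises(ScoreTableError, match="sbp"):
            load_score_table({"sbp": bad})

    def test_concern_override_raises_max(self):
        table = load_score_table({"concern": {"no": 0, "yes": 2}})
        assert table.max_total == 16
        assert score_parameter(True, "concern", table) == 2

    def test_points_out_of_range_rejected(self):
        with pytest.raises(ScoreTableError):
            load_score_table({"rr": [{"upper": 10, "points": 4},
                                     {"upper": None, "points": 0}]})

    def test_non_increasing_uppers_rejected(self):
        with pytest.raises(ScoreTableError, match="hr"):
            load_score_table({"hr": [{"upper": 50, "points": 1},
                                     {"upper": 50, "points": 0},
                                     {"upper": None, "points": 3}]})

    def test_unknown_key_rejected(self):
        with pytest.raises(ScoreTableError, match="spo2"):
            load_score_table({"spo2": []})


class TestScoreParameter:
    @pytest.mark.parametrize(
        "value,parameter,expected",
        [
            (120, "sbp", 0),
            (65, "sbp", 3),
            (70, "sbp", 3),
            (71, "sbp", 2),
            (100, "sbp", 1),
            (101, "sbp", 0),
            (199, "sbp", 0),
            (200, "sbp", 2),
            (40, "hr", 2),
            (41, "hr", 1),
            (100, "hr", 0),
            (110, "hr", 1),
            (129, "hr", 2),
            (130, "hr", 3),
            (8, "rr", 2),
            (9, "rr", 0),
            (15, "rr", 1),
            (21, "rr", 2),
            (30, "rr", 3),
            (35.0, "temp", 2),
            (35.1, "temp", 0),
            (38.4, "temp", 0),
            (38.5, "temp", 2),
        ],
    )
    def test_numeric_bands(self, default_table, value, parameter, expected):
        assert score_parameter(value, parameter, default_table) == expected

    @pytest.mark.parametrize(
        "level,expected",
        [(Consciousness.ALERT, 0), (Consciousness.VOICE, 1),
         (Consciousness.PAIN, 2), (Consciousness.UNRESPONSIVE, 3)],
    )
    def test_consciousness(self, default_table, level, expected):
        assert score_parameter(level, "consciousness", default_table) == expected

    def test_concern(self, default_table):
        assert score_parameter(True, "concern", default_table) == 1
        assert score_parameter(False, "concern", default_table) == 0

    def test_rounding_half_up_to_granularity(self, default_table):
        # 0.1 degC granularity: 38.44 -> 38.4 (0 pts), 38.45 -> 38.5 (2 pts)
        assert score_parameter(38.44, "temp", default_table) == 0
        assert score_parameter(38.45, "temp", default_table) == 2
        # integer granularity: 70.4 -> 70 (3 pts), 70.5 -> 71 (2 pts)
        assert score_parameter(70.4, "sbp", default_table) == 3
        assert score_parameter(70.5, "sbp", default_table) == 2

    def test_out_of_range_names_bound(self, default_table):
        with pytest.raises(ObservationError, match=r"\[0.0, 400.0\]"):
            score_parameter(500, "sbp", default_table)

    def test_missing_zero_policy(self, default_table):
        assert score_parameter(None, "sbp", default_table) == 0

    def test_missing_strict_policy_raises(self):
        table = load_score_table({"missing_policy": "strict"})
        with pytest.raises(ObservationError, match="missing"):
            score_parameter(None, "hr", table)


class TestComputeMews:
    def test_rr16_totals_one(self, default_table):
        assert compute_mews(obs(rr=16), default_table).total == 1

    def test_all_normal_totals_zero(self, default_table):
        assert compute_mews(obs(rr=12), default_table).total == 0

    def test_worst_case_totals_15(self, default_table):
        worst = obs(sbp=65, hr=135, rr=32, temp=34.0,
                    consciousness=Consciousness.UNRESPONSIVE, concern=True)
        assert compute_mews(worst, default_table).total == 15

    def test_missing_parameters_recorded(self, default_table):
        res = compute_mews(obs(temp=None, concern=None), default_table)
        assert res.missing_parameters == ("temp", "concern")
        assert res.total == 0

    def test_all_missing_raises(self, default_table):
        empty = VitalObservation(patient_id="p1", timestamp=T0)
        with pytest.raises(ObservationError, match="no score computable"):
            compute_mews(empty, default_table)

    def test_additivity(self, default_table):
        o = obs(sbp=85, hr=112, rr=22, temp=38.9,
                consciousness=Consciousness.PAIN, concern=True)
        res = compute_mews(o, default_table)
        parts = [score_parameter(getattr(o, p), p, default_table) for p in PARAMETERS]
        assert res.total == sum(parts) == sum(res.points.values())

    def test_observation_range_validation(self):
        with pytest.raises(ObservationError):
            obs(hr=400)


class TestDailyMax:
    def test_singleton(self, default_table):
        res = daily_max_mews([obs(rr=16)], default_table)
        assert res.total == 1

    def test_picks_maximum(self, default_table):
        group = [
            obs(rr=22, hr=105, timestamp=T0),                       # 3
            obs(sbp=65, hr=135, rr=16, timestamp=T0.replace(hour=12)),  # 7
            obs(rr=22, timestamp=T0.replace(hour=16)),              # 2
        ]
        assert daily_max_mews(group, default_table).total == 7

    def test_tie_breaks_to_earliest(self, default_table):
        early = obs(rr=22, hr=112, concern=True, timestamp=T0)          # 5
        late = obs(sbp=75, rr=30, timestamp=T0.replace(hour=20))        # 5
        res = daily_max_mews([late, early], default_table)
        assert res.total == 5
        assert res.timestamp == T0

    def test_empty_raises(self, default_table):
        with pytest.raises(ObservationError):
            daily_max_mews([], default_table)

    def test_mixed_patients_raise(self, default_table):
        with pytest.raises(ObservationError, match="patients"):
            daily_max_mews([obs(), obs(patient_id="p2")], default_table)

    def test_mixed_days_raise(self, default_table):
        with pytest.raises(ObservationError, match="days"):
            daily_max_mews(
                [obs(), obs(timestamp=datetime(2014, 3, 2, 8))], default_table
            )


class TestIsWarning:
    @pytest.mark.parametrize("total,threshold,expected",
                             [(7, 7, True), (6, 7, False), (0, 7, False),
                              (15, 7, True)])
    def test_examples(self, total, threshold, expected):
        assert is_warning(total, threshold) is expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            is_warning(-1, 7)
        with pytest.raises(ValueError):
            is_warning(3, 0)


class TestProperties:
    def test_band_partition_dense_grid(self, default_table):
        """Every on-grid value in the physiological range scores exactly once."""
        for name in NUMERIC_PARAMETERS:
            lo, hi = PHYSIOLOGICAL_RANGES[name]
            g = default_table.granularity[name]
            n = int(round((hi - lo) / g))
            for k in range(n + 1):
                value = round((lo + k * g) / g) * g if g < 1 else lo + k * g
                pts = score_parameter(value, name, default_table)
                assert 0 <= pts <= 3

    @given(
        sbp=st.floats(0, 400),
        hr=st.floats(0, 350),
        rr=st.floats(0, 100),
        temp=st.floats(20, 45),
        consciousness=st.sampled_from(list(Consciousness)),
        concern=st.booleans(),
    )
    @settings(max_examples=200, deadline=None)
    def test_bounded_and_additive(self, default_table, sbp, hr, rr, temp,
                                  consciousness, concern):
        o = obs(sbp=sbp, hr=hr, rr=rr, temp=temp,
                consciousness=consciousness, concern=concern)
        res = compute_mews(o, default_table)
        assert 0 <= res.total <= default_table.max_total
        assert res.total == sum(res.points.values())

    def test_monotone_under_single_parameter_worsening(self, default_table):
        """Moving one parameter to a higher-point band never lowers the total."""
        base = obs(sbp=120, hr=75, rr=12, temp=36.8)
        base_total = compute_mews(base, default_table).total
        worse_values = {"sbp": 65, "hr": 135, "rr": 32, "temp": 34.0}
        for name, value in worse_values.items():
            worse = obs(**{**dict(sbp=120, hr=75, rr=12, temp=36.8), name: value})
            assert compute_mews(worse, default_table).total >= base_total
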