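"""Cohort statistics: distributions, sensitivity, lead times, tests,
attribution and group segmentation, each checked against an independent
oracle (hand computation, exhaustive enumeration, or a sorting oracle)."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mprtws import (
    EvaluationError,
    Level,
    PatientOutcome,
    attribution,
    compare_distributions,
    compare_identified,
    lead_times,
    level_distribution,
    round_percent,
    segment_by_group,
    sensitivity,
)

L, M, H, U = Level.LOW, Level.MEDIUM, Level.HIGH, Level.URGENT
LMH = [L, M, H]


# ---------------------------------------------------------------------------
# distributions and rounding
# ---------------------------------------------------------------------------


def test_low_share_from_event_counts():
    dist = level_distribution({L: 85_247, M: 5_924, H: 624}, LMH)
    assert dist[L] == (85_247, 92.9)


def test_high_share_from_event_counts():
    dist = level_distribution({L: 108_782, M: 7_158, H: 1_491}, LMH)
    assert dist[H] == (1_491, 1.3)


def test_single_level_is_hundred_percent():
    dist = level_distribution({L: 10}, [L])
    assert dist[L] == (10, 100.0)


def test_empty_cohort_distribution_rejected():
    with pytest.raises(EvaluationError):
        level_distribution({L: 0, M: 0}, LMH)


def test_percentages_round_half_up():
    assert round_percent(0.125) == 12.5
    assert round_percent(0.06445) == 6.4   # 6.445 → 6.4 (below the half)
    assert round_percent(0.06455) == 6.5
    assert round_percent(0.0645) == 6.5    # exactly half rounds up
    assert round_percent(23 / 39, 0) == 59.0


@given(st.dictionaries(st.sampled_from(LMH), st.integers(1, 10**6),
                       min_size=3, max_size=3))
def test_shares_sum_to_about_hundred(counts):
    dist = level_distribution(counts, LMH)
    assert sum(pct for _, pct in dist.values()) == pytest.approx(100, abs=0.2)


# ---------------------------------------------------------------------------
# sensitivity
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "identified,total,expected",
    [(23, 39, 0.5897), (4, 39, 0.1026), (0, 17, 0.0)],
)
def test_sensitivity_fraction(identified, total, expected):
    assert sensitivity(identified, total) == pytest.approx(expected, abs=1e-4)


def test_sensitivity_input_validation():
    with pytest.raises(EvaluationError):
        sensitivity(1, 0)
    with pytest.raises(EvaluationError):
        sensitivity(5, 3)


@given(st.integers(1, 100), st.data())
def test_sensitivity_monotone_in_identified(n, data):
    a = data.draw(st.integers(0, n - 1))
    assert sensitivity(a, n) <= sensitivity(a + 1, n)


# ---------------------------------------------------------------------------
# lead times
# ---------------------------------------------------------------------------


def _outcomes(**times):
    return {
        p: PatientOutcome(p, t is not None, t) for p, t in times.items()
    }


def test_alert_at_deterioration_time_is_not_identified():
    out = lead_times({"a": 480.0}, _outcomes(a=480.0))
    assert out.n_identified == 0 and out.mean is None


def test_two_patient_lead_mean_and_sd():
    # leads 10 h and 30 h → mean 20, sample SD 14.142
    out = lead_times(
        {"a": 0.0, "b": 0.0}, _outcomes(a=600.0, b=1800.0)
    )
    assert out.mean == pytest.approx(20.0)
    assert out.sd == pytest.approx(math.sqrt(200), abs=1e-3)


def test_single_identified_patient_has_undefined_sd():
    out = lead_times({"a": 0.0}, _outcomes(a=600.0))
    assert out.n_identified == 1
    assert out.mean == pytest.approx(10.0)
    assert out.sd is None


def test_unalerted_and_stable_patients_ignored():
    out = lead_times(
        {"a": None, "b": 100.0, "c": 50.0},
        {**_outcomes(a=600.0, b=600.0), "c": PatientOutcome("c", False)},
    )
    assert set(out.leads) == {"b"}


def test_lead_times_invariant_to_global_time_shift():
    alerts = {"a": 120.0, "b": 300.0}
    outcomes = _outcomes(a=720.0, b=1500.0)
    shifted_alerts = {p: t + 1000.0 for p, t in alerts.items()}
    shifted_outcomes = _outcomes(a=1720.0, b=2500.0)
    base = lead_times(alerts, outcomes)
    moved = lead_times(shifted_alerts, shifted_outcomes)
    assert base.leads == moved.leads


# ---------------------------------------------------------------------------
# comparison tests vs. oracles
# ---------------------------------------------------------------------------


def test_identical_distributions_give_zero_statistic():
    counts = {L: 10, M: 10, H: 10}
    stat, p = compare_distributions(counts, counts)
    assert stat == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_chi2_hand_computed_2x2():
    # [[20,10],[10,20]]: all expected 15, stat = 4 * 25/15 = 20/3
    stat, _ = compare_distributions({L: 20, M: 10}, {L: 10, M: 20})
    assert stat == pytest.approx(20 / 3, rel=1e-12)


def test_chi2_matches_direct_summation_on_random_tables():
    rng = np.random.default_rng(11)
    for _ in range(50):
        a = rng.integers(1, 500, size=3)
        b = rng.integers(1, 500, size=3)
        counts_a = dict(zip(LMH, map(int, a)))
        counts_b = dict(zip(LMH, map(int, b)))
        stat, _ = compare_distributions(counts_a, counts_b)
        observed = np.array([a, b], dtype=float)
        expected = (
            observed.sum(axis=1, keepdims=True)
            * observed.sum(axis=0, keepdims=True)
            / observed.sum()
        )
        direct = ((observed - expected) ** 2 / expected).sum()
        assert stat == pytest.approx(direct, rel=1e-10)


def test_mismatched_level_sets_rejected():
    with pytest.raises(EvaluationError):
        compare_distributions({L: 5, M: 5}, {L: 5, M: 5, H: 5})


def test_fisher_equal_counts_give_p_one():
    assert compare_identified(10, 10, 39) == pytest.approx(1.0)


def test_fisher_three_vs_zero_of_three():
    # table [[3,0],[0,3]]: exact two-sided p = 2/20
    assert compare_identified(3, 0, 3) == pytest.approx(0.1, rel=1e-9)


def test_fisher_degenerate_margin_gives_p_one():
    assert compare_identified(0, 0, 7) == pytest.approx(1.0)


def test_fisher_count_validation():
    with pytest.raises(EvaluationError):
        compare_identified(-1, 0, 5)
    with pytest.raises(EvaluationError):
        compare_identified(6, 0, 5)


# ---------------------------------------------------------------------------
# attribution
# ---------------------------------------------------------------------------


def _frame(rows):
    """rows: list of (confirmed_level, {param: score})"""
    records = []
    for i, (level, scores) in enumerate(rows):
        record = {"timestamp": 5.0 * i, "confirmed_mprt": int(level)}
        for p in ("hr", "spo2", "rr", "sbp", "dbp", "temp", "sv", "co", "svr"):
            record[f"{p}_score"] = float(scores.get(p, 0))
        records.append(record)
    frame = pd.DataFrame(records)
    frame["confirmed_mprt"] = frame["confirmed_mprt"].astype("Int64")
    return frame


def test_single_urgent_reading_attributes_to_its_driver():
    frames = {"p": _frame([(U, {"spo2": 3})])}
    result = attribution(frames, U)
    assert result["spo2"] == 1.0
    assert all(v == 0.0 for k, v in result.items() if k != "spo2")


def test_attribution_counts_fraction_of_readings():
    frames = {"p": _frame([(H, {"sbp": 2, "dbp": 2, "svr": 2}),
                           (H, {"dbp": 2, "svr": 2, "hr": 2})])}
    result = attribution(frames, H)
    assert result["sbp"] == 0.5
    assert result["dbp"] == 1.0


def test_attribution_on_absent_level_warns_and_returns_empty():
    frames = {"p": _frame([(L, {})])}
    with pytest.warns(UserWarning, match="URGENT"):
        assert attribution(frames, U) == {}


# ---------------------------------------------------------------------------
# group segmentation
# ---------------------------------------------------------------------------


def test_single_patient_group_summary_equals_its_counts():
    frames = {"p": _frame([(H, {"sbp": 2, "dbp": 2, "svr": 2}),
                           (U, {"sbp": 3, "dbp": 2, "svr": 2})])}
    result = segment_by_group(frames, {"p": "CKD"})
    sbp = result["CKD"]["sbp"]
    assert sbp.n_patients == 1
    assert sbp.total == 2
    assert sbp.median == 2.0 and sbp.q1 == 2.0 and sbp.q3 == 2.0


def test_identical_patients_have_zero_iqr():
    frame = _frame([(H, {"sbp": 2, "dbp": 2, "svr": 2})])
    result = segment_by_group({"a": frame, "b": frame.copy()}, {"a": "g", "b": "g"})
    summary = result["g"]["sbp"]
    assert summary.q3 - summary.q1 == 0.0
    assert summary.outliers == ()


def test_five_patient_quartiles_match_order_statistics():
    counts = [0, 1, 2, 3, 10]
    frames = {}
    groups = {}
    for i, c in enumerate(counts):
        rows = [(H, {"sbp": 2, "dbp": 2, "svr": 2})] * c
        frames[f"p{i}"] = _frame(rows) if rows else _frame([(L, {})])
        groups[f"p{i}"] = "g"
    result = segment_by_group(frames, groups)
    summary = result["g"]["sbp"]
    q1, med, q3 = np.percentile(np.array(counts, dtype=float), [25, 50, 75])
    assert (summary.q1, summary.median, summary.q3) == (q1, med, q3)
    iqr = q3 - q1
    assert summary.outliers == tuple(
        float(c) for c in counts if c < q1 - 1.5 * iqr or c > q3 + 1.5 * iqr
    )


def test_unlabelled_patient_rejected():
    frames = {"p": _frame([(L, {})])}
    with pytest.raises(EvaluationError, match="p"):
        segment_by_group(frames, {})
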