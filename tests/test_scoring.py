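"""Band scoring and instantaneous level aggregation for both tools."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mprtws import (
    MPRT_PARAMETERS,
    Level,
    VitalReading,
    mprt_instant_level,
    news_level,
    score_parameter,
    score_stream,
    stream_from_readings,
)

scores9 = st.lists(
    st.one_of(st.none(), st.integers(0, 3)), min_size=9, max_size=9
)


# ---------------------------------------------------------------------------
# score_parameter
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "value,expected",
    [
        (70, 0),
        (130, 3),       # half-open boundary belongs to the upper band
        (109.999, 1),
        (110, 2),
        (39.999, 3),
        (40, 1),
    ],
)
def test_score_parameter_toy_table(toy_bands, value, expected):
    assert score_parameter(value, toy_bands) == expected


def test_missing_value_scores_missing(toy_bands):
    assert score_parameter(None, toy_bands) is None
    assert score_parameter(math.nan, toy_bands) is None


def test_nonfinite_value_rejected(toy_bands):
    with pytest.raises(ValueError):
        score_parameter(math.inf, toy_bands)


@given(st.floats(-1e6, 1e6, allow_nan=False))
def test_every_finite_value_gets_a_score(toy_bands, value):
    assert score_parameter(value, toy_bands) in (0, 1, 2, 3)


# ---------------------------------------------------------------------------
# level aggregation
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "scores,expected",
    [
        ([0] * 9, Level.LOW),
        ([1] * 9, Level.LOW),                       # 1-scores never escalate
        ([2, 0, 0, 0, 0, 0, 0, 0, 0], Level.LOW),   # one 2 stays Low
        ([2, 2, 1, 0, 0, 0, 0, 0, 0], Level.MEDIUM),
        ([2, 2, 2, 1, 0, 0, 0, 0, 0], Level.HIGH),
        ([2] * 9, Level.HIGH),
        ([0, 0, 0, 0, 0, 0, 0, 0, 3], Level.URGENT),
        ([None] * 9, Level.LOW),                    # missing counts as 0
        ([2, 2, None, None, None, 0, 0, 0, 0], Level.MEDIUM),
    ],
)
def test_mprt_level_definitions(scores, expected):
    assert mprt_instant_level(scores) == expected


def test_mprt_level_rejects_out_of_range():
    with pytest.raises(ValueError):
        mprt_instant_level([4] + [0] * 8)


@given(scores9)
def test_any_three_dominates(scores):
    if any(s == 3 for s in scores if s is not None):
        assert mprt_instant_level(scores) == Level.URGENT


@given(scores9, st.data())
def test_raising_one_score_never_lowers_level(scores, data):
    base = mprt_instant_level(scores)
    i = data.draw(st.integers(0, 8))
    raised = list(scores)
    current = raised[i] if raised[i] is not None else 0
    raised[i] = data.draw(st.integers(current, 3))
    assert mprt_instant_level(raised) >= base


@given(scores9, st.randoms(use_true_random=False))
def test_level_is_permutation_invariant(scores, rnd):
    shuffled = list(scores)
    rnd.shuffle(shuffled)
    assert mprt_instant_level(shuffled) == mprt_instant_level(scores)


@pytest.mark.parametrize(
    "scores,expected_level,expected_total",
    [
        ([0, 0, 0, 0, 0], Level.LOW, 0),
        ([3, 0, 0, 0, 0], Level.HIGH, 3),   # single Red score
        ([2, 2, 2, 1, 0], Level.HIGH, 7),   # total 7+
        ([2, 2, 1, 0, 0], Level.MEDIUM, 5),
        ([2, 2, 0, 0, 0], Level.LOW, 4),
        ([2, None, 2, 1, None], Level.MEDIUM, 5),
    ],
)
def test_news_level_rules(scores, expected_level, expected_total):
    level, total = news_level(scores)
    assert (level, total) == (expected_level, expected_total)


@settings(max_examples=200)
@given(st.lists(st.integers(0, 3), min_size=5, max_size=5))
def test_news_total_is_the_sum(scores):
    _, total = news_level(scores)
    assert total == sum(scores)


# ---------------------------------------------------------------------------
# score_stream
# ---------------------------------------------------------------------------


def _reading(t, **overrides):
    values = dict(hr=72, spo2=97.5, rr=15, sbp=123, dbp=74, temp=36.8,
                  sv=81, co=5.4, svr=1012)
    values.update(overrides)
    return VitalReading("p1", t, **values)


def test_empty_stream_scores_empty(mprt_table, news_table):
    stream = stream_from_readings([])
    scored = score_stream(stream, mprt_table, news_table)
    assert len(scored) == 0


def test_all_normal_stream_is_all_low(mprt_table, news_table):
    stream = stream_from_readings([_reading(5.0 * i) for i in range(10)])
    scored = score_stream(stream, mprt_table, news_table)
    assert (scored["instant_mprt"] == int(Level.LOW)).all()
    assert (scored["instant_news"] == int(Level.LOW)).all()
    assert (scored["news_total"] == 0).all()


def test_nine_two_band_values_give_high(mprt_table, news_table):
    """Composition check: per-parameter 2-band values → instant High."""
    # one value inside a 2-band of each parameter of the default table
    in_two_band = dict(hr=120, spo2=92.5, rr=22, sbp=95, dbp=115,
                       temp=36.8, sv=130, co=11, svr=1800)
    stream = stream_from_readings(
        [_reading(0.0), _reading(5.0, **in_two_band)]
    )
    scored = score_stream(stream, mprt_table, news_table)
    for name, value in in_two_band.items():
        if name == "temp":
            continue
        assert scored.loc[1, f"{name}_score"] == 2, name
    assert scored.loc[1, "instant_mprt"] == int(Level.HIGH)
    assert scored.loc[0, "instant_mprt"] == int(Level.LOW)


def test_scores_match_scalar_path(mprt_table, news_table):
    """Vectorised stream scoring agrees with scalar score_parameter."""
    rng = np.random.default_rng(42)
    rows = []
    for i in range(50):
        values = {
            "hr": rng.uniform(20, 200),
            "spo2": rng.uniform(80, 100),
            "rr": rng.uniform(4, 40),
            "sbp": rng.uniform(60, 260),
            "dbp": rng.uniform(30, 140),
            "temp": rng.uniform(34, 41),
            "sv": rng.uniform(20, 160),
            "co": rng.uniform(1, 14),
            "svr": rng.uniform(300, 2500),
        }
        rows.append(VitalReading("p1", 5.0 * i, **values))
    stream = stream_from_readings(rows)
    scored = score_stream(stream, mprt_table, news_table)
    for i, reading in enumerate(rows):
        for name in MPRT_PARAMETERS:
            expected = score_parameter(
                getattr(reading, name), mprt_table.bands[name]
            )
            assert scored.loc[i, f"{name}_score"] == expected, (i, name)
        expected_level = mprt_instant_level(
            [
                score_parameter(getattr(reading, name), mprt_table.bands[name])
                for name in MPRT_PARAMETERS
            ]
        )
        assert scored.loc[i, "instant_mprt"] == int(expected_level)


def test_too_many_missing_parameters_is_unscorable(mprt_table, news_table):
    stream = stream_from_readings(
        [
            _reading(0.0),
            VitalReading("p1", 5.0, hr=72, spo2=97.5),  # 7 missing
        ]
    )
    scored = score_stream(stream, mprt_table, news_table)
    assert bool(scored.loc[0, "scorable"])
    assert not bool(scored.loc[1, "scorable"])
    assert pd.isna(scored.loc[1, "instant_mprt"])
    assert scored.loc[1, "n_missing"] == 7


def test_unordered_stream_rejected(mprt_table, news_table):
    stream = stream_from_readings([_reading(10.0), _reading(0.0)])
    stream = stream.iloc[::1]  # keep as-is: timestamps decrease
    with pytest.raises(ValueError, match="time-ordered"):
        score_stream(stream, mprt_table, news_table)
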