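"""Development-cohort reference counts and the arithmetic checks over them.

The warning score was developed on a hospital cohort of 361 high-risk general
ward patients (plus 160 healthy controls) monitored at 5-min cadence for up to
72 h; its published summary statistics are simple arithmetic over per-reading
event counts and per-patient identification counts.  Those printed counts are
stored here as data, and :func:`reference_statistics` recomputes every summary
from them through the package's own evaluation functions — a desk-scale
consistency check that the reporting conventions implemented here reproduce
the published numbers.
"""

from __future__ import annotations

from .evaluation import level_distribution, round_percent, sensitivity
from .scoring import Level

#: per-reading confirmed event counts in the development cohort (n=361)
REFERENCE_COUNTS = {
    "MPRT-WS": {Level.LOW: 85_247, Level.MEDIUM: 5_924, Level.HIGH: 624},
    "NEWS": {Level.LOW: 108_782, Level.MEDIUM: 7_158, Level.HIGH: 1_491},
    "temporal-NEWS": {Level.LOW: 111_931, Level.MEDIUM: 4_755, Level.HIGH: 744},
    "MPRT-WS-15min": {Level.LOW: 88_977, Level.MEDIUM: 5_467, Level.HIGH: 521},
}

#: Urgent readings and the grand total they are quoted against
REFERENCE_URGENT = {"count": 25_635, "total_readings": 117_431}

#: deteriorating patients and how many each tool identified in advance
REFERENCE_IDENTIFIED = {
    "n_deteriorated": 39,
    "MPRT-WS": 23,
    "NEWS": 4,
    "MPRT-WS-15min": 22,
}

_LMH = [Level.LOW, Level.MEDIUM, Level.HIGH]


def _share(tool: str, level: Level, digits: int = 1) -> float:
    dist = level_distribution(REFERENCE_COUNTS[tool], _LMH)
    return dist[level][1] if digits == 1 else round_percent(
        REFERENCE_COUNTS[tool][level]
        / sum(REFERENCE_COUNTS[tool][lv] for lv in _LMH),
        digits,
    )


def reference_statistics() -> dict[str, dict[str, float | int]]:
    """Recompute every published development-cohort summary from its counts.

    Returns ``{name: {"value": ..., "n": ...}}`` with values on the printed
    scale (percent, rounded to the printed precision).
    """
    n_det = REFERENCE_IDENTIFIED["n_deteriorated"]
    stats: dict[str, dict[str, float | int]] = {}

    stats["sensitivity_mprtws_pct"] = {
        "value": round_percent(
            sensitivity(REFERENCE_IDENTIFIED["MPRT-WS"], n_det), 0
        ),
        "n": n_det,
    }
    stats["sensitivity_news_pct"] = {
        "value": round_percent(sensitivity(REFERENCE_IDENTIFIED["NEWS"], n_det), 0),
        "n": n_det,
    }
    stats["sensitivity_mprtws_15min_pct"] = {
        "value": round_percent(
            sensitivity(REFERENCE_IDENTIFIED["MPRT-WS-15min"], n_det), 1
        ),
        "n": n_det,
    }

    mprt_total = sum(REFERENCE_COUNTS["MPRT-WS"][lv] for lv in _LMH)
    stats["share_mprtws_low_pct"] = {
        "value": _share("MPRT-WS", Level.LOW),
        "n": mprt_total,
    }
    stats["share_mprtws_high_pct"] = {
        "value": _share("MPRT-WS", Level.HIGH),
        "n": mprt_total,
    }
    news_total = sum(REFERENCE_COUNTS["NEWS"][lv] for lv in _LMH)
    stats["share_news_high_pct"] = {
        "value": _share("NEWS", Level.HIGH),
        "n": news_total,
    }
    tnews_total = sum(REFERENCE_COUNTS["temporal-NEWS"][lv] for lv in _LMH)
    stats["share_temporal_news_low_pct"] = {
        "value": _share("temporal-NEWS", Level.LOW),
        "n": tnews_total,
    }
    stats["share_urgent_pct"] = {
        "value": round_percent(
            REFERENCE_URGENT["count"] / REFERENCE_URGENT["total_readings"]
        ),
        "n": REFERENCE_URGENT["total_readings"],
    }
    m15_total = sum(REFERENCE_COUNTS["MPRT-WS-15min"][lv] for lv in _LMH)
    stats["share_mprtws_15min_low_pct"] = {
        "value": _share("MPRT-WS-15min", Level.LOW),
        "n": m15_total,
    }
    return stats


#: the published values each statistic should reproduce
REFERENCE_EXPECTED = {
    "sensitivity_mprtws_pct": 59.0,
    "sensitivity_news_pct": 10.0,
    "sensitivity_mprtws_15min_pct": 56.4,
    "share_mprtws_low_pct": 92.9,
    "share_mprtws_high_pct": 0.7,
    "share_news_high_pct": 1.3,
    "share_temporal_news_low_pct": 95.3,
    "share_urgent_pct": 21.8,
    "share_mprtws_15min_low_pct": 93.7,
}
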