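"""Per-parameter band scoring and instantaneous risk-level aggregation.

Two tools are scored side by side on each reading:

* **MPRT-WS** — nine parameters each scored 0–3, aggregated into four alert
  levels: Urgent if any parameter scores 3; otherwise High with three or more
  parameters at score ≥ 2, Medium with exactly two, Low with at most one.
* **NEWS** — the five classic vitals scored 0–3 and summed; High if the total
  reaches 7 or any single parameter scores 3 (the "Red score" rule), Medium for
  totals in the configured aggregate band (default 5–6), otherwise Low.

Missing parameters score 0 for aggregation but are counted; a reading with
more than ``max_missing`` absent parameters is unscorable and carries no
level.
"""

from __future__ import annotations

import enum
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    MPRT_PARAMETERS,
    NEWS_PARAMETERS,
    ScoreBand,
    ScoreBandTable,
)

#: default tolerance for sensor dropout: readings missing more than this many
#: parameters are excluded from levels and event counts
DEFAULT_MAX_MISSING = 3


class Level(enum.IntEnum):
    """Alert levels, ordered LOW < MEDIUM < HIGH < URGENT.

    NEWS uses only the first three; URGENT is specific to MPRT-WS and marks a
    deterioration judged to be happening now rather than merely at risk.
    """

    LOW = 0
    MEDIUM = 1
    HIGH = 2
    URGENT = 3

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


def score_parameter(value: float | None, bands: Sequence[ScoreBand]) -> int | None:
    """Score one raw value against one parameter's ordered band list.

    Returns the score of the unique half-open band containing ``value``, or
    ``None`` for a missing value.
    """
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if not math.isfinite(value):
        raise ValueError(f"cannot score non-finite value {value!r}")
    for band in bands:
        if band.contains(value):
            return band.score
    raise ValueError(f"no band contains {value!r}; table is invalid")


def mprt_instant_level(scores: Iterable[int | None]) -> Level:
    """Aggregate nine per-parameter scores into the MPRT-WS level.

    Missing scores count as 0.  Any score of 3 forces URGENT; else the count
    of scores ≥ 2 decides: ≥3 → HIGH, exactly 2 → MEDIUM, otherwise LOW
    (1-scores never escalate the level).
    """
    present = [s for s in scores if s is not None]
    if any(s not in (0, 1, 2, 3) for s in present):
        raise ValueError("scores must be in 0..3 or missing")
    if any(s == 3 for s in present):
        return Level.URGENT
    n_concern = sum(1 for s in present if s >= 2)
    if n_concern >= 3:
        return Level.HIGH
    if n_concern == 2:
        return Level.MEDIUM
    return Level.LOW


def news_level(
    scores: Iterable[int | None], aggregate_medium: tuple[int, int] = (5, 6)
) -> tuple[Level, int]:
    """Aggregate the five NEWS parameter scores into (level, total).

    HIGH on a total of 7+ or any single "Red score" (parameter at 3); MEDIUM
    for totals inside ``aggregate_medium`` (inclusive); else LOW.
    """
    present = [s for s in scores if s is not None]
    if any(s not in (0, 1, 2, 3) for s in present):
        raise ValueError("scores must be in 0..3 or missing")
    total = sum(present)
    if total >= 7 or any(s == 3 for s in present):
        return Level.HIGH, total
    low, high = aggregate_medium
    if low <= total <= high:
        return Level.MEDIUM, total
    return Level.LOW, total


def _vector_scores(
    stream: pd.DataFrame, table: ScoreBandTable, parameters: Sequence[str]
) -> pd.DataFrame:
    """Vectorised band lookup: np.searchsorted over the interior band edges."""
    out = {}
    for name in parameters:
        cut, per_cell = table.edges(name)
        values = stream[name].to_numpy(dtype=float)
        cells = np.searchsorted(cut, values, side="right")
        scored = per_cell[np.clip(cells, 0, len(per_cell) - 1)]
        scored[np.isnan(values)] = np.nan
        out[name] = scored
    return pd.DataFrame(out, index=stream.index)


def score_stream(
    stream: pd.DataFrame,
    mprt_table: ScoreBandTable,
    news_table: ScoreBandTable,
    max_missing: int = DEFAULT_MAX_MISSING,
) -> pd.DataFrame:
    """Score every reading of one patient stream under both tools.

    Returns a frame aligned with ``stream`` carrying ``<param>_score`` columns
    (float; NaN = missing), ``n_missing``, ``scorable`` (False when more than
    ``max_missing`` parameters are absent), ``news_total``, and the
    instantaneous levels ``instant_mprt`` / ``instant_news`` (NaN-levels are
    represented by ``pd.NA`` for unscorable readings).
    """
    if not stream["timestamp"].is_monotonic_increasing:
        raise ValueError("stream must be time-ordered")
    mprt_scores = _vector_scores(stream, mprt_table, MPRT_PARAMETERS)
    news_scores = _vector_scores(stream, news_table, NEWS_PARAMETERS)

    out = pd.DataFrame(index=stream.index)
    if "patient_id" in stream.columns:
        out["patient_id"] = stream["patient_id"]
    out["timestamp"] = stream["timestamp"].astype(float)
    for name in MPRT_PARAMETERS:
        out[f"{name}_score"] = mprt_scores[name]
    n_missing = mprt_scores.isna().sum(axis=1)
    out["n_missing"] = n_missing.astype(int)
    out["scorable"] = n_missing <= max_missing

    filled = mprt_scores.fillna(0.0)
    any3 = (filled == 3).any(axis=1)
    n_concern = (filled >= 2).sum(axis=1)
    instant = np.select(
        [any3, n_concern >= 3, n_concern == 2],
        [int(Level.URGENT), int(Level.HIGH), int(Level.MEDIUM)],
        default=int(Level.LOW),
    )

    news_filled = news_scores.fillna(0.0)
    total = news_filled.sum(axis=1).astype(int)
    news_any3 = (news_scores == 3).any(axis=1)
    lo, hi = news_table.aggregate_medium
    news_instant = np.select(
        [(total >= 7) | news_any3, (total >= lo) & (total <= hi)],
        [int(Level.HIGH), int(Level.MEDIUM)],
        default=int(Level.LOW),
    )
    out["news_total"] = total
    scorable = out["scorable"].to_numpy()
    out["instant_mprt"] = pd.array(
        np.where(scorable, instant, -1), dtype="Int64"
    )
    out["instant_news"] = pd.array(
        np.where(scorable, news_instant, -1), dtype="Int64"
    )
    out.loc[~out["scorable"], ["instant_mprt", "instant_news"]] = pd.NA
    return out


def score_cohort(
    streams: Mapping[str, pd.DataFrame],
    mprt_table: ScoreBandTable,
    news_table: ScoreBandTable,
    max_missing: int = DEFAULT_MAX_MISSING,
) -> dict[str, pd.DataFrame]:
    """Apply :func:`score_stream` per patient, preserving stream order."""
    return {
        patient: score_stream(stream, mprt_table, news_table, max_missing)
        for patient, stream in streams.items()
    }
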