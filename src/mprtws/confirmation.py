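"""Temporal confirmation of instantaneous alert levels.

A single abnormal reading in a 5-min stream may be a motion artifact or a
sensing glitch, so levels above Low only count once they persist: a level is
*confirmed* at a reading when the last ``min_consecutive`` readings (that one
included) all reached at least that level and their timestamps span at most
``max_span`` minutes.  Equivalently, the confirmed level at a reading is the
minimum instantaneous level over that trailing window — Low when the window is
incomplete (start of stream), broken by an unscorable reading, or stretched
over a transmission gap longer than ``max_span``.

The default policy — two consecutive readings within 10 minutes — matches the
native 5-min cadence.  For coarser resampled cadences,
:meth:`ConfirmationPolicy.for_interval` keeps the rule at "two consecutive
readings" by widening the span to ``min_consecutive × interval``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .scoring import Level

#: levels whose first confirmed occurrence counts as "identifying" a
#: deteriorating patient, per tool
DEFAULT_ALERT_LEVELS = {
    "MPRT-WS": frozenset({Level.HIGH, Level.URGENT}),
    "NEWS": frozenset({Level.HIGH}),
}


@dataclass(frozen=True)
class ConfirmationPolicy:
    """Persistence rule: ``min_consecutive`` readings within ``max_span`` min.

    ``confirm_urgent=False`` lets URGENT bypass confirmation for real-time
    use; the default applies the rule uniformly to every level.
    """

    min_consecutive: int = 2
    max_span: float = 10.0
    confirm_urgent: bool = True

    def __post_init__(self) -> None:
        if self.min_consecutive < 1:
            raise ValueError("min_consecutive must be >= 1")
        if not self.max_span > 0:
            raise ValueError("max_span must be positive")

    @classmethod
    def for_interval(cls, interval: float, min_consecutive: int = 2,
                     confirm_urgent: bool = True) -> "ConfirmationPolicy":
        """Policy for a resampled cadence: span = min_consecutive × interval."""
        return cls(min_consecutive=min_consecutive,
                   max_span=min_consecutive * interval,
                   confirm_urgent=confirm_urgent)


@dataclass(frozen=True)
class ConfirmedStream:
    """Confirmed levels for one stream plus per-level event counts.

    An *event* is one confirmed reading at a level (episodes are not merged).
    ``levels[i]`` is ``None`` for unscorable readings; those are excluded from
    the counts.
    """

    timestamps: tuple[float, ...]
    instant: tuple[Level | None, ...]
    levels: tuple[Level | None, ...]
    counts: Mapping[Level, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.levels)


def _confirm_codes(
    codes: np.ndarray, timestamps: np.ndarray, policy: ConfirmationPolicy
) -> np.ndarray:
    """Core rule on integer level codes (-1 = unscorable)."""
    n = len(codes)
    out = np.full(n, -1, dtype=int)
    k = policy.min_consecutive
    for i in range(n):
        if codes[i] < 0:
            continue
        if policy.confirm_urgent is False and codes[i] == int(Level.URGENT):
            out[i] = codes[i]
            continue
        j = i - k + 1
        if j < 0:
            out[i] = int(Level.LOW)
            continue
        window = codes[j : i + 1]
        if (window < 0).any() or timestamps[i] - timestamps[j] > policy.max_span:
            out[i] = int(Level.LOW)
            continue
        out[i] = int(window.min())
    return out


def confirm(
    levels: Sequence[Level | None],
    timestamps: Sequence[float],
    policy: ConfirmationPolicy = ConfirmationPolicy(),
) -> ConfirmedStream:
    """Apply the persistence rule to one time-ordered level sequence.

    Raises ``ValueError`` on unordered timestamps.
    """
    ts = np.asarray(timestamps, dtype=float)
    if len(ts) != len(levels):
        raise ValueError("levels and timestamps must have equal length")
    if len(ts) > 1 and not (np.diff(ts) > 0).all():
        raise ValueError("timestamps must be strictly increasing")
    codes = np.array(
        [-1 if lv is None else int(lv) for lv in levels], dtype=int
    )
    confirmed = _confirm_codes(codes, ts, policy)
    out_levels = tuple(None if c < 0 else Level(c) for c in confirmed)
    counts = {
        level: int((confirmed == int(level)).sum()) for level in Level
    }
    return ConfirmedStream(
        timestamps=tuple(ts),
        instant=tuple(levels),
        levels=out_levels,
        counts=counts,
    )


def confirm_frame(
    scored: pd.DataFrame,
    policy: ConfirmationPolicy = ConfirmationPolicy(),
    columns: Mapping[str, str] = {
        "instant_mprt": "confirmed_mprt",
        "instant_news": "confirmed_news",
    },
) -> pd.DataFrame:
    """Add confirmed-level columns to a scored stream frame."""
    ts = scored["timestamp"].to_numpy(dtype=float)
    out = scored.copy()
    for source, target in columns.items():
        codes = scored[source].fillna(-1).to_numpy(dtype=int)
        confirmed = _confirm_codes(codes, ts, policy)
        out[target] = pd.array(confirmed, dtype="Int64")
        out.loc[out[target] < 0, target] = pd.NA
    return out


def first_alert(
    confirmed: ConfirmedStream, alert_levels: frozenset[Level] | set[Level]
) -> float | None:
    """Earliest timestamp whose confirmed level is in ``alert_levels``."""
    if not alert_levels:
        raise ValueError("alert_levels must be non-empty")
    for ts, level in zip(confirmed.timestamps, confirmed.levels):
        if level is not None and level in alert_levels:
            return ts
    return None


def resample(stream: pd.DataFrame, interval: float) -> pd.DataFrame:
    """Thin a stream to one reading per ``interval``-minute grid instant.

    The grid is anchored at the first reading; for each grid instant the
    nearest reading is retained (ties resolved toward the earlier reading),
    and duplicates are dropped.  Emulates monitoring at a coarser cadence for
    interval-sensitivity analyses.
    """
    if not interval > 0:
        raise ValueError("interval must be positive")
    ts = stream["timestamp"].to_numpy(dtype=float)
    if len(ts) <= 1:
        return stream.copy()
    grid = ts[0] + interval * np.arange(int((ts[-1] - ts[0]) // interval) + 1)
    # nearest reading per grid instant, earlier on ties
    idx = np.searchsorted(ts, grid)
    idx = np.clip(idx, 1, len(ts) - 1)
    left, right = ts[idx - 1], ts[idx]
    pick = np.where(grid - left <= right - grid, idx - 1, idx)
    pick = np.unique(pick)
    return stream.iloc[pick].reset_index(drop=True)
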