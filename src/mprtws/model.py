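"""Domain types, band-table configuration and vitals/outcome file I/O.

The package's unit of data is a *stream*: the time-ordered sequence of
multi-parameter readings one wearable monitor produces for one patient, at a
nominally fixed cadence (5 min in the motivating deployment).  Streams are held
as :class:`pandas.DataFrame` objects with one row per reading and ``NaN`` for
parameters the sensor failed to deliver; :class:`VitalReading` is the row-level
view used when single readings are constructed or validated in isolation.

Score-band tables — the mapping from a raw parameter value to an integer risk
score 0–3 — are configuration, not code.  They are loaded from YAML/JSON and
validated to be an exhaustive, disjoint, half-open partition of the real line
per parameter, so that every finite value maps to exactly one score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

#: the nine MPRT-WS parameters, in canonical column order
MPRT_PARAMETERS = ("hr", "spo2", "rr", "sbp", "dbp", "temp", "sv", "co", "svr")
#: the five NEWS parameters (a subset of the nine)
NEWS_PARAMETERS = ("sbp", "hr", "rr", "spo2", "temp")

#: exact, ordered column schema of a vitals CSV
VITALS_COLUMNS = ("patient_id", "timestamp") + MPRT_PARAMETERS
#: column schema of an outcomes CSV
OUTCOME_COLUMNS = ("patient_id", "deteriorated", "deterioration_time")

_REQUIRED = {"MPRT-WS": MPRT_PARAMETERS, "NEWS": NEWS_PARAMETERS}


class VitalsError(ValueError):
    """Raised for malformed vitals/outcome files or invalid readings."""


class BandTableError(ValueError):
    """Raised when a score-band configuration violates the table invariants."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VitalReading:
    """One timestamped nine-parameter measurement from one patient.

    ``timestamp`` is minutes since the start of the patient's stream.  Any
    parameter may be ``None`` (missing).  Present values must be positive and
    SpO2 cannot exceed 100%.
    """

    patient_id: str
    timestamp: float
    hr: float | None = None
    spo2: float | None = None
    rr: float | None = None
    sbp: float | None = None
    dbp: float | None = None
    temp: float | None = None
    sv: float | None = None
    co: float | None = None
    svr: float | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.timestamp) or self.timestamp < 0:
            raise VitalsError(
                f"patient {self.patient_id!r}: timestamp must be a finite "
                f"non-negative number of minutes, got {self.timestamp!r}"
            )
        for name in MPRT_PARAMETERS:
            value = getattr(self, name)
            if value is None:
                continue
            if not math.isfinite(value) or value <= 0:
                raise VitalsError(
                    f"patient {self.patient_id!r}: {name} must be a positive "
                    f"finite value, got {value!r}"
                )
        if self.spo2 is not None and self.spo2 > 100:
            raise VitalsError(
                f"patient {self.patient_id!r}: spo2 cannot exceed 100%, "
                f"got {self.spo2!r}"
            )

    def values(self) -> dict[str, float | None]:
        """Parameter name → value (``None`` where missing)."""
        return {name: getattr(self, name) for name in MPRT_PARAMETERS}


@dataclass(frozen=True)
class ScoreBand:
    """A half-open value interval ``[lower, upper)`` carrying a score 0–3."""

    lower: float
    upper: float
    score: int

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise BandTableError(
                f"band lower bound must be below upper bound: "
                f"[{self.lower}, {self.upper})"
            )
        if self.score not in (0, 1, 2, 3):
            raise BandTableError(f"band score must be in 0..3, got {self.score!r}")

    def contains(self, value: float) -> bool:
        return self.lower <= value < self.upper


@dataclass(frozen=True)
class ScoreBandTable:
    """Per-parameter ordered score bands for one tool ("MPRT-WS" or "NEWS").

    Invariants (checked by :func:`validate_band_table` / the constructor):
    per parameter the bands are pairwise disjoint and jointly cover
    ``(-inf, +inf)`` under the half-open convention, and at least one band has
    score 0.
    """

    tool: str
    bands: Mapping[str, tuple[ScoreBand, ...]]
    units: Mapping[str, str] = field(default_factory=dict)
    #: inclusive [lo, hi] total-score range for the NEWS Medium level
    aggregate_medium: tuple[int, int] = (5, 6)

    def __post_init__(self) -> None:
        validate_band_table(self)

    @property
    def parameters(self) -> tuple[str, ...]:
        return tuple(self.bands)

    def edges(self, parameter: str) -> tuple[np.ndarray, np.ndarray]:
        """Sorted interior band edges and the score per cell, for vectorised
        lookup via ``np.searchsorted``."""
        bands = sorted(self.bands[parameter], key=lambda b: b.lower)
        cut = np.array([b.upper for b in bands[:-1]], dtype=float)
        scores = np.array([b.score for b in bands], dtype=float)
        return cut, scores


def validate_band_table(table: ScoreBandTable) -> None:
    """Check disjointness, full coverage and presence of a 0-band.

    Errors name the offending parameter and interval, so a mis-transcribed
    configuration points straight at the cell to fix.
    """
    required = _REQUIRED.get(table.tool)
    if required is None:
        raise BandTableError(
            f"unknown tool {table.tool!r}; expected one of {sorted(_REQUIRED)}"
        )
    missing = [p for p in required if p not in table.bands]
    if missing:
        raise BandTableError(
            f"tool {table.tool!r} is missing band definitions for: "
            + ", ".join(missing)
        )
    unknown = [p for p in table.bands if p not in MPRT_PARAMETERS]
    if unknown:
        raise BandTableError(f"unknown parameter name(s): {', '.join(unknown)}")
    for name, bands in table.bands.items():
        if not bands:
            raise BandTableError(f"{name}: empty band list")
        ordered = sorted(bands, key=lambda b: b.lower)
        if ordered[0].lower != -math.inf:
            raise BandTableError(
                f"{name}: gap below {ordered[0].lower} (no band covers -inf)"
            )
        if ordered[-1].upper != math.inf:
            raise BandTableError(
                f"{name}: gap above {ordered[-1].upper} (no band covers +inf)"
            )
        for left, right in zip(ordered, ordered[1:]):
            if left.upper < right.lower:
                raise BandTableError(
                    f"{name}: gap between bands over "
                    f"[{left.upper}, {right.lower})"
                )
            if left.upper > right.lower:
                raise BandTableError(
                    f"{name}: overlapping bands over "
                    f"[{right.lower}, {min(left.upper, right.upper)})"
                )
        if not any(b.score == 0 for b in bands):
            raise BandTableError(f"{name}: no band carries score 0")
    low, high = table.aggregate_medium
    if not (isinstance(low, int) and isinstance(high, int) and 0 < low <= high):
        raise BandTableError(
            f"aggregate_medium must be an increasing pair of positive "
            f"integers, got {table.aggregate_medium!r}"
        )


@dataclass(frozen=True)
class PatientOutcome:
    """Per-patient deterioration annotation.

    ``deterioration_time`` is minutes on the same clock as the patient's
    vitals stream, required iff ``deteriorated``.
    """

    patient_id: str
    deteriorated: bool
    deterioration_time: float | None = None

    def __post_init__(self) -> None:
        if self.deteriorated and self.deterioration_time is None:
            raise VitalsError(
                f"patient {self.patient_id!r}: deteriorated but no "
                "deterioration_time given"
            )
        if not self.deteriorated and self.deterioration_time is not None:
            raise VitalsError(
                f"patient {self.patient_id!r}: deterioration_time given for a "
                "non-deteriorating patient"
            )


# ---------------------------------------------------------------------------
# band-table configuration I/O
# ---------------------------------------------------------------------------


def _as_bound(raw: object, which: str, parameter: str) -> float:
    if isinstance(raw, str):
        text = raw.strip().lower()
        if text in ("-inf", "-infinity"):
            return -math.inf
        if text in ("inf", "+inf", "infinity"):
            return math.inf
        raise BandTableError(f"{parameter}: unrecognised {which} bound {raw!r}")
    if isinstance(raw, (int, float)):
        return float(raw)
    raise BandTableError(f"{parameter}: unrecognised {which} bound {raw!r}")


def band_table_from_dict(config: Mapping[str, object]) -> ScoreBandTable:
    """Build and validate a :class:`ScoreBandTable` from a parsed config."""
    try:
        tool = str(config["tool"])
        raw_bands = config["bands"]
    except (KeyError, TypeError) as exc:
        raise BandTableError(
            "band config must define top-level keys 'tool' and 'bands'"
        ) from exc
    if not isinstance(raw_bands, Mapping):
        raise BandTableError("'bands' must map parameter names to band lists")
    bands: dict[str, tuple[ScoreBand, ...]] = {}
    for name, entries in raw_bands.items():
        if not isinstance(entries, Sequence):
            raise BandTableError(f"{name}: band list must be a sequence")
        parsed = []
        for entry in entries:
            try:
                parsed.append(
                    ScoreBand(
                        lower=_as_bound(entry["lower"], "lower", name),
                        upper=_as_bound(entry["upper"], "upper", name),
                        score=int(entry["score"]),
                    )
                )
            except (KeyError, TypeError) as exc:
                raise BandTableError(
                    f"{name}: each band needs 'lower', 'upper' and 'score', "
                    f"got {entry!r}"
                ) from exc
        bands[name] = tuple(parsed)
    medium = config.get("aggregate_medium", (5, 6))
    return ScoreBandTable(
        tool=tool,
        bands=bands,
        units=dict(config.get("units", {})),
        aggregate_medium=(int(medium[0]), int(medium[1])),
    )


def load_band_table(path: str | Path) -> ScoreBandTable:
    """Load a YAML (or JSON — a YAML subset) band config and validate it."""
    with open(path) as handle:
        config = yaml.safe_load(handle)
    if not isinstance(config, Mapping):
        raise BandTableError(f"{path}: config root must be a mapping")
    return band_table_from_dict(config)


def default_band_table(tool: str) -> ScoreBandTable:
    """The band table shipped with the package for ``tool``."""
    filename = {"MPRT-WS": "mprtws_default.yaml", "NEWS": "news_default.yaml"}
    try:
        name = filename[tool]
    except KeyError:
        raise BandTableError(
            f"unknown tool {tool!r}; expected one of {sorted(filename)}"
        ) from None
    ref = resources.files("mprtws.data").joinpath(name)
    config = yaml.safe_load(ref.read_text())
    return band_table_from_dict(config)


# ---------------------------------------------------------------------------
# vitals / outcome file I/O
# ---------------------------------------------------------------------------


def _timestamps_to_minutes(column: pd.Series, context: str) -> pd.Series:
    """Numeric timestamps pass through; ISO-8601 instants are converted to
    minutes since the first instant of the series."""
    numeric = pd.to_numeric(column, errors="coerce")
    if not numeric.isna().any():
        return numeric.astype(float)
    try:
        instants = pd.to_datetime(column, utc=True, format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise VitalsError(
            f"{context}: timestamps must be minutes (numeric) or ISO-8601 "
            f"instants"
        ) from exc
    origin = instants.min()
    return (instants - origin).dt.total_seconds() / 60.0


def read_vitals(path: str | Path) -> dict[str, pd.DataFrame]:
    """Read a vitals CSV into per-patient time-ordered streams.

    Returns a mapping patient_id → DataFrame with a float ``timestamp`` column
    (minutes since the patient's stream start) and one float column per
    parameter, ``NaN`` marking missing readings.  Empty cells and ``NA`` are
    missing markers, never zeros.

    Raises :class:`VitalsError` naming the line for a malformed row and the
    patient for non-monotone timestamps.
    """
    frame = pd.read_csv(
        path, dtype={"patient_id": str}, na_values=["NA"], keep_default_na=True
    )
    got = tuple(frame.columns)
    if got != VITALS_COLUMNS:
        raise VitalsError(
            f"{path}: expected columns {list(VITALS_COLUMNS)}, got {list(got)}"
        )
    for name in MPRT_PARAMETERS:
        coerced = pd.to_numeric(frame[name], errors="coerce")
        bad = coerced.isna() & frame[name].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise VitalsError(
                f"{path}: malformed {name} value {frame[name][bad.idxmax()]!r} "
                f"on line {line}"
            )
        frame[name] = coerced.astype(float)
    if frame["patient_id"].isna().any():
        line = int(frame["patient_id"].isna().idxmax()) + 2
        raise VitalsError(f"{path}: missing patient_id on line {line}")

    streams: dict[str, pd.DataFrame] = {}
    for patient, group in frame.groupby("patient_id", sort=True):
        stream = group.copy()
        stream["timestamp"] = _timestamps_to_minutes(
            stream["timestamp"], f"{path}: patient {patient!r}"
        )
        stream = stream.sort_values("timestamp", kind="stable")
        diffs = stream["timestamp"].diff().dropna()
        if (diffs <= 0).any():
            raise VitalsError(
                f"{path}: patient {patient!r} has non-increasing timestamps "
                "(duplicate or out-of-order readings)"
            )
        values = stream[list(MPRT_PARAMETERS)]
        if (values <= 0).any().any():
            raise VitalsError(
                f"{path}: patient {patient!r} has non-positive vital values"
            )
        if (stream["spo2"] > 100).any():
            raise VitalsError(f"{path}: patient {patient!r} has spo2 > 100%")
        streams[str(patient)] = stream.reset_index(drop=True)
    return streams


def write_vitals(path: str | Path, streams: Mapping[str, pd.DataFrame]) -> None:
    """Write per-patient streams back to the canonical vitals CSV schema."""
    parts = []
    for patient, stream in streams.items():
        part = stream.copy()
        part["patient_id"] = patient
        parts.append(part[list(VITALS_COLUMNS)])
    if parts:
        combined = pd.concat(parts, ignore_index=True)
    else:
        combined = pd.DataFrame(columns=list(VITALS_COLUMNS))
    combined.to_csv(path, index=False, float_format="%.6g")


def read_outcomes(path: str | Path) -> dict[str, PatientOutcome]:
    """Read per-patient outcome annotations (deteriorated flag + time)."""
    frame = pd.read_csv(path, dtype={"patient_id": str}, na_values=["NA"])
    got = tuple(frame.columns)
    if got != OUTCOME_COLUMNS:
        raise VitalsError(
            f"{path}: expected columns {list(OUTCOME_COLUMNS)}, got {list(got)}"
        )
    outcomes: dict[str, PatientOutcome] = {}
    for row in frame.itertuples(index=False):
        deteriorated = bool(int(row.deteriorated))
        time = None
        if not pd.isna(row.deterioration_time):
            time = float(row.deterioration_time)
        outcomes[str(row.patient_id)] = PatientOutcome(
            patient_id=str(row.patient_id),
            deteriorated=deteriorated,
            deterioration_time=time if deteriorated else None,
        )
    return outcomes


def write_outcomes(path: str | Path, outcomes: Mapping[str, PatientOutcome]) -> None:
    rows = [
        {
            "patient_id": o.patient_id,
            "deteriorated": int(o.deteriorated),
            "deterioration_time": o.deterioration_time,
        }
        for o in outcomes.values()
    ]
    pd.DataFrame(rows, columns=list(OUTCOME_COLUMNS)).to_csv(path, index=False)


def write_events(path: str | Path, events: pd.DataFrame) -> None:
    """Write a scored+confirmed events table (one row per reading) to CSV.

    ``events`` is the long-format frame produced by the pipeline: patient,
    timestamp, per-parameter scores, instantaneous and confirmed levels.
    """
    events.to_csv(path, index=False, float_format="%.6g")


def stream_from_readings(readings: Iterable[VitalReading]) -> pd.DataFrame:
    """Build a stream DataFrame from validated single readings."""
    rows = [
        {"patient_id": r.patient_id, "timestamp": r.timestamp, **r.values()}
        for r in readings
    ]
    frame = pd.DataFrame(rows, columns=list(VITALS_COLUMNS))
    frame[list(MPRT_PARAMETERS)] = frame[list(MPRT_PARAMETERS)].astype(float)
    return frame
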