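"""Seeded synthetic wearable-vitals cohorts.

Emulates the sampling structure the warning score assumes: one reading of all
nine parameters every ``cadence`` minutes (5 by default) for up to 72 h per
patient.  Each parameter fluctuates as a stationary first-order
autoregression around a patient baseline (physiologically smooth sensor
noise); deteriorating patients additionally ramp a chosen subset of
parameters linearly from baseline into the midpoint of a configured target
score band, then hold there.  Isolated single-reading artifacts (excursions
into a 3-band that immediately revert) and per-parameter missingness model
wearable data quality.

Everything is reproducible bit-for-bit from ``(spec, seed)``; per-patient
generators are derived deterministically from the master seed.  The
parameters are generated independently of one another — the scoring tool
treats all nine as independent inputs, so cross-parameter physiological
coupling (e.g. SVR from pressures and flow) is deliberately not modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .model import (
    MPRT_PARAMETERS,
    PatientOutcome,
    ScoreBandTable,
    default_band_table,
)

#: textbook mid-normal adult resting baselines (units as in VitalReading)
DEFAULT_BASELINES: Mapping[str, float] = {
    "hr": 75.0, "spo2": 97.5, "rr": 16.0, "sbp": 125.0, "dbp": 75.0,
    "temp": 37.0, "sv": 80.0, "co": 5.5, "svr": 1000.0,
}

#: realistic wearable sensor-noise SDs (stationary, per reading)
DEFAULT_NOISE_SD: Mapping[str, float] = {
    "hr": 3.0, "spo2": 1.0, "rr": 1.5, "sbp": 6.0, "dbp": 4.0,
    "temp": 0.15, "sv": 4.0, "co": 0.3, "svr": 50.0,
}

#: illustrative deterioration phenotypes by admission diagnosis — each names
#: the parameter subset that degrades; not clinically validated
PHENOTYPES: Mapping[str, tuple[str, ...]] = {
    "CHF": ("sv", "co", "spo2"),
    "CVA": ("sbp", "hr", "rr"),
    "COPD": ("spo2", "rr", "hr"),
    "CKD": ("sbp", "dbp", "svr"),
    "arrhythmia": ("hr", "co", "sv"),
}


class SpecError(ValueError):
    """Raised when a trajectory specification violates its invariants."""


@dataclass(frozen=True)
class Deterioration:
    """A deterioration signature: which parameters degrade, to where, when.

    ``affected`` maps parameter → target band score (2 or 3); values ramp
    linearly from baseline to the midpoint of the target band between
    ``onset`` and ``onset + ramp`` minutes, then hold.  ``direction`` picks
    the band side relative to baseline (default "high"; "low" for e.g.
    desaturation or falling stroke volume).
    """

    onset: float
    ramp: float
    affected: Mapping[str, int]
    direction: Mapping[str, str] = field(default_factory=dict)

    def side(self, parameter: str) -> str:
        return self.direction.get(parameter, "high")


@dataclass(frozen=True)
class TrajectorySpec:
    """Generation recipe for one patient stream."""

    baselines: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINES)
    )
    noise_sd: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NOISE_SD)
    )
    autocorr: float = 0.8
    deterioration: Deterioration | None = None
    artifact_rate: float = 0.0       # expected isolated spikes per 24 h
    missing_prob: float = 0.0        # per parameter per reading
    cadence: float = 5.0             # minutes
    duration: float = 1440.0         # minutes (<= 72 h)

    def __post_init__(self) -> None:
        if not self.cadence > 0:
            raise SpecError("cadence must be positive")
        if not 0 <= self.autocorr < 1:
            raise SpecError("autocorr must be in [0, 1)")
        if not 0 <= self.missing_prob <= 1:
            raise SpecError("missing_prob must be a probability")
        if self.artifact_rate < 0:
            raise SpecError("artifact_rate must be non-negative")
        if self.duration <= 0 or self.duration > 4320:
            raise SpecError("duration must be in (0, 4320] minutes (72 h)")
        missing = [p for p in MPRT_PARAMETERS if p not in self.baselines]
        if missing:
            raise SpecError(f"baselines missing parameter(s): {missing}")
        det = self.deterioration
        if det is not None:
            if det.onset < 0 or det.ramp <= 0:
                raise SpecError("deterioration needs onset >= 0 and ramp > 0")
            if det.onset + det.ramp > self.duration:
                raise SpecError("onset + ramp must not exceed duration")
            for p, score in det.affected.items():
                if p not in MPRT_PARAMETERS:
                    raise SpecError(f"unknown affected parameter {p!r}")
                if score not in (1, 2, 3):
                    raise SpecError("target band score must be 1, 2 or 3")


@dataclass(frozen=True)
class SyntheticCohort:
    """Streams + outcomes generated from (spec, seed)."""

    streams: dict[str, pd.DataFrame]
    outcomes: dict[str, PatientOutcome]
    seed: int
    stable_spec: TrajectorySpec
    deteriorating_spec: TrajectorySpec | None


def band_target_value(
    table: ScoreBandTable, parameter: str, score: int,
    baseline: float, side: str = "high",
) -> float:
    """Midpoint of the nearest band with ``score`` on ``side`` of baseline.

    For a half-infinite band the midpoint is taken one half-width of the
    adjacent finite band beyond the finite edge.
    """
    bands = sorted(table.bands[parameter], key=lambda b: b.lower)
    if side == "high":
        candidates = [b for b in bands if b.score == score and b.lower >= baseline]
        if not candidates:
            raise SpecError(
                f"{parameter}: no {score}-band above baseline {baseline}"
            )
        band = candidates[0]
    else:
        candidates = [b for b in bands if b.score == score and b.upper <= baseline]
        if not candidates:
            raise SpecError(
                f"{parameter}: no {score}-band below baseline {baseline}"
            )
        band = candidates[-1]
    if math.isfinite(band.lower) and math.isfinite(band.upper):
        return (band.lower + band.upper) / 2
    widths = [
        b.upper - b.lower
        for b in bands
        if math.isfinite(b.lower) and math.isfinite(b.upper)
    ]
    step = (min(widths) if widths else 1.0) / 2
    return band.lower + step if math.isfinite(band.lower) else band.upper - step


def _mean_track(
    spec: TrajectorySpec, table: ScoreBandTable, parameter: str,
    timestamps: np.ndarray,
) -> np.ndarray:
    baseline = spec.baselines[parameter]
    track = np.full_like(timestamps, baseline, dtype=float)
    det = spec.deterioration
    if det is None or parameter not in det.affected:
        return track
    target = band_target_value(
        table, parameter, det.affected[parameter], baseline, det.side(parameter)
    )
    frac = np.clip((timestamps - det.onset) / det.ramp, 0.0, 1.0)
    return baseline + frac * (target - baseline)


def generate_patient(
    spec: TrajectorySpec,
    seed: int,
    patient_id: str = "P0",
    table: ScoreBandTable | None = None,
) -> tuple[pd.DataFrame, PatientOutcome]:
    """One stream + outcome from a validated spec and an integer seed."""
    if table is None:
        table = default_band_table("MPRT-WS")
    rng = np.random.default_rng(seed)
    n = int(spec.duration // spec.cadence) + 1
    timestamps = spec.cadence * np.arange(n, dtype=float)

    columns: dict[str, np.ndarray] = {}
    rho = spec.autocorr
    for parameter in MPRT_PARAMETERS:
        mean = _mean_track(spec, table, parameter, timestamps)
        sd = spec.noise_sd.get(parameter, 0.0)
        if sd > 0:
            innovations = rng.normal(0.0, sd * math.sqrt(1 - rho**2), size=n)
            noise = np.empty(n)
            noise[0] = rng.normal(0.0, sd)
            for i in range(1, n):
                noise[i] = rho * noise[i - 1] + innovations[i]
        else:
            rng.normal(size=n + 1)  # keep the draw count stable across sds
            noise = np.zeros(n)
        columns[parameter] = mean + noise

    # isolated single-reading artifacts: excursion into a 3-band, then return
    if spec.artifact_rate > 0:
        p_artifact = spec.artifact_rate * spec.cadence / 1440.0
        hits = np.flatnonzero(rng.random(n) < p_artifact)
        isolated = []
        last = -2
        for i in hits:
            if i - last >= 2:
                isolated.append(i)
                last = i
        for i in isolated:
            parameter = MPRT_PARAMETERS[rng.integers(len(MPRT_PARAMETERS))]
            side = "low" if parameter in ("spo2", "sv", "co", "temp") else "high"
            try:
                excursion = band_target_value(
                    table, parameter, 3, spec.baselines[parameter], side
                )
            except SpecError:  # no 3-band on that side of baseline
                other = "high" if side == "low" else "low"
                excursion = band_target_value(
                    table, parameter, 3, spec.baselines[parameter], other
                )
            columns[parameter][i] = excursion

    if spec.missing_prob > 0:
        for parameter in MPRT_PARAMETERS:
            drop = rng.random(n) < spec.missing_prob
            columns[parameter][drop] = np.nan

    # physical limits: positive values, SpO2 capped at 100%
    for parameter in MPRT_PARAMETERS:
        columns[parameter] = np.clip(columns[parameter], 0.01, None)
    columns["spo2"] = np.clip(columns["spo2"], None, 100.0)

    frame = pd.DataFrame({"patient_id": patient_id, "timestamp": timestamps})
    for parameter in MPRT_PARAMETERS:
        frame[parameter] = columns[parameter]

    det = spec.deterioration
    outcome = PatientOutcome(
        patient_id=patient_id,
        deteriorated=det is not None,
        deterioration_time=(det.onset + det.ramp) if det is not None else None,
    )
    return frame, outcome


def generate_cohort(
    n_stable: int,
    n_deteriorating: int,
    seed: int,
    stable_spec: TrajectorySpec | None = None,
    deteriorating_spec: TrajectorySpec | None = None,
    table: ScoreBandTable | None = None,
) -> SyntheticCohort:
    """A cohort of stable and deteriorating patients.

    Per-patient generators are seeded as ``default_rng([seed, index])`` so the
    cohort is reproducible and individual patients are independent.
    """
    if n_stable < 0 or n_deteriorating < 0:
        raise SpecError("patient counts must be non-negative")
    if stable_spec is None:
        stable_spec = TrajectorySpec()
    if deteriorating_spec is None and n_deteriorating > 0:
        deteriorating_spec = default_deteriorating_spec()
    if table is None:
        table = default_band_table("MPRT-WS")

    streams: dict[str, pd.DataFrame] = {}
    outcomes: dict[str, PatientOutcome] = {}
    index = 0
    for count, spec, prefix in (
        (n_stable, stable_spec, "S"),
        (n_deteriorating, deteriorating_spec, "D"),
    ):
        for _ in range(count):
            patient_id = f"{prefix}{index:04d}"
            child_seed = int(
                np.random.SeedSequence([seed, index]).generate_state(1)[0]
                % (2**31)
            )
            stream, outcome = generate_patient(
                spec, child_seed, patient_id, table
            )
            streams[patient_id] = stream
            outcomes[patient_id] = outcome
            index += 1
    return SyntheticCohort(
        streams=streams,
        outcomes=outcomes,
        seed=seed,
        stable_spec=stable_spec,
        deteriorating_spec=deteriorating_spec,
    )


def default_deteriorating_spec(
    phenotype: str = "CKD",
    target_score: int = 2,
    onset: float = 360.0,
    ramp: float = 120.0,
    **overrides,
) -> TrajectorySpec:
    """A deteriorating recipe from a named phenotype preset.

    Direction defaults to "high" except for parameters that clinically fall
    during deterioration (SpO2, SV, CO, and SBP — deterioration toward shock
    is hypotensive, and the SBP chart grades hypotension more finely).
    """
    try:
        affected = PHENOTYPES[phenotype]
    except KeyError:
        raise SpecError(
            f"unknown phenotype {phenotype!r}; choose from {sorted(PHENOTYPES)}"
        ) from None
    falling = {"spo2", "sv", "co", "sbp"}
    det = Deterioration(
        onset=onset,
        ramp=ramp,
        affected={p: target_score for p in affected},
        direction={p: "low" for p in affected if p in falling},
    )
    return TrajectorySpec(deterioration=det, **overrides)


def noise_from_band_width(
    table: ScoreBandTable,
    affected: Mapping[str, int],
    direction: Mapping[str, str] | None = None,
    fraction: float = 0.25,
    baselines: Mapping[str, float] = DEFAULT_BASELINES,
) -> dict[str, float]:
    """Noise SDs scaled to the target band: ``fraction`` of each affected
    parameter's target-band width, defaults elsewhere.

    Expresses sensor noise relative to the scale the score discriminates on,
    so detection difficulty is comparable across parameters with very
    different units.
    """
    direction = direction or {}
    noise = dict(DEFAULT_NOISE_SD)
    for parameter, score in affected.items():
        target = band_target_value(
            table, parameter, score, baselines[parameter],
            direction.get(parameter, "high"),
        )
        band = next(
            b
            for b in sorted(table.bands[parameter], key=lambda b: b.lower)
            if b.contains(target)
        )
        if math.isfinite(band.lower) and math.isfinite(band.upper):
            noise[parameter] = fraction * (band.upper - band.lower)
    return noise


def predicted_alert_time(
    spec: TrajectorySpec,
    table: ScoreBandTable | None = None,
    policy_min_consecutive: int = 2,
) -> float:
    """Closed-form confirmed-alert time for a *noiseless* deterioration ramp.

    Each affected parameter crosses into its target band where the linear
    ramp meets the band edge; the instantaneous level escalates at the first
    grid reading after all affected parameters have crossed, and confirmation
    adds ``policy_min_consecutive − 1`` further cadence steps.
    """
    det = spec.deterioration
    if det is None:
        raise SpecError("spec has no deterioration")
    if table is None:
        table = default_band_table("MPRT-WS")
    crossings = []
    for parameter, score in det.affected.items():
        baseline = spec.baselines[parameter]
        side = det.side(parameter)
        target = band_target_value(table, parameter, score, baseline, side)
        bands = sorted(table.bands[parameter], key=lambda b: b.lower)
        band = next(b for b in bands if b.contains(target))
        edge = band.lower if side == "high" else band.upper
        frac = (edge - baseline) / (target - baseline)
        crossings.append(det.onset + frac * det.ramp)
    t_all = max(crossings)
    first_instant = spec.cadence * math.ceil(t_all / spec.cadence)
    return first_instant + (policy_min_consecutive - 1) * spec.cadence
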