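"""Cohort-level evaluation: level distributions, sensitivity, lead times,
tool-comparison tests, per-parameter attribution and diagnosis-group
segmentation.

Conventions
-----------
* An *event* is one confirmed reading at a level; distributions are over
  per-reading event counts.
* A deteriorating patient is *identified* by a tool when its first confirmed
  alert (High/Urgent for MPRT-WS, High for NEWS) falls strictly before the
  annotated deterioration time; sensitivity is identified / deteriorated.
* Lead time is (deterioration time − first alert) in hours, summarised as
  mean ± sample SD over identified patients.
* Reported percentages are rounded half-up to one decimal place.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .confirmation import DEFAULT_ALERT_LEVELS, ConfirmationPolicy, confirm_frame
from .model import MPRT_PARAMETERS, PatientOutcome
from .scoring import Level


class EvaluationError(ValueError):
    """Raised for ill-posed evaluation requests (empty cohorts, bad tables)."""


def round_percent(fraction: float, digits: int = 1) -> float:
    """Round ``fraction × 100`` half-up to ``digits`` decimals (report style)."""
    quantum = Decimal(1).scaleb(-digits)
    return float(
        (Decimal(repr(fraction)) * 100).quantize(quantum, rounding=ROUND_HALF_UP)
    )


# ---------------------------------------------------------------------------
# distributions
# ---------------------------------------------------------------------------


def level_distribution(
    counts: Mapping[Level, int], levels: Sequence[Level] | None = None
) -> dict[Level, tuple[int, float]]:
    """Per-level counts and percentage shares over the reported level set.

    ``levels`` fixes the denominator (e.g. Low/Medium/High with Urgent
    reported separately over the grand total); by default every level present
    in ``counts`` with a nonzero count is reported.
    """
    if levels is None:
        levels = [lv for lv in Level if counts.get(lv, 0) > 0]
    total = sum(counts.get(lv, 0) for lv in levels)
    if total == 0:
        raise EvaluationError("empty cohort: no readings at the reported levels")
    return {
        lv: (counts.get(lv, 0), round_percent(counts.get(lv, 0) / total))
        for lv in levels
    }


def count_confirmed(
    frames: Mapping[str, pd.DataFrame], column: str
) -> dict[Level, int]:
    """Pool per-reading confirmed-level event counts over a cohort."""
    counts = {lv: 0 for lv in Level}
    for frame in frames.values():
        codes = frame[column].dropna().astype(int)
        for lv in Level:
            counts[lv] += int((codes == int(lv)).sum())
    return counts


# ---------------------------------------------------------------------------
# sensitivity and lead times
# ---------------------------------------------------------------------------


def sensitivity(n_identified: int, n_deteriorated: int) -> float:
    """Fraction of deteriorating patients the tool identified in advance."""
    if n_deteriorated <= 0:
        raise EvaluationError("n_deteriorated must be positive")
    if not 0 <= n_identified <= n_deteriorated:
        raise EvaluationError(
            f"need 0 <= n_identified <= n_deteriorated, got "
            f"{n_identified}/{n_deteriorated}"
        )
    return n_identified / n_deteriorated


@dataclass(frozen=True)
class LeadTimeSummary:
    """Per-patient advance-warning times (hours) and their mean ± sample SD."""

    leads: Mapping[str, float]
    mean: float | None
    sd: float | None

    @property
    def n_identified(self) -> int:
        return len(self.leads)


def lead_times(
    first_alerts: Mapping[str, float | None],
    outcomes: Mapping[str, PatientOutcome],
) -> LeadTimeSummary:
    """Advance warning per identified patient, in hours.

    A deteriorated patient counts as identified only when the first alert is
    strictly before the deterioration time; alerts at or after it give no
    advance warning.  Mean and sample SD are over identified patients (SD is
    ``None`` with fewer than two).
    """
    leads: dict[str, float] = {}
    for patient, outcome in outcomes.items():
        if not outcome.deteriorated:
            continue
        alert = first_alerts.get(patient)
        if alert is None or alert >= outcome.deterioration_time:
            continue
        leads[patient] = (outcome.deterioration_time - alert) / 60.0
    values = np.array(sorted(leads.values()), dtype=float)
    mean = float(values.mean()) if len(values) else None
    sd = float(values.std(ddof=1)) if len(values) > 1 else None
    return LeadTimeSummary(leads=leads, mean=mean, sd=sd)


# ---------------------------------------------------------------------------
# comparison tests
# ---------------------------------------------------------------------------


def compare_distributions(
    counts_a: Mapping[Level, int], counts_b: Mapping[Level, int]
) -> tuple[float, float]:
    """Pearson chi-square homogeneity test on the 2×k level-count table."""
    levels_a = {lv for lv, c in counts_a.items() if c > 0}
    levels_b = {lv for lv, c in counts_b.items() if c > 0}
    levels = sorted(levels_a | levels_b)
    if levels_a != levels_b:
        raise EvaluationError(
            f"mismatched level sets: {sorted(levels_a)} vs {sorted(levels_b)}"
        )
    table = np.array(
        [[counts_a[lv] for lv in levels], [counts_b[lv] for lv in levels]]
    )
    result = stats.chi2_contingency(table, correction=False)
    return float(result.statistic), float(result.pvalue)


def compare_identified(
    identified_a: int, identified_b: int, n_deteriorated: int
) -> float:
    """Two-sided Fisher exact p for identified/not-identified × tool."""
    for n in (identified_a, identified_b):
        if n < 0 or n > n_deteriorated:
            raise EvaluationError("identified counts must lie in [0, n_deteriorated]")
    table = [
        [identified_a, n_deteriorated - identified_a],
        [identified_b, n_deteriorated - identified_b],
    ]
    return float(stats.fisher_exact(table, alternative="two-sided").pvalue)


# ---------------------------------------------------------------------------
# attribution and segmentation
# ---------------------------------------------------------------------------


def _abnormal_threshold(level: Level) -> int:
    # Urgent is driven by 3-scores; High/Medium by 2-scores.
    return 3 if level == Level.URGENT else 2


def attribution(
    frames: Mapping[str, pd.DataFrame],
    level: Level,
    column: str = "confirmed_mprt",
    threshold: int | None = None,
    parameters: Sequence[str] = MPRT_PARAMETERS,
) -> dict[str, float]:
    """Fraction of confirmed readings at ``level`` where each parameter is
    abnormal (score ≥ ``threshold``; default 3 for Urgent, 2 otherwise).

    Shows which vitals drive each alert level; fractions need not sum to 1.
    """
    if threshold is None:
        threshold = _abnormal_threshold(level)
    hits = {p: 0 for p in parameters}
    total = 0
    for frame in frames.values():
        at_level = frame[frame[column].notna() & (frame[column] == int(level))]
        total += len(at_level)
        for p in parameters:
            hits[p] += int((at_level[f"{p}_score"] >= threshold).sum())
    if total == 0:
        warnings.warn(f"no confirmed readings at level {level.name}", stacklevel=2)
        return {}
    return {p: hits[p] / total for p in parameters}


@dataclass(frozen=True)
class GroupSummary:
    """Box-plot style summary of per-patient alert counts in one group."""

    n_patients: int
    total: int
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]


def _summarise(values: np.ndarray) -> GroupSummary:
    q1, median, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    outliers = values[(values < lo_fence) | (values > hi_fence)]
    return GroupSummary(
        n_patients=len(values),
        total=int(values.sum()),
        median=float(median),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()) if len(inside) else float(q1),
        whisker_high=float(inside.max()) if len(inside) else float(q3),
        outliers=tuple(float(v) for v in sorted(outliers)),
    )


def segment_by_group(
    frames: Mapping[str, pd.DataFrame],
    groups: Mapping[str, str],
    alert_levels: frozenset[Level] | set[Level] = frozenset(
        {Level.HIGH, Level.URGENT}
    ),
    column: str = "confirmed_mprt",
    threshold: int = 2,
    parameters: Sequence[str] = MPRT_PARAMETERS,
) -> dict[str, dict[str, GroupSummary]]:
    """Per diagnosis group and parameter: confirmed-alert counts in which the
    parameter is abnormal, with per-patient box-plot summaries
    (median, quartiles, 1.5×IQR whiskers, outliers).
    """
    missing = [p for p in frames if p not in groups]
    if missing:
        raise EvaluationError(
            f"no group label for patient(s): {', '.join(sorted(missing))}"
        )
    alert_codes = {int(lv) for lv in alert_levels}
    per_group: dict[str, dict[str, list[int]]] = {}
    for patient, frame in frames.items():
        group = groups[patient]
        bucket = per_group.setdefault(group, {p: [] for p in parameters})
        mask = frame[column].notna() & frame[column].isin(alert_codes)
        at_alert = frame[mask]
        for p in parameters:
            bucket[p].append(int((at_alert[f"{p}_score"] >= threshold).sum()))
    return {
        group: {
            p: _summarise(np.array(vals, dtype=float))
            for p, vals in buckets.items()
        }
        for group, buckets in per_group.items()
    }


# ---------------------------------------------------------------------------
# the full report
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    """Everything the cohort evaluation computes, JSON-serialisable."""

    counts_mprt: dict[Level, int]
    counts_news: dict[Level, int]
    distribution_mprt: dict[Level, tuple[int, float]]
    distribution_news: dict[Level, tuple[int, float]]
    urgent_fraction_pct: float | None
    n_deteriorated: int
    n_identified_mprt: int
    n_identified_news: int
    sensitivity_mprt: float | None
    sensitivity_news: float | None
    lead_mprt: LeadTimeSummary | None
    lead_news: LeadTimeSummary | None
    chi2_stat: float | None
    chi2_p: float | None
    fisher_p: float | None
    attribution_mprt: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        def dist(d: dict[Level, tuple[int, float]]) -> dict:
            return {
                lv.name: {"count": c, "percent": pct} for lv, (c, pct) in d.items()
            }

        def lead(summary: LeadTimeSummary | None) -> dict | None:
            if summary is None:
                return None
            return {
                "n_identified": summary.n_identified,
                "mean_h": summary.mean,
                "sd_h": summary.sd,
            }

        return {
            "mprt_ws": {
                "distribution": dist(self.distribution_mprt),
                "urgent_fraction_pct": self.urgent_fraction_pct,
                "sensitivity": self.sensitivity_mprt,
                "n_identified": self.n_identified_mprt,
                "lead_time": lead(self.lead_mprt),
            },
            "news": {
                "distribution": dist(self.distribution_news),
                "sensitivity": self.sensitivity_news,
                "n_identified": self.n_identified_news,
                "lead_time": lead(self.lead_news),
            },
            "n_deteriorated": self.n_deteriorated,
            "comparison": {
                "chi2_stat": self.chi2_stat,
                "chi2_p": self.chi2_p,
                "fisher_p": self.fisher_p,
            },
            "attribution_mprt": self.attribution_mprt,
        }

    def to_text(self) -> str:
        lines = ["Cohort evaluation", "================="]
        for tool, dist in (
            ("MPRT-WS", self.distribution_mprt),
            ("NEWS", self.distribution_news),
        ):
            lines.append(f"\n{tool} confirmed event distribution:")
            for lv, (count, pct) in dist.items():
                lines.append(f"  {lv.name:<7} {count:>10,d}  {pct:5.1f}%")
        if self.urgent_fraction_pct is not None:
            lines.append(
                f"  URGENT share of all readings: {self.urgent_fraction_pct:.1f}%"
            )
        if self.n_deteriorated:
            lines.append(f"\nDeteriorated patients: {self.n_deteriorated}")
            for tool, n_id, sens, lead in (
                ("MPRT-WS", self.n_identified_mprt, self.sensitivity_mprt,
                 self.lead_mprt),
                ("NEWS", self.n_identified_news, self.sensitivity_news,
                 self.lead_news),
            ):
                if sens is None:
                    continue
                line = (
                    f"  {tool}: identified {n_id}/{self.n_deteriorated} "
                    f"(sensitivity {round_percent(sens):.1f}%)"
                )
                if lead is not None and lead.mean is not None:
                    sd = f" ± {lead.sd:.1f}" if lead.sd is not None else ""
                    line += f", lead time {lead.mean:.1f}{sd} h"
                lines.append(line)
        if self.chi2_stat is not None:
            lines.append(
                f"\nChi-square (distributions): stat={self.chi2_stat:.3f}, "
                f"p={self.chi2_p:.3f}"
            )
        if self.fisher_p is not None:
            lines.append(f"Fisher exact (identified): p={self.fisher_p:.3f}")
        return "\n".join(lines)


def evaluate_cohort(
    scored: Mapping[str, pd.DataFrame],
    outcomes: Mapping[str, PatientOutcome] | None = None,
    policy: ConfirmationPolicy = ConfirmationPolicy(),
    with_attribution: bool = False,
) -> EvaluationReport:
    """Confirm and evaluate a scored cohort end to end.

    ``scored`` maps patient → frame from :func:`mprtws.scoring.score_stream`.
    Distributions follow the reporting convention of the score: Low/Medium/
    High shares over non-Urgent readings for MPRT-WS with the Urgent share
    quoted over all readings, and Low/Medium/High shares for NEWS.
    """
    if not scored:
        raise EvaluationError("empty cohort")
    confirmed = {
        patient: confirm_frame(frame, policy) for patient, frame in scored.items()
    }
    counts_mprt = count_confirmed(confirmed, "confirmed_mprt")
    counts_news = count_confirmed(confirmed, "confirmed_news")
    lmh = [Level.LOW, Level.MEDIUM, Level.HIGH]
    dist_mprt = level_distribution(counts_mprt, lmh)
    dist_news = level_distribution(counts_news, lmh)
    total_mprt = sum(counts_mprt.values())
    urgent_pct = (
        round_percent(counts_mprt[Level.URGENT] / total_mprt)
        if total_mprt
        else None
    )
    chi2_stat = chi2_p = None
    try:
        chi2_stat, chi2_p = compare_distributions(
            {lv: counts_mprt[lv] for lv in lmh},
            {lv: counts_news[lv] for lv in lmh},
        )
    except EvaluationError:
        pass

    n_det = n_id_m = n_id_n = 0
    sens_m = sens_n = fisher_p = None
    lead_m = lead_n = None
    if outcomes:
        n_det = sum(1 for o in outcomes.values() if o.deteriorated)
        alerts_m: dict[str, float | None] = {}
        alerts_n: dict[str, float | None] = {}
        for patient, frame in confirmed.items():
            ts = frame["timestamp"].to_numpy(dtype=float)
            for column, store, levels in (
                ("confirmed_mprt", alerts_m, DEFAULT_ALERT_LEVELS["MPRT-WS"]),
                ("confirmed_news", alerts_n, DEFAULT_ALERT_LEVELS["NEWS"]),
            ):
                codes = frame[column]
                mask = codes.notna() & codes.isin({int(lv) for lv in levels})
                store[patient] = float(ts[mask.to_numpy()][0]) if mask.any() else None
        if n_det > 0:
            lead_m = lead_times(alerts_m, outcomes)
            lead_n = lead_times(alerts_n, outcomes)
            n_id_m, n_id_n = lead_m.n_identified, lead_n.n_identified
            sens_m = sensitivity(n_id_m, n_det)
            sens_n = sensitivity(n_id_n, n_det)
            fisher_p = compare_identified(n_id_m, n_id_n, n_det)
        else:
            warnings.warn(
                "no deteriorated patients: sensitivity section omitted",
                stacklevel=2,
            )

    attribution_mprt: dict[str, dict[str, float]] = {}
    if with_attribution:
        for lv in (Level.MEDIUM, Level.HIGH, Level.URGENT):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                attribution_mprt[lv.name] = attribution(confirmed, lv)

    return EvaluationReport(
        counts_mprt=counts_mprt,
        counts_news=counts_news,
        distribution_mprt=dist_mprt,
        distribution_news=dist_news,
        urgent_fraction_pct=urgent_pct,
        n_deteriorated=n_det,
        n_identified_mprt=n_id_m,
        n_identified_news=n_id_n,
        sensitivity_mprt=sens_m,
        sensitivity_news=sens_n,
        lead_mprt=lead_m,
        lead_news=lead_n,
        chi2_stat=chi2_stat,
        chi2_p=chi2_p,
        fisher_p=fisher_p,
        attribution_mprt=attribution_mprt,
    )
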