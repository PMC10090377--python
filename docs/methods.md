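# Methods

## Scoring model

Each of the nine parameters (HR, SpO₂, RR, SBP, DBP, temperature, SV, CO,
SVR) is scored against an ordered list of half-open bands [ℓ, u) carrying
integer scores 0–3, where 0 is the accepted normal range, 1 a slight
departure, and 3 a change implying immediate risk. Band tables are pure
configuration (`src/mprtws/data/*.yaml`) validated at load time to be a
disjoint, exhaustive partition of ℝ per parameter with at least one 0-band;
validation is provably equivalent to probing every value on a fine grid and
finding exactly one owning band (checked in the test suite at step 0.01 over
[−500, 5000]).

**Half-open convention.** Published charts state inclusive bounds
("≤ 90", "91–100"). Each inclusive upper bound X becomes the exclusive
bound X + r, where r is the parameter's printed resolution (1 for
integer-charted vitals, 0.1 °C for temperature). This preserves exactly the
published integer-grid behaviour while making disjointness and coverage
mechanically checkable.

**Band values.** The five NEWS parameters carry the standard published NEWS
chart bands in both tables. The four hemodynamic additions (DBP, SV, CO,
SVR) are banded around their accepted adult normal ranges (DBP 60–89 mmHg,
SV 60–99 mL, CO 4.0–7.9 L/min, SVR 800–1199 dyn·s·cm⁻⁵) with one step of
concern per score level on each side. Users evaluating a different chart
supply their own YAML; nothing in the code depends on the shipped values.

**Aggregation.** MPRT-WS: Urgent ⇔ any score 3; else High ⇔ ≥ 3 scores ≥ 2;
Medium ⇔ exactly 2 scores ≥ 2; Low otherwise. "Parameters with a value of 2"
is implemented as *score ≥ 2*: since any 3 forces Urgent, the choice only
affects mixed vectors, and ≥ 2 is the reading that keeps the level monotone
in every score (raising a score can never lower the level — a property the
suite checks exhaustively over all 4⁹ vectors). Score-1 parameters never
escalate the level, however many there are. NEWS: the five scores are
summed; High ⇔ total ≥ 7 or any single score 3; Medium ⇔ total in the
configured aggregate band, default [5, 6] (standard NEWS practice); Low
otherwise. Oxygen-supplementation and AVPU inputs are not modelled in either
tool.

**Missing data.** A missing parameter scores "missing" and counts as 0 in
aggregation; a reading missing more than `max_missing` parameters
(default 3) is unscorable, carries no level, breaks confirmation runs, and
is excluded from event counts. The threshold trades dropout tolerance
against inventing levels from too few vitals and is exposed in the API.

## Temporal confirmation

The confirmed level at reading t is the highest L such that the last
`min_consecutive` readings (t included) all have instantaneous level ≥ L and
span ≤ `max_span` minutes — equivalently the window minimum. Incomplete
windows (stream start), windows crossing a transmission gap > `max_span`,
and windows containing an unscorable reading confirm Low. Defaults
(2 readings / 10 min) match the native 5-min cadence; `min_consecutive = 1`
reproduces the instantaneous stream exactly.

At a coarser resampled cadence a literal 10-min span can never contain two
readings, so `ConfirmationPolicy.for_interval(interval)` keeps the rule at
"two consecutive readings" by setting the span to
`min_consecutive × interval`; the 15-min analyses use this policy. Urgent is
confirmed like every other level by default; a flag (`confirm_urgent=False`)
lets it fire instantly for real-time use.

An **event** is one confirmed reading at a level; episodes are not merged.
Resampling to interval Δ keeps, for each grid instant anchored at the first
reading, the nearest reading (earlier on ties), dropping duplicates.

## Evaluation

Distribution shares are per-reading confirmed event counts; the reporting
convention quotes Low/Medium/High shares over non-Urgent readings and the
Urgent share over all readings. Percentages round half-up to one decimal.
A deteriorating patient is **identified** when the first confirmed alert
(High/Urgent for MPRT-WS, High for NEWS) is strictly before the annotated
deterioration time; sensitivity = identified / deteriorated, and lead time
is the gap in hours, summarised as mean ± sample SD (ddof = 1, undefined
below two patients). Distribution comparison is a Pearson χ² homogeneity
test on the 2×k per-reading count table (no continuity correction, df =
k − 1); identification comparison is a two-sided Fisher exact test on the
2×2 identified/not × tool table; both delegate to scipy.stats and are
verified in the suite against direct Σ(O−E)²/E summation and exhaustive
hypergeometric enumeration (all equal-margin tables with margins ≤ 12).
Attribution reports, over readings confirmed at a level, the fraction in
which each parameter meets the abnormality criterion — score = 3 for the
Urgent panel, score ≥ 2 for High/Medium (both configurable); fractions need
not sum to 1. Group segmentation counts confirmed High/Urgent readings with
the parameter abnormal per patient and summarises per-group distributions
with median, quartiles (linear-interpolation percentiles), 1.5×IQR whiskers
clipped to observed points, and outliers.

## Synthetic cohorts

Each parameter is a stationary AR(1) process around a baseline:
x_t = μ_t + ρ(x_{t−1} − μ_{t−1}) + ε_t with innovations scaled so the
stationary SD equals the configured noise SD (ρ = 0.8 by default —
physiologically smooth minute-scale fluctuation). Baselines sit at textbook
mid-normal values; default noise SDs are realistic wearable magnitudes
(e.g. HR 3 bpm, SpO₂ 1 %, temperature 0.15 °C). Deterioration ramps the
affected parameters' means linearly from baseline to the midpoint of the
target score band between `onset` and `onset + ramp`, then holds; the
annotated deterioration time is `onset + ramp`. For a half-infinite target
band the "midpoint" is half the narrowest finite band-width beyond the
finite edge. Artifacts are isolated single-reading excursions to a 3-band
value with immediate return (never at adjacent readings); missingness is
i.i.d. per parameter per reading. SpO₂ is capped at 100 % and all values at
a small positive floor. Parameters are generated independently — the score
treats them as independent inputs, so the device-level coupling of CO and
SVR to pressures and flow is out of scope. Phenotype presets (CHF, CVA,
COPD, CKD, arrhythmia) name illustrative affected-parameter subsets only;
they are not clinically validated. Streams default to 24 h at 5-min cadence
(enough for >280 readings per patient and unhurried cohort-scale runs) and
accept up to 72 h, the design envelope of the monitoring setting emulated.

Everything derives from `numpy.random.default_rng` with explicit integer
seeds; cohorts spawn per-patient seeds from the master seed via
`SeedSequence([seed, index])`, so results are reproducible bit-for-bit and
patients are mutually independent.

**Closed-form alert time.** With zero noise, the time each affected
parameter enters its target band is where the linear ramp crosses the band
edge; the instantaneous level escalates at the first cadence-grid reading
after the last such crossing, and confirmation adds (k − 1) cadence steps.
Measured alerts match this prediction within one cadence step across all
phenotype presets (a descending parameter can land exactly on the exclusive
band edge at a grid instant, which defers detection by one reading — hence
the one-step tolerance).

**Study conditions for the noisy-sensitivity check.** 100 deteriorating
patients, a three-parameter hemodynamic signature (SBP falling, DBP and SVR
rising into their 2-bands) with a 4-h onset and an 8-h ramp within 24 h of
monitoring, and noise SD equal to 25 % of each affected parameter's
target-band width (`noise_from_band_width`), defaults elsewhere. The long
gradual ramp is the realistic emulation of multi-hour pre-deterioration
drift; expressing noise relative to band width makes detection difficulty
comparable across parameters with very different units.

**What passing these tests does and does not show.** The generator
reproduces the *sampling structure* the score assumes — cadence, banded
abnormality, persistence, artifacts, dropout — not real physiology: no
circadian rhythm, no treatment response, no cross-parameter correlation, no
heavy-tailed artifact bursts. Synthetic sensitivities near 1 therefore
validate the pipeline's mechanics (scoring, confirmation, identification
arithmetic), not clinical performance on real patients.

## Numerical and design choices

* Band lookup is vectorised `np.searchsorted` over interior band edges;
  equality with the scalar linear scan is asserted in the tests.
* Timestamps are minutes since stream start (real); file I/O accepts
  ISO-8601 instants and converts per patient. CSV missing markers: empty
  cell or `NA`.
* Validation errors name the offending patient, line, or parameter and
  interval.
* Reported percentages use decimal half-up rounding (not banker's), matching
  clinical report conventions.
* Empty identified sets yield mean/SD of `None` rather than NaN; empty
  cohorts raise.

## Known limitations

* The shipped nine-parameter band values are a chart transcription plus
  standard normal ranges, not a validated clinical instrument; treat them as
  defaults for methodological work.
* Confirmation operates per level on the window minimum; it does not model
  alarm silencing, escalation workflows, or episode merging.
* The simulator's independence assumptions understate the correlated
  excursions real hemodynamics produce, which would raise NEWS totals more
  than independent noise does.
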