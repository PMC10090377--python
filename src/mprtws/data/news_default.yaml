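# NEWS (National Early Warning Score) per-parameter band tables.
# Five physiological inputs; oxygen-supplementation and AVPU inputs are
# deliberately not modelled.  All bands are half-open [lower, upper): a
# published inclusive upper bound "<= X" becomes upper = X + one unit of the
# parameter's printed resolution (1 for integer-charted vitals, 0.1 degC for
# temperature).
tool: NEWS
units:
  sbp: mmHg
  hr: bpm
  rr: breaths/min
  spo2: "%"
  temp: degC
aggregate_medium: [5, 6]   # total-score band for the Medium alert level
bands:
  sbp:                      # chart: <=90 | 91-100 | 101-110 | 111-219 | >=220
    - {lower: -inf, upper: 91, score: 3}
    - {lower: 91, upper: 101, score: 2}
    - {lower: 101, upper: 111, score: 1}
    - {lower: 111, upper: 220, score: 0}
    - {lower: 220, upper: inf, score: 3}
  hr:                       # chart: <=40 | 41-50 | 51-90 | 91-110 | 111-130 | >=131
    - {lower: -inf, upper: 41, score: 3}
    - {lower: 41, upper: 51, score: 1}
    - {lower: 51, upper: 91, score: 0}
    - {lower: 91, upper: 111, score: 1}
    - {lower: 111, upper: 131, score: 2}
    - {lower: 131, upper: inf, score: 3}
  rr:                       # chart: <=8 | 9-11 | 12-20 | 21-24 | >=25
    - {lower: -inf, upper: 9, score: 3}
    - {lower: 9, upper: 12, score: 1}
    - {lower: 12, upper: 21, score: 0}
    - {lower: 21, upper: 25, score: 2}
    - {lower: 25, upper: inf, score: 3}
  spo2:                     # chart: <=91 | 92-93 | 94-95 | >=96
    - {lower: -inf, upper: 92, score: 3}
    - {lower: 92, upper: 94, score: 2}
    - {lower: 94, upper: 96, score: 1}
    - {lower: 96, upper: inf, score: 0}
  temp:                     # chart: <=35.0 | 35.1-36.0 | 36.1-38.0 | 38.1-39.0 | >=39.1
    - {lower: -inf, upper: 35.1, score: 3}
    - {lower: 35.1, upper: 36.1, score: 1}
    - {lower: 36.1, upper: 38.1, score: 0}
    - {lower: 38.1, upper: 39.1, score: 1}
    - {lower: 39.1, upper: inf, score: 2}
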