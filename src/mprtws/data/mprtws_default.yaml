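# MPRT-WS per-parameter band tables: the five NEWS vitals plus diastolic blood
# pressure, stroke volume, cardiac output and systemic vascular resistance,
# each scored 0-3.  The shared five carry the NEWS chart bands; the four
# hemodynamic additions are banded around their accepted adult normal ranges
# (DBP 60-89 mmHg, SV 60-99 mL, CO 4.0-7.9 L/min, SVR 800-1199 dyn.s.cm-5)
# with one step of concern per score level on each side.  All bands are
# half-open [lower, upper).
tool: MPRT-WS
units:
  sbp: mmHg
  dbp: mmHg
  hr: bpm
  rr: breaths/min
  spo2: "%"
  temp: degC
  sv: mL
  co: L/min
  svr: dyn.s.cm-5
bands:
  sbp:
    - {lower: -inf, upper: 91, score: 3}
    - {lower: 91, upper: 101, score: 2}
    - {lower: 101, upper: 111, score: 1}
    - {lower: 111, upper: 220, score: 0}
    - {lower: 220, upper: inf, score: 3}
  hr:
    - {lower: -inf, upper: 41, score: 3}
    - {lower: 41, upper: 51, score: 1}
    - {lower: 51, upper: 91, score: 0}
    - {lower: 91, upper: 111, score: 1}
    - {lower: 111, upper: 131, score: 2}
    - {lower: 131, upper: inf, score: 3}
  rr:
    - {lower: -inf, upper: 9, score: 3}
    - {lower: 9, upper: 12, score: 1}
    - {lower: 12, upper: 21, score: 0}
    - {lower: 21, upper: 25, score: 2}
    - {lower: 25, upper: inf, score: 3}
  spo2:
    - {lower: -inf, upper: 92, score: 3}
    - {lower: 92, upper: 94, score: 2}
    - {lower: 94, upper: 96, score: 1}
    - {lower: 96, upper: inf, score: 0}
  temp:
    - {lower: -inf, upper: 35.1, score: 3}
    - {lower: 35.1, upper: 36.1, score: 1}
    - {lower: 36.1, upper: 38.1, score: 0}
    - {lower: 38.1, upper: 39.1, score: 1}
    - {lower: 39.1, upper: inf, score: 2}
  dbp:                      # normal 60-89 mmHg
    - {lower: -inf, upper: 40, score: 3}
    - {lower: 40, upper: 50, score: 2}
    - {lower: 50, upper: 60, score: 1}
    - {lower: 60, upper: 90, score: 0}
    - {lower: 90, upper: 110, score: 1}
    - {lower: 110, upper: 120, score: 2}
    - {lower: 120, upper: inf, score: 3}
  sv:                       # normal 60-99 mL
    - {lower: -inf, upper: 30, score: 3}
    - {lower: 30, upper: 45, score: 2}
    - {lower: 45, upper: 60, score: 1}
    - {lower: 60, upper: 100, score: 0}
    - {lower: 100, upper: 120, score: 1}
    - {lower: 120, upper: 140, score: 2}
    - {lower: 140, upper: inf, score: 3}
  co:                       # normal 4.0-7.9 L/min
    - {lower: -inf, upper: 2.5, score: 3}
    - {lower: 2.5, upper: 3.5, score: 2}
    - {lower: 3.5, upper: 4.0, score: 1}
    - {lower: 4.0, upper: 8.0, score: 0}
    - {lower: 8.0, upper: 10.0, score: 1}
    - {lower: 10.0, upper: 12.0, score: 2}
    - {lower: 12.0, upper: inf, score: 3}
  svr:                      # normal 800-1199 dyn.s.cm-5
    - {lower: -inf, upper: 500, score: 3}
    - {lower: 500, upper: 650, score: 2}
    - {lower: 650, upper: 800, score: 1}
    - {lower: 800, upper: 1200, score: 0}
    - {lower: 1200, upper: 1600, score: 1}
    - {lower: 1600, upper: 2000, score: 2}
    - {lower: 2000, upper: inf, score: 3}
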