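"""Recompute the development-cohort summary statistics from their counts.

The score's development cohort (361 high-risk ward patients, 39 of whom
deteriorated) is summarised by per-reading event counts and per-patient
identification counts; every published percentage is plain arithmetic over
them.  This example recomputes each one through the package's evaluation
functions and prints it next to the published value.
"""

from mprtws.reference import REFERENCE_EXPECTED, reference_statistics

print(f"{'statistic':<34}{'recomputed':>11}{'published':>11}")
for name, payload in reference_statistics().items():
    print(
        f"{name:<34}{payload['value']:>10.1f}%{REFERENCE_EXPECTED[name]:>10.1f}%"
    )
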