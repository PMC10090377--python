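"""The persistence rule: why a single abnormal reading never alarms.

Runs the 2-consecutive-readings-in-10-minutes confirmation over two level
sequences: an isolated High spike (suppressed) and a sustained High episode
(confirmed from its second reading).  Confirmed levels are what drive event
counts and patient identification downstream.
"""

from mprtws import ConfirmationPolicy, Level, confirm

L, H = Level.LOW, Level.HIGH
policy = ConfirmationPolicy(min_consecutive=2, max_span=10.0)

for name, levels in [
    ("isolated spike ", [L, L, H, L, L, L]),
    ("sustained alert", [L, L, H, H, H, L]),
]:
    timestamps = [5.0 * i for i in range(len(levels))]
    result = confirm(levels, timestamps, policy)
    instant = " ".join(lv.name[0] for lv in levels)
    confirmed = " ".join(lv.name[0] for lv in result.levels)
    print(f"{name}: instantaneous {instant}  ->  confirmed {confirmed}")

print()
print("The spike is never confirmed (zero High events); the sustained")
print("episode yields High events from its second abnormal reading on.")
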