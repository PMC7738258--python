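"""Generate the default synthetic cohort and look at its ground truth.

Ten children, 8 consecutive nights in each of 2 months.  Bedtimes are
drawn around 21:00 (between-child habit + nightly variation), wake-ups
around 06:30 with a weekend lie-in, and each night carries a Poisson
number of brief true awakenings.
"""

import numpy as np

from actisleep import CohortConfig, generate_truth
from actisleep.timeutil import noon_of

cfg = CohortConfig(seed=1)
truths = generate_truth(cfg)

bed = [(t.bedtime - noon_of(t.night_date)).total_seconds() / 60 for t in truths]
wake = [(t.wake_time - noon_of(t.night_date)).total_seconds() / 60 for t in truths]
awak = [len(t.awakenings) for t in truths]

def clock(m):
    h, mm = divmod(int(round(m)) + 720, 60)
    return f"{h % 24:02d}:{mm:02d}"

print(f"child-nights     : {len(truths)}")
print(f"mean bedtime     : {clock(np.mean(bed))} (sd {np.std(bed):.0f} min)")
print(f"mean wake-up     : {clock(np.mean(wake))} (sd {np.std(wake):.0f} min)")
print(f"true awakenings  : {np.mean(awak):.2f} per night")
wk = [w for t, w in zip(truths, wake) if t.is_weekend]
wd = [w for t, w in zip(truths, wake) if not t.is_weekend]
print(f"weekend lie-in   : wake {clock(np.mean(wk))} vs weekday {clock(np.mean(wd))}")
print()
print("The cohort is shaped like a real toddler study: ~21:00 +/- ~37 min")
print("bedtimes, ~06:30 wake-ups, and one to two brief awakenings a night.")
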