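"""Score a single synthetic night: sleep onset, final waking, awakenings.

Builds one night of 2-minute activity intensities (evening wakefulness,
quiet sleep with two motor bursts, morning wakefulness), classifies every
epoch with the five-coefficient linear score, and prints the derived
night summary.
"""

from datetime import datetime, timedelta

import numpy as np

from actisleep import NightWindow, summarize_night_actigraphy
from actisleep.actigraph import ActivityIntensitySeries

rng = np.random.default_rng(1)
start = datetime(2024, 6, 3, 18, 0)

intensity = np.concatenate([
    rng.integers(25, 55, 95),   # 18:00-21:10 awake and active
    np.zeros(90, dtype=int),    # asleep
    [30],                       # a single motor burst
    np.zeros(80, dtype=int),
    rng.integers(25, 55, 5),    # a true awakening (10 min)
    np.zeros(105, dtype=int),
    rng.integers(25, 55, 104),  # from ~06:30 awake
])
series = ActivityIntensitySeries("demo", start, intensity)
night = NightWindow(start.date(), start, start + timedelta(minutes=2 * len(intensity)))

summary = summarize_night_actigraphy(series, night)
print(f"sleep onset      : {summary.bedtime:%H:%M}")
print(f"final waking     : {summary.wake_up:%H:%M}")
print(f"nighttime sleep  : {summary.nighttime_sleep:.0f} min")
print(f"awakenings >=6min: {summary.awakenings:.0f}")
print()
print("The onset is the start of the first 10 min of continuous sleep; the")
print("single-epoch burst is smeared into a >=6-min wake event by the")
print("5-epoch scoring window, so it counts as one awakening, as does the")
print("true 10-min awakening.")
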