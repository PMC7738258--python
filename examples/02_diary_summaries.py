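"""Diary-derived sleep parameters, including a cross-midnight night.

Night-time sleep from a diary is the bed-to-wake span minus the reported
sleep-onset latency; nights are keyed to the bedtime's calendar date so
a bedtime of 23:50 and a wake-up of 06:40 the next morning unroll onto
one monotone axis.
"""

from datetime import date, time

from actisleep import DiaryRecord, diary_to_summary

records = [
    DiaryRecord(
        child_id="child01", night_date=date(2024, 6, 7),
        bedtime=time(21, 0), wake_up=time(6, 30),
        sleep_latency_min=20, reported_awakenings=1,
    ),
    DiaryRecord(
        child_id="child01", night_date=date(2024, 6, 8),  # a Saturday night
        bedtime=time(23, 50), wake_up=time(6, 40),
        sleep_latency_min=10, reported_awakenings=0,
    ),
]

for r in records:
    s = diary_to_summary(r)
    kind = "weekend" if s.is_weekend else "weekday"
    print(
        f"{s.night_date} ({kind}): bed {s.bedtime:%H:%M}, wake {s.wake_up:%H:%M}, "
        f"sleep {s.nighttime_sleep:.0f} min, awakenings {s.awakenings:.0f}"
    )
print()
print("570 - 20 = 550 min for the first night; the second spans midnight:")
print("410 min in bed minus 10 min latency = 400 min of sleep.")
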