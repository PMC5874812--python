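"""Replay a delivery event by event and confirm the closed-form total.

The discrete-event simulator schedules every beam-on/off, leaf command,
and gantry rotation.  Its final event time must equal the closed-form
prediction — that agreement is the package's internal verification of the
MLC and sequencing models.
"""

import datetime as dt

from cobaltime import SourceCalibration, generate_plan, predict, simulate

calibration = SourceCalibration(
    reference_dose_rate={1: 1.55, 2: 1.54, 3: 1.56},
    reference_date=dt.date(2026, 1, 1),
)
date = dt.date(2026, 6, 1)
plan = generate_plan(seed=2, n_groups=2, heads_per_group_range=(2, 3))

events, end_s = simulate(plan, calibration, date)
print("first events:")
for e in events[:8]:
    print(f"  {e.time_s:9.3f} s  head {e.head:>6}  {e.kind:<14} {e.detail}")
print(f"  ... {len(events)} events total")

predicted_s = predict(plan, calibration, date).t_total_min * 60.0
print(f"\nsimulated end: {end_s:.6f} s")
print(f"predicted:     {predicted_s:.6f} s")
print(f"difference:    {abs(end_s - predicted_s):.2e} s (closed form == replay)")
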