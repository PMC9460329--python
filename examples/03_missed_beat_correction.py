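"""The missed-beat correction rules on hand-sized inputs.

Walks through the two core primitives: the median-harmonics rule on the
70/32/73 bpm triplet (one missed beat read as a period at twice the median)
and the bucketing algorithm's index/majority/harmonic-folding machinery.
"""

import numpy as np

import bandevents as be
from bandevents.compensation import BucketState, bucket_hr, bucket_update

# --- median harmonics: 70, 32, 73 bpm -> the 32 is one missed beat --------
history = [60.0 / 70.0] * 30                    # 30 beats at 70 bpm
outlier = 60.0 / 32.0                           # 1.875 s period = 32 bpm
ps = be.PeriodSeries(times=np.cumsum(history + [outlier]),
                     periods=np.array(history + [outlier]))
out = be.median_compensate(ps)
print(f"median harmonics: 32 bpm outlier -> {60 / out.periods[0]:.1f} bpm "
      f"(period {outlier:.3f} s / 2 = {out.periods[0]:.4f} s)")

# --- bucketing: index, majority, harmonic folding -------------------------
print(f"bucket index for a 0.67 s period: {be.bucket_index(0.67)} "
      f"(first threshold >= 0.67 is 0.7 s)")

state = BucketState()
for p in [0.70] * 24 + [1.40] * 6:              # 6 doubled periods = missed beats
    bucket_update(state, p)
maj = be.bucket_majority(state)
print(f"majority: rule={maj.rule}, bucket mean {maj.mean_period_s:.2f} s")
print(f"bucketing HR with harmonic folding: {bucket_hr(state):.2f} bpm "
      f"(the 1.4 s bucket re-enters at 1.4/2 = 0.7 s)")
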