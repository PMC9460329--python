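"""Estimate HR and RR from a synthetic recording with known rates.

Compares the three missed-beat compensation algorithms (median harmonics,
bucketing, windowed k-means) against the generator's true 85 beats/min, and
breath-to-breath RR against the true 17.4 breaths/min.
"""

import numpy as np

import bandevents as be

cfg = be.SyntheticConfig(duration_s=600.0, seed=1, rr_mean=17.4, rr_sd=0.0,
                         hr_mean=85.0, hr_sd=0.0, pulse_dropout_prob=0.3)
res = be.analyze(be.PipelineConfig(synthetic=cfg))

print(f"{len(res.periods)} cardiac event periods; naive mean-period HR = "
      f"{be.naive_mean_hr(res.periods):.1f} bpm (biased low: every missed "
      f"beat doubles a period)")

for method in ("median", "bucket", "kmeans"):
    hr = be.hr_series(res.periods, method)
    err = np.abs(hr.rates - 85.0)
    print(f"{method:>7s}: {len(hr):4d} estimates, mean {hr.rates.mean():6.2f} bpm, "
          f"MAE vs truth {err.mean():.2f} bpm")

truth_rr = be.RateSeries(res.truth.breath_peak_times[1:],
                         60.0 / np.diff(res.truth.breath_peak_times), kind="RR")
stats = be.rate_error(res.rr, truth_rr)
print(f"     RR: {len(res.rr):4d} breath-to-breath estimates, mean "
      f"{res.rr.rates.mean():.2f} breaths/min, MAE {stats.mean_abs:.3f}")
print("Compensation recovers the true rates although ~45% of beats never "
      "reach the event stream.")
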