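"""Track heart rate through a 20-minute stationary-bike session.

The synthetic protocol rests for 10 min (~72 BPM), pedals to ~155 BPM, and
recovers; both HR estimators should follow the trajectory closely.  Prints
the mean absolute error of each estimator against the ground-truth HR and a
small table of HR values along the session.
"""

import numpy as np

from roma_ppg import SynthConfig, generate, process_record

synth = generate(SynthConfig(seed=42))  # defaults: 20 min bike protocol, 46.3 Hz
result = process_record(synth.record)

truth = np.interp(result.hr_time.times, synth.truth_hr.times, synth.truth_hr.hr)
keep = ~result.beats.outlier_mask
mae_time = np.mean(np.abs(result.hr_time.hr[keep] - truth[keep]))
mae_freq = np.mean(np.abs(result.hr_freq.hr[keep] - truth[keep]))

print(f"{result.beats.peak_times.size} beats detected, "
      f"{100 * result.beats.outlier_fraction:.2f}% flagged as outliers")
print(f"time-domain  MAE vs truth: {mae_time:.2f} BPM")
print(f"freq-domain  MAE vs truth: {mae_freq:.2f} BPM\n")

print("  t (min)   truth    time-HR   freq-HR")
for minute in (2, 8, 11, 14, 17):
    i = np.argmin(np.abs(result.hr_time.times - 60.0 * minute))
    print(f"   {minute:4d}    {truth[i]:6.1f}   {result.hr_time.hr[i]:7.1f}  "
          f"{result.hr_freq.hr[i]:8.1f}")
print("\nBoth estimators follow the rest-exercise-recovery trajectory; the")
print("frequency branch lags slightly during the ramp (30 s analysis window).")
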