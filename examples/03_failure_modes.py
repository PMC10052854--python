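"""Why imaging sessions fail: movement and wet patches.

The study's failed validations were dominated by animal movement and by
wet or obstructed thermal windows.  This script degrades the worked-example
clip with those artifacts and shows the clear-peak criterion correctly
refusing to report a heart rate, instead of inventing one.
"""

from thermovitals import measure_hr, measure_rr
from thermovitals.synthetic import SynthParams, degrade, generate_clip

seq, truth = generate_clip(SynthParams(seed=7))
rr_est, _ = measure_rr(seq, truth.window_roi)
hr_good, peak_good = measure_hr(seq, truth.window_roi, rr_est.source_freq)
print(f"intact clip:    HR {hr_good.rate_per_min:.1f} bpm "
      f"(prominence {peak_good.prominence_ratio:.1f}x, clear)")

wet = degrade(seq, "wet_patch", roi=truth.window_roi)
hr_wet, peak_wet = measure_hr(wet, truth.window_roi, rr_est.source_freq)
print(f"wet window:     HR {'-' if hr_wet is None else hr_wet.rate_per_min} "
      f"(prominence {peak_wet.prominence_ratio:.1f}x, clear={peak_wet.clear})")

diameter = 2 * 0.35 * seq.frame_shape[1]  # body-ellipse diameter in px
shaky = degrade(seq, "motion", amplitude_px=diameter / 4, seed=5)
rr_shaky, peak_rr = measure_rr(shaky, truth.window_roi)
hr_shaky, peak_shaky = measure_hr(shaky, truth.window_roi, peak_rr.freq)
print(f"heavy jitter:   HR {'-' if hr_shaky is None else hr_shaky.rate_per_min} "
      f"(prominence {peak_shaky.prominence_ratio:.1f}x, clear={peak_shaky.clear})")
print("A missing value here is the correct answer: the method does not pull")
print("false signals out of motion-contaminated or signal-free video.")
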