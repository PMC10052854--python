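"""What Eulerian magnification actually does to an in-band signal.

A noise-free clip with a 0.63 Hz body modulation of known amplitude is
magnified at gain 40 with the wide passband.  The body-ROI trace amplitude
is measured by sinusoid regression before and after: the in-band component
comes out amplified by (1 + alpha) = 41, out-of-band content (and a clip
magnified at alpha = 0) is untouched.
"""

import numpy as np

from thermovitals import MagnifyConfig, Passband, extract_trace, magnify
from thermovitals.synthetic import SynthParams, generate_clip

seq, truth = generate_clip(SynthParams(a_card=0.0, noise_sd=0.0, seed=0))
band = Passband(0.1, 3.5)

t = np.arange(seq.n_frames) / seq.fps
basis = np.c_[np.cos(2 * np.pi * 0.63 * t), np.sin(2 * np.pi * 0.63 * t), np.ones_like(t)]


def amplitude(s):
    coef, *_ = np.linalg.lstsq(basis, extract_trace(s, truth.body_roi).values, rcond=None)
    return np.hypot(coef[0], coef[1])


a0 = amplitude(seq)
a40 = amplitude(magnify(seq, MagnifyConfig(alpha=40.0, band=band)))
ident = magnify(seq, MagnifyConfig(alpha=0.0, band=band))

print(f"body-trace modulation amplitude, raw clip:      {a0:.3f} intensity units")
print(f"body-trace modulation amplitude, magnified 40x: {a40:.3f}")
print(f"measured gain: {a40 / a0:.2f}  (theory: 1 + alpha = 41)")
print(f"alpha=0 reproduces the input exactly: max|diff| = "
      f"{np.abs(ident.frames - seq.frames).max():.2e}")
print("This 41x boost is what turns a sub-visible 4-unit temperature wobble into")
print("an unmistakable spectral line while leaving out-of-band content alone.")
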