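# Methods

## Signal model

A thermal camera reports per-pixel surface radiance in arbitrary
instrument units at a fixed frame rate (nominally 30 Hz, 464×348 px for
the validated hardware; the math is resolution-agnostic). Breathing
modulates the bulk surface temperature of the torso at the respiration
frequency *f*<sub>RR</sub>; cardiac pulsation modulates skin temperature
much more weakly and only where major vessels run close to the surface —
the "thermal windows" (temple, inner leg, groin). Both modulations are
far below sensor noise in a raw frame-to-frame difference but are
narrowband, which is what the amplification exploits. Absolute radiometric
calibration is irrelevant: every statistic used downstream is invariant to
affine rescaling of intensity.

## Eulerian magnification

`magnify` implements linear (intensity) EVM:

1. **Spatial decomposition.** A Gaussian pyramid with the fixed 5-tap
   binomial kernel (1,4,6,4,1)/16, blur-then-decimate; default depth
   ⌊log₂ min(H,W)⌋ − 3, leaving ≥ 8 px per side at the coarsest level.
   Internally the corresponding Laplacian (difference-of-Gaussians)
   pyramid is formed with a normalized zero-insertion upsampler
   (renormalized by the filter response to a ones image, so constants are
   reproduced exactly even at frame edges). Collapsing an unmodified
   Laplacian pyramid is exact by construction, which gives two properties
   the tests rely on: α = 0 reproduces the input to float precision, and
   a spatially smooth in-band signal is amplified by exactly (1 + α)
   rather than once per level (a Gaussian-level upsample-and-sum would
   multiply-count it). The pyramid variant is isolated behind one
   function (`_laplacian_levels`) so an alternative decomposition can be
   swapped without touching the rest.
2. **Temporal filtering.** An ideal frequency-domain mask along the time
   axis: FFT, zero every bin outside [f_lo, f_hi], inverse FFT, real
   part. This filter is linear and *exactly* idempotent, which we
   prioritized over mirror-padding the time axis (padding-then-cropping
   breaks idempotence at the 1e−9 tolerance the invariant demands, and on
   9–30 s clips the edge ringing it would suppress does not move the
   spectral argmax the pipeline reads out).
3. **Amplification.** Every Laplacian level except the full-resolution
   detail level is bandpassed and added back scaled by α (α/2 at the
   finest amplified level when `attenuate_edges`, the default — the
   finest levels carry mostly pixel noise). Defaults: α = 40 for thermal
   video; 200 is the setting used for RGB color amplification.

## Spectral readout

The ROI trace is the per-frame unweighted ROI mean with the clip mean
subtracted. Its magnitude spectrum is computed by zero-padded real FFT on
a grid no coarser than 0.01 Hz: a 9 s clip natively resolves only 0.11 Hz,
and padding (rather than parabolic interpolation) is how frequencies like
0.63 Hz become representable; it is simpler and directly testable.
Zero-padding interpolates the continuous spectrum of the windowed trace;
it does not add information, so precision claims are always checked by
simulation.

`dominant_peak` takes the in-band argmax, guarded below 0.05 Hz (DC/drift
guard). Its clarity measure, the **prominence ratio**, is the peak
magnitude divided by the median in-band magnitude *outside the peak's own
main lobe* (±1.5 native resolution widths). Excluding the main lobe
matters: with a 1 Hz narrow band and a 9 s window, the lobe occupies
~20% of the band and a self-inflated median made the ratio hover near
threshold for clean tones. A peak is *clear* when the ratio ≥ 4.0. That
threshold was chosen so that pure white-noise traces produce a false
"clear" peak in ≤ 5% of seeds (measured ≤ 0.5% over 200 seeds); genuine
single tones at the default synthetic SNR sit at ratios ≈ 5–60.

**Resolvability guard.** A clear peak must also complete ≥ 1.5 cycles in
the analysis window (`RunConfig.min_cycles`). Less than that is
indistinguishable from drift: a 0.05 Hz tone observed for 9 s otherwise
leaks a confidently wrong peak at ~0.11 Hz. With the guard, a 9 s window
can call rates ≥ 10 breaths/min; slower breathers are deferred to the
30 s fallback window, where the search band is also extended down to the
DC guard so very low rates (2–6 breaths/min, tortoise/bear territory) can
be identified. The 30 s window still holds only 1.5 cycles of a 3
breaths/min signal, so at the very bottom of the range the estimate is
detected but only ±1–1.5 breaths/min accurate — a physics limit, not an
implementation one.

**Narrow-band placement.** The cardiac band is [f_lo, f_lo + 1] Hz with
f_lo the smallest multiple of 0.5 Hz at or above *f*<sub>RR</sub> + 0.35 Hz
(RR 0.6 Hz → 1–2 Hz). The 0.35 Hz margin and 0.5 Hz snapping reproduce
the single documented worked placement and guarantee the respiration
frequency is excluded; both are heuristics and configurable. If the
snapped edge would exceed the 3.5 Hz ceiling an un-snapped band adjacent
to the respiration peak is used and a warning is raised — no validated
case required it. Respiration harmonics that fall inside the narrow band
are *not* notched by default (matching the validated procedure); a pure
sinusoidal generator has no harmonics, so the synthetic tests cannot
exercise that risk — see Limitations.

## Synthetic clips

`generate_clip` renders: background 20, elliptical body +60, an ~8×8 px
thermal-window patch +40 (arbitrary units ≈ an 8-bit thermal export);
body-wide respiration modulation a_resp·sin(2π f_resp t) and window-only
cardiac modulation a_card·sin(2π f_card t + φ) with φ seed-drawn (results
must not and do not depend on it); i.i.d. Gaussian sensor noise; optional
sub-pixel linear-interpolation drift and background flicker. Defaults are
the worked-example conditions: f_resp = 0.63 Hz, f_card = 1.64 Hz, 30
frames/s, 9 s, a_resp = 4, a_card = 1.2 (the cardiac signal is the weaker
one — that is why magnification is needed), noise_sd = 0.8, i.e.
SNR ≡ a_resp/noise_sd = 5. `degrade` adds the observed failure modes:
random-walk jitter (motion), a time-frozen reflective patch (wet fur), and
periodic dark stripes (enclosure bars).

`sample_session_params` draws recovery-ensemble sessions: f_resp uniform
on 0.1–1.2 Hz (6–72 breaths/min) and f_card uniform inside the narrow
band the pipeline will search, intersected over RR ± 0.02 Hz because a
respiration frequency within measurement resolution of a 0.5 Hz snapping
boundary makes the band placement ambiguous by half a step. That
conditioning mirrors the imaging protocol itself, which presumes the
heart rate lies in the chosen band; heart rates below RR + 0.35 Hz
(e.g. a large ratite's 0.67 Hz heart beat over 0.18 Hz breathing) are
outside what the documented placement rule can see. Slow breathers get
30 s clips so the fallback path is exercised.

What the generator does **not** emulate: respiration harmonics and
non-sinusoidal waveforms, fur/feather texture, radiometric drift of the
sensor, rate variability within a clip, anatomically realistic geometry,
and correlated (non-white) sensor noise. Passing the recovery tests
therefore shows the pipeline correctly inverts its own forward model at
realistic SNR — not that it handles every property of real animals.
Problem sizes were chosen to keep the whole suite desk-scale: 64×64 px
clips, 50-session ensembles, 200-seed noise calibrations.

## Session workflow

Per session: clips scoring ≤ 3 on the 8-point checklist are excluded
(quality is human-scored metadata; automating it from pixels is a
non-goal); each remaining clip is trimmed to 9 s (half-open windows,
0-based, floor(duration×fps) frames); wide pass, then narrow pass only if
a respiration peak exists (the narrow band is defined relative to RR, so
`hr_success ⇒ rr peak existed` is a structural invariant); the session
estimate is taken from the clip with the highest peak prominence, with a
multi-site agreement flag when several ROIs yield clear RR within
1 breath/min. Aggregation by maximum prominence is this package's rule —
the validated study reported one value per session without stating how
site disagreements were resolved.

## Validation statistics

Computed from the packaged 58-session transcription (`data/table1.csv`;
uncertain cells are flagged in `transcription_notes`, never silently
guessed — see that file and `data/README.md`):

* Paired errors: MAE = mean |IRT − true|; MAPE uses the true value as
  denominator, excluding non-positive true values. Heart-rate MAE is
  reported both with and without the one flagged extreme bird value
  (51.8 bpm error), because the published error summary singles it out
  without stating whether it entered the mean; the two variants bracket
  the published 2.6 bpm.
* Paired t on d = true − IRT (the sign convention that reproduces the
  published negative respiration t), two-tailed, n−1 df; implemented in
  closed form and cross-checked against `scipy.stats.ttest_rel`.
* OLS of IRT on true (statsmodels), residuals retained for by-group
  summaries; subsets: all taxa and mammals-only.
* Chi-squared: Pearson 2×2 **without** Yates continuity correction — the
  convention verified to reproduce the published 6.200, 4.860 and 13.974
  from the group sizes and percentages in `data/table2.csv`
  (counts = round(n·pct/100)); cross-checked against
  `scipy.stats.chi2_contingency(correction=False)`. The implied-count
  route is used for these tests because the per-session tallies and the
  published group table disagree by one heart-rate success (23 vs 24) —
  an internal inconsistency of the source, documented rather than
  reconciled. Known irreproducibilities, reported as computed: the
  subcutaneous-fat margin (9/35 here vs published 10/34), the published
  fat×HR chi-squared (25.615 is not obtainable from its own implied
  counts), and the published "average percent error" values (4.4% / 1.3%),
  which are inconsistent with the published MAEs under any standard MAPE
  definition.
* "Success" means a clear IRT peak was extracted, independent of whether
  a reference value exists (one session has a derived heart rate whose
  stethoscope reading failed); the group-table universe is the 44
  sessions with any reference measurement.

## Degenerate inputs and numerical choices

Frames must be finite, ≥ 2 per clip, uniform in size; ROIs ≥ 4 px and in
bounds; traces ≥ 8 samples; bandpass edges validated against Nyquist;
zero-variance difference vectors and constant regressors raise instead of
returning NaN. Spectral ties are broken by `argmax` (lowest frequency
wins); a flat spectrum reports prominence 1 and is never clear. Float
TIFF output round-trips pixel values losslessly; 16-bit PNG output
records its affine scale in the JSON sidecar.

## Limitations

Phase-based motion magnification is out of scope (the RGB motion arm of
the validation found no cardiac signal). Thermal-window detection and
tracking is manual (ROIs are inputs). Respiration-harmonic contamination
of the narrow band is possible on real, non-sinusoidal breathing and is
only addressed by the optional harmonic notch (±0.05 Hz around integer
multiples of the respiration frequency, `RunConfig.harmonic_notch`),
which is off by default to match the validated procedure. Real-data success rates depend on animal
integument, fat, movement and wetness in ways the synthetic generator
only caricatures; the packaged statistics quantify those effects for the
validated species set.
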