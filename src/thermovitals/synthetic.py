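"""Seeded synthetic thermal clips with known vital-rate ground truth.

The generator emulates the scene the vital-sign pipeline faces: a warm
elliptical body on a cooler background, whose mean intensity is modulated
at the respiration frequency, plus a small high-intensity "thermal window"
patch (the temple/inner-leg analogue) carrying a much weaker modulation at
the cardiac frequency.  Additive Gaussian sensor noise, optional sub-pixel
global drift, and optional background flicker provide the main real-world
nuisances.  Intensities are in arbitrary instrument units; the default
scene uses a background of 20, a body contrast of 60, and a window
contrast of 40 on top of the body, roughly an 8-bit thermal export.

Default modulation frequencies are the worked-example gray-seal values
(0.63 Hz respiration, 1.64 Hz cardiac) at 30 frames/s for 9 s.  The
default cardiac amplitude is below the respiration amplitude - the cardiac
signal is the one that needs magnification - and the default noise level
sets a_resp/noise_sd = 5.

:func:`degrade` applies the empirically observed failure modes (animal
movement, a wet low-emissivity patch, enclosure bars) so that tests can
check the clear-peak criterion *fails* when it should.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.ndimage import shift as nd_shift

from .io_video import FrameSequence, Rect

__all__ = [
    "SynthParams",
    "GroundTruth",
    "generate_clip",
    "degrade",
    "sample_session_params",
]

BACKGROUND_LEVEL = 20.0
BODY_CONTRAST = 60.0
WINDOW_CONTRAST = 40.0


@dataclass(frozen=True)
class SynthParams:
    """Scene and signal parameters for one synthetic clip.

    Frequencies are in Hz, amplitudes and noise in intensity units, drift
    in px/s.  Invariants: 0 < f_resp < f_card < fps/2, a_card <= a_resp,
    duration_s >= 2/f_resp (at least two respiration cycles).
    """

    f_resp: float = 0.63
    a_resp: float = 4.0
    f_card: float = 1.64
    a_card: float = 1.2
    noise_sd: float = 0.8
    drift_px_per_s: float = 0.0
    background_flicker_sd: float = 0.0
    width: int = 64
    height: int = 64
    fps: float = 30.0
    duration_s: float = 9.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.f_resp < self.f_card:
            raise ValueError("need 0 < f_resp < f_card")
        if self.f_card >= self.fps / 2:
            raise ValueError("f_card must be below Nyquist (fps/2)")
        if self.a_card > self.a_resp:
            raise ValueError("a_card must not exceed a_resp")
        if self.noise_sd < 0 or self.background_flicker_sd < 0:
            raise ValueError("noise levels must be non-negative")
        if self.duration_s < 2 / self.f_resp:
            raise ValueError("duration_s must cover at least two respiration cycles")
        if min(self.width, self.height) < 32:
            raise ValueError("frame must be at least 32x32 px")

    @property
    def snr(self) -> float:
        return np.inf if self.noise_sd == 0 else self.a_resp / self.noise_sd


@dataclass(frozen=True)
class GroundTruth:
    """True per-minute rates and the ROIs where the signals live."""

    rr_true: float
    hr_true: float
    window_roi: Rect
    body_roi: Rect


def _scene_masks(p: SynthParams) -> tuple[np.ndarray, np.ndarray, Rect, Rect]:
    yy, xx = np.mgrid[0 : p.height, 0 : p.width]
    cy, cx = p.height / 2.0, p.width / 2.0
    ry, rx = 0.42 * p.height, 0.35 * p.width
    body = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0

    ww = wh = max(8, p.width // 8)
    wx = int(cx - ww / 2)
    wy = int(cy - 0.22 * p.height)  # upper-body thermal window
    window = np.zeros_like(body)
    window[wy : wy + wh, wx : wx + ww] = True
    window &= body

    # inscribed rectangle, shrunk so every pixel lies inside the ellipse
    body_roi = Rect(int(cx - 0.65 * rx), int(cy - 0.65 * ry), int(1.3 * rx), int(1.3 * ry))
    return body.astype(float), window.astype(float), Rect(wx, wy, ww, wh), body_roi


def generate_clip(p: SynthParams) -> tuple[FrameSequence, GroundTruth]:
    """Render a seeded clip; identical parameters give bit-identical arrays.

    The body-mask mean intensity is modulated by ``a_resp*sin(2*pi*f_resp*t)``
    and the window patch additionally by ``a_card*sin(2*pi*f_card*t + phi)``
    with phi drawn from the seeded RNG (results must not depend on it).
    """
    rng = np.random.default_rng(p.seed)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    body, window, window_roi, body_roi = _scene_masks(p)
    n = int(round(p.duration_s * p.fps))
    t = np.arange(n) / p.fps

    resp = p.a_resp * np.sin(2 * np.pi * p.f_resp * t)
    card = p.a_card * np.sin(2 * np.pi * p.f_card * t + phi)

    static = BACKGROUND_LEVEL + BODY_CONTRAST * body + WINDOW_CONTRAST * window
    frames = (
        static[None, :, :]
        + resp[:, None, None] * body[None, :, :]
        + card[:, None, None] * window[None, :, :]
    )

    if p.background_flicker_sd > 0:
        flicker = rng.normal(0.0, p.background_flicker_sd, size=n)
        frames = frames + flicker[:, None, None] * (1.0 - body)[None, :, :]

    if p.drift_px_per_s != 0.0:
        offsets = p.drift_px_per_s * t
        frames = np.stack(
            [
                nd_shift(frames[k], (0.0, offsets[k]), order=1, mode="nearest")
                for k in range(n)
            ]
        )

    if p.noise_sd > 0:
        frames = frames + rng.normal(0.0, p.noise_sd, size=frames.shape)

    seq = FrameSequence(frames, fps=p.fps, origin_label=f"synthetic(seed={p.seed})")
    truth = GroundTruth(
        rr_true=60.0 * p.f_resp,
        hr_true=60.0 * p.f_card,
        window_roi=window_roi,
        body_roi=body_roi,
    )
    return seq, truth


def sample_session_params(rng: np.random.Generator, snr: float = 5.0) -> SynthParams:
    """Draw one synthetic session spanning the validated vital-rate ranges.

    Respiration is uniform over 0.1-1.2 Hz (6-72 breaths/min); the cardiac
    frequency is drawn inside the narrow passband the pipeline will search.
    Because that band's lower edge snaps to 0.5 Hz steps, a respiration
    frequency within measurement resolution of a snapping boundary makes
    the band placement ambiguous by half a step, so the cardiac draw is
    confined to the intersection of the bands implied by RR +/- 0.02 Hz
    (the cardiac search presumes the heart rate lies in the selected band -
    the same design condition the imaging protocol relies on).  Slow
    breathers (under 1.5 cycles in 9 s) get 30 s clips so the fallback
    window applies.  ``snr`` sets a_resp/noise_sd.
    """
    from .spectral import select_narrow_band

    f_resp = rng.uniform(0.1, 1.2)
    lo = select_narrow_band(f_resp + 0.02).f_lo
    hi = select_narrow_band(max(f_resp - 0.02, 0.0)).f_lo + 1.0
    f_card = rng.uniform(lo + 0.1, hi - 0.1)
    # slow breathers, including those within measurement resolution of the
    # 9 s resolvability limit, get clips long enough for the 30 s fallback
    duration = 9.0 if f_resp >= 1.5 / 9.0 + 0.02 else 30.0
    a_resp = 4.0
    return SynthParams(
        f_resp=f_resp,
        f_card=f_card,
        a_resp=a_resp,
        a_card=1.2,
        noise_sd=a_resp / snr,
        duration_s=max(duration, 2.0 / f_resp),
        seed=int(rng.integers(2**31)),
    )


def degrade(
    seq: FrameSequence,
    mode: str,
    amplitude_px: float = 8.0,
    roi: Optional[Rect] = None,
    covered_fraction: float = 0.25,
    seed: int = 0,
) -> FrameSequence:
    """Apply a named acquisition artifact to a copy of the clip.

    ``motion``: random-walk camera/animal jitter, scaled so the maximum
    excursion equals ``amplitude_px`` (sub-pixel, linear interpolation, so
    motion contaminates the spectrum smoothly).
    ``wet_patch``: the ``roi`` (default: center patch) is frozen to a
    constant high value - a reflective wet area carrying no physiological
    signal.
    ``occlusion_bars``: periodic dark vertical stripes covering
    ``covered_fraction`` of the width; a zero fraction is the identity.
    """
    h, w = seq.frame_shape
    frames = seq.frames.copy()
    if mode == "motion":
        rng = np.random.default_rng(seed)
        walk = np.cumsum(rng.normal(0.0, 1.0, size=(seq.n_frames, 2)), axis=0)
        peak = np.abs(walk).max()
        if peak > 0:
            walk *= amplitude_px / peak
        frames = np.stack(
            [
                nd_shift(frames[k], (walk[k, 0], walk[k, 1]), order=1, mode="nearest")
                for k in range(seq.n_frames)
            ]
        )
    elif mode == "wet_patch":
        if roi is None:
            roi = Rect(w // 2 - w // 8, h // 2 - h // 8, w // 4, h // 4)
        ys, xs = roi.slices()
        frames[:, ys, xs] = frames[:, ys, xs].max()
    elif mode == "occlusion_bars":
        if not 0 <= covered_fraction <= 1:
            raise ValueError("covered_fraction must be in [0, 1]")
        if covered_fraction > 0:
            period = 8
            bar = max(1, int(round(period * covered_fraction)))
            floor = frames.min()
            for x0 in range(0, w, period):
                frames[:, :, x0 : x0 + bar] = floor
    else:
        raise ValueError(f"unknown degradation mode {mode!r}")
    return FrameSequence(frames, seq.fps, origin_label=f"{seq.origin_label}+{mode}")
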