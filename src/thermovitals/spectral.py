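"""From magnified clips to vital-rate estimates.

A region of interest (ROI) placed on the area of highest thermal signature
is reduced to a single normalized intensity trace (per-frame ROI mean with
the clip mean subtracted).  The trace is Fourier-decomposed on a
zero-padded grid fine enough (default 0.01 Hz) that rates printed to two
decimals in Hz are representable from a 9 s clip, and the dominant peak in
the searched passband is taken as the physiological frequency:
rate [per minute] = 60 * frequency [Hz].

A peak is *clear* when its magnitude exceeds ``clear_threshold`` times the
median in-band magnitude.  The default threshold of 4.0 keeps the false
"clear peak" rate on white noise below 5% (checked by a Monte-Carlo
calibration test) while passing genuine single-tone signals easily.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .evm import Passband
from .io_video import FrameSequence, Rect

__all__ = [
    "IntensityTrace",
    "Spectrum",
    "PeakEstimate",
    "VitalEstimate",
    "NarrowBandFallbackWarning",
    "DC_GUARD_HZ",
    "extract_trace",
    "spectrum",
    "dominant_peak",
    "freq_to_rate",
    "select_narrow_band",
]

#: Spectral bins below this frequency are never searched (DC / drift guard).
DC_GUARD_HZ = 0.05


class NarrowBandFallbackWarning(UserWarning):
    """The snapped narrow passband would exceed the ceiling; an un-snapped
    band adjacent to the respiration peak is used instead."""


@dataclass
class IntensityTrace:
    """Normalized mean-ROI intensity per frame (dimensionless), zero mean."""

    values: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1 or self.values.size < 8:
            raise ValueError("trace must be 1-D with length >= 8")
        if not self.fps > 0:
            raise ValueError("fps must be positive")

    @property
    def duration_seconds(self) -> float:
        return self.values.size / self.fps


@dataclass
class Spectrum:
    """One-sided magnitude spectrum on a uniform grid from 0 to fps/2.

    ``resolution`` is the (zero-padded) grid spacing; ``native_resolution``
    is 1/duration of the underlying trace, which sets the width of a
    spectral line's main lobe.
    """

    freqs: np.ndarray
    magnitude: np.ndarray
    resolution: float
    native_resolution: Optional[float] = None


@dataclass
class PeakEstimate:
    """Dominant spectral frequency with magnitude and a clarity measure.

    ``prominence_ratio`` is peak magnitude over the median in-band
    magnitude; ``clear`` operationalizes the qualitative "clear peak"
    success criterion.
    """

    freq: float
    magnitude: float
    prominence_ratio: float
    clear: bool


@dataclass
class VitalEstimate:
    """A per-minute vital rate and the spectral frequency it came from."""

    rate_per_min: float
    source_freq: float
    kind: str  # "RR" or "HR"


def extract_trace(seq: FrameSequence, roi: Rect) -> IntensityTrace:
    """Per-frame unweighted ROI mean, normalized by subtracting the clip mean."""
    h, w = seq.frame_shape
    if not roi.within(h, w):
        raise ValueError(f"ROI {roi} outside {h}x{w} frame")
    if roi.area < 4:
        raise ValueError("ROI area must be >= 4 px")
    ys, xs = roi.slices()
    values = seq.frames[:, ys, xs].mean(axis=(1, 2))
    return IntensityTrace(values - values.mean(), seq.fps)


def spectrum(trace: IntensityTrace, pad_to_resolution: float = 0.01) -> Spectrum:
    """Magnitude of the real-input FFT of the zero-padded trace.

    Zero padding only refines the grid (``pad_to_resolution`` must not be
    coarser than the native fps/length resolution); it interpolates the
    underlying continuous spectrum so that peak positions are read off a
    fine grid rather than the coarse 1/duration bins of a short clip.
    """
    n = trace.values.size
    native = trace.fps / n
    if pad_to_resolution > native + 1e-12:
        raise ValueError(
            f"pad_to_resolution {pad_to_resolution} Hz is coarser than native {native:.4f} Hz"
        )
    n_pad = int(math.ceil(trace.fps / pad_to_resolution))
    spec = np.abs(np.fft.rfft(trace.values, n=n_pad))
    freqs = np.fft.rfftfreq(n_pad, d=1.0 / trace.fps)
    return Spectrum(
        freqs=freqs,
        magnitude=spec,
        resolution=trace.fps / n_pad,
        native_resolution=native,
    )


def dominant_peak(
    sp: Spectrum,
    band: Passband,
    clear_threshold: float = 4.0,
    exclude: Sequence[tuple[float, float]] = (),
) -> PeakEstimate:
    """Argmax of the spectrum magnitude within the band (DC-guarded).

    The prominence ratio is the peak magnitude divided by the median
    in-band *background* magnitude — bins inside the peak's own main lobe
    (width set by the native 1/duration resolution) are excluded from the
    median so a genuine line is compared against what surrounds it, not
    against itself.  The peak is clear when the ratio meets
    ``clear_threshold``.  ``exclude`` lists [lo, hi] frequency intervals
    (e.g. respiration harmonics) removed from the search and background.
    """
    lo = max(band.f_lo, DC_GUARD_HZ)
    mask = (sp.freqs >= lo - 1e-9) & (sp.freqs <= band.f_hi + 1e-9)
    for xlo, xhi in exclude:
        mask &= ~((sp.freqs >= xlo - 1e-9) & (sp.freqs <= xhi + 1e-9))
    if not mask.any():
        raise ValueError(f"band [{band.f_lo}, {band.f_hi}] Hz empty after DC guard")
    mags = sp.magnitude[mask]
    freqs = sp.freqs[mask]
    i = int(np.argmax(mags))
    peak_mag = float(mags[i])
    background = mags
    if sp.native_resolution is not None:
        outside_lobe = np.abs(freqs - freqs[i]) > 1.5 * sp.native_resolution
        if outside_lobe.any():
            background = mags[outside_lobe]
    med = float(np.median(background))
    if med > 0:
        ratio = peak_mag / med
    else:
        ratio = math.inf if peak_mag > 0 else 1.0
    return PeakEstimate(
        freq=float(freqs[i]),
        magnitude=peak_mag,
        prominence_ratio=ratio,
        clear=ratio >= clear_threshold,
    )


def freq_to_rate(f: float) -> float:
    """Convert a frequency in Hz to a per-minute rate (60*f), unrounded."""
    if f < 0:
        raise ValueError("frequency must be non-negative")
    return 60.0 * f


def select_narrow_band(
    rr_freq: float,
    width: float = 1.0,
    margin: float = 0.35,
    ceiling: float = 3.5,
) -> Passband:
    """Place the 1 Hz-wide cardiac search band above the respiration peak.

    The lower edge is the smallest multiple of 0.5 Hz at or above
    ``rr_freq + margin``, so the respiration frequency is always excluded
    (e.g. RR at 0.6 Hz gives the 1-2 Hz band).  If the snapped edge would
    exceed ``ceiling``, an un-snapped band starting at ``rr_freq + margin``
    is used instead and a :class:`NarrowBandFallbackWarning` is issued.
    """
    if rr_freq < 0:
        raise ValueError("rr_freq must be non-negative")
    f_lo = 0.5 * math.ceil((rr_freq + margin) / 0.5 - 1e-9)
    if f_lo > ceiling:
        f_lo = rr_freq + margin
        warnings.warn(
            f"narrow band for RR {rr_freq:.2f} Hz exceeds {ceiling} Hz ceiling; "
            f"using un-snapped [{f_lo:.2f}, {f_lo + width:.2f}] Hz",
            NarrowBandFallbackWarning,
            stacklevel=2,
        )
    return Passband(f_lo, f_lo + width)
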