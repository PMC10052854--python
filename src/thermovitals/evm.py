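"""Eulerian video magnification.

Sub-visible periodic intensity fluctuations (here: surface-temperature
oscillations driven by breathing and by pulsatile blood flow) are made
measurable by (1) decomposing each frame into a spatial pyramid,
(2) temporally bandpass-filtering each pyramid level pixel-wise, and
(3) adding the filtered signal back, scaled by a large gain ``alpha``.
An in-band fluctuation of amplitude ``a`` leaves the reconstruction with
amplitude approximately ``(1 + alpha) * a``; out-of-band content is
untouched.

The temporal filter is an ideal frequency-domain mask: linear, exactly
idempotent, and fully described by its passband edges.  The spatial
decomposition is a Gaussian pyramid with the fixed 5-tap binomial kernel
(1, 4, 6, 4, 1)/16; :func:`magnify` internally forms the corresponding
Laplacian (difference-of-Gaussians) pyramid so that the collapse is exact
and ``alpha = 0`` reproduces the input bit-for-bit up to float rounding.
The pyramid variant is isolated behind :func:`_laplacian_levels` so an
alternative decomposition can be swapped in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import convolve1d

from .io_video import FrameSequence

__all__ = [
    "Passband",
    "MagnifyConfig",
    "Pyramid",
    "build_pyramid",
    "temporal_bandpass",
    "magnify",
    "default_n_levels",
]

_KERNEL = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


@dataclass(frozen=True)
class Passband:
    """Temporal frequency interval [f_lo, f_hi] in Hz."""

    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 <= self.f_lo < self.f_hi):
            raise ValueError(f"invalid passband [{self.f_lo}, {self.f_hi}]")

    def validate_for(self, fps: float) -> None:
        if self.f_hi > fps / 2 + 1e-12:
            raise ValueError(
                f"passband upper edge {self.f_hi} Hz exceeds Nyquist {fps / 2} Hz"
            )

    def contains(self, f: float) -> bool:
        return self.f_lo <= f <= self.f_hi


@dataclass
class MagnifyConfig:
    """Amplification settings: gain, passband, pyramid depth, edge handling.

    ``alpha`` is the dimensionless gain (40 for thermal video, 200 for RGB).
    ``n_levels=None`` selects floor(log2(min(H, W))) - 3, leaving >= 8 px at
    the coarsest level.  ``attenuate_edges`` halves the gain at the finest
    amplified level to suppress pixel noise; the full-resolution detail
    level is never amplified.
    """

    alpha: float
    band: Passband
    n_levels: Optional[int] = None
    attenuate_edges: bool = True

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if self.n_levels is not None and self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")


@dataclass
class Pyramid:
    """Gaussian pyramid: levels[k] is the source blurred and decimated k times."""

    levels: list[np.ndarray] = field(default_factory=list)

    @property
    def n_levels(self) -> int:
        return len(self.levels)


def default_n_levels(height: int, width: int) -> int:
    """Pyramid depth leaving at least 8 px per side at the coarsest level."""
    return max(2, int(math.floor(math.log2(min(height, width)))) - 3)


def _blur(a: np.ndarray, kernel: np.ndarray = _KERNEL) -> np.ndarray:
    """Separable spatial blur over the trailing two axes (reflect boundary)."""
    out = convolve1d(a, kernel, axis=-1, mode="reflect")
    return convolve1d(out, kernel, axis=-2, mode="reflect")


def _reduce(a: np.ndarray) -> np.ndarray:
    return _blur(a)[..., ::2, ::2]


def _expand(a: np.ndarray, target_shape: tuple[int, int]) -> np.ndarray:
    """Zero-insertion upsample to ``target_shape``, normalized so constants
    are reproduced exactly (the interpolation weights are renormalized by
    the filter response to a ones image)."""
    h, w = target_shape
    up = np.zeros(a.shape[:-2] + (h, w), dtype=np.float64)
    up[..., ::2, ::2] = a
    ones = np.zeros((h, w))
    ones[::2, ::2] = 1.0
    norm = _blur(ones)
    return _blur(up) / norm


def build_pyramid(frame: np.ndarray, n_levels: int) -> Pyramid:
    """Gaussian pyramid of a single frame (or a frame stack on the leading axis).

    Level k is the blur-then-decimate of level k-1 with the fixed 5-tap
    binomial kernel; deterministic.
    """
    frame = np.asarray(frame, dtype=np.float64)
    h, w = frame.shape[-2:]
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    if min(h, w) < 8 * 2 ** (n_levels - 1):
        raise ValueError(
            f"{n_levels} levels too deep for {h}x{w} frame (needs >= 8 px per side at every level)"
        )
    levels = [frame]
    for _ in range(n_levels - 1):
        levels.append(_reduce(levels[-1]))
    return Pyramid(levels)


def _laplacian_levels(gauss: Pyramid) -> list[np.ndarray]:
    """Difference-of-Gaussians levels; the last entry is the lowpass residual.

    Reconstruction by repeated expand-and-add is exact by construction.
    """
    levels = []
    for k in range(gauss.n_levels - 1):
        g, g_next = gauss.levels[k], gauss.levels[k + 1]
        levels.append(g - _expand(g_next, g.shape[-2:]))
    levels.append(gauss.levels[-1])
    return levels


def temporal_bandpass(series: np.ndarray, band: Passband, fps: float) -> np.ndarray:
    """Ideal bandpass along the leading (time) axis.

    FFT, zero every bin whose frequency lies outside [f_lo, f_hi], inverse
    FFT, real part.  Linear and exactly idempotent.
    """
    series = np.asarray(series, dtype=np.float64)
    n = series.shape[0]
    if n < 8:
        raise ValueError("series length must be >= 8")
    band.validate_for(fps)
    spec = np.fft.rfft(series, axis=0)
    freqs = np.fft.rfftfreq(n, d=1.0 / fps)
    keep = (freqs >= band.f_lo - 1e-12) & (freqs <= band.f_hi + 1e-12)
    spec[~keep] = 0.0
    return np.fft.irfft(spec, n=n, axis=0)


def magnify(seq: FrameSequence, cfg: MagnifyConfig) -> FrameSequence:
    """Amplify temporally band-limited variation in a clip.

    Every pyramid level except the full-resolution detail level is
    bandpassed and added back scaled by ``alpha`` (half ``alpha`` at the
    finest amplified level when ``attenuate_edges``); the per-level
    additions are expanded and summed onto the original frames.
    ``alpha = 0`` reproduces the input exactly.
    """
    cfg.band.validate_for(seq.fps)
    h, w = seq.frame_shape
    n_levels = cfg.n_levels if cfg.n_levels is not None else default_n_levels(h, w)
    gauss = build_pyramid(seq.frames, n_levels)
    lap = _laplacian_levels(gauss)

    addition = None  # accumulated from coarsest to finest
    for k in range(len(lap) - 1, 0, -1):  # level 0 (finest detail) never amplified
        weight = cfg.alpha
        if cfg.attenuate_edges and k == 1 and len(lap) > 2:
            weight = cfg.alpha / 2.0
        contrib = weight * temporal_bandpass(lap[k], cfg.band, seq.fps)
        if addition is not None:
            contrib = contrib + _expand(addition, contrib.shape[-2:])
        addition = contrib
    out = seq.frames + (_expand(addition, (h, w)) if len(lap) > 1 else 0.0)
    return FrameSequence(out, seq.fps, origin_label=seq.origin_label)
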