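import numpy as np
import pytest

from thermovitals.evm import Passband
from thermovitals.io_video import FrameSequence, Rect
from thermovitals.spectral import (
    DC_GUARD_HZ,
    IntensityTrace,
    NarrowBandFallbackWarning,
    Spectrum,
    dominant_peak,
    extract_trace,
    freq_to_rate,
    select_narrow_band,
    spectrum,
)


def trace_of(values, fps=30.0):
    return IntensityTrace(np.asarray(values, dtype=float), fps=fps)


class TestExtractTrace:
    def test_constant_clip_gives_zero_trace(self):
        seq = FrameSequence(np.full((30, 16, 16), 42.0), fps=30.0)
        tr = extract_trace(seq, Rect(2, 2, 8, 8))
        np.testing.assert_allclose(tr.values, 0.0)

    def test_normalization_removes_mean_only(self):
        t = np.arange(60) / 30.0
        mod = 5.0 + 2.0 * np.sin(2 * np.pi * 1.0 * t)
        seq = FrameSequence(np.tile(mod[:, None, None], (1, 16, 16)), fps=30.0)
        tr = extract_trace(seq, Rect(0, 0, 16, 16))
        np.testing.assert_allclose(tr.values, mod - mod.mean(), atol=1e-12)
        assert abs(tr.values.mean()) < 1e-9

    def test_full_frame_roi_equals_mean_of_per_pixel_traces(self, seal_clip):
        seq, _ = seal_clip
        h, w = seq.frame_shape
        tr = extract_trace(seq, Rect(0, 0, w, h))
        per_pixel = seq.frames.reshape(seq.n_frames, -1)
        oracle = per_pixel.mean(axis=1)
        oracle = oracle - oracle.mean()
        np.testing.assert_allclose(tr.values, oracle, atol=1e-12)

    def test_roi_out_of_bounds(self, seal_clip):
        seq, _ = seal_clip
        with pytest.raises(ValueError, match="outside"):
            extract_trace(seq, Rect(60, 60, 10, 10))

    def test_tiny_roi_rejected(self, seal_clip):
        seq, _ = seal_clip
        with pytest.raises(ValueError, match=">= 4 px"):
            extract_trace(seq, Rect(0, 0, 1, 2))


class TestSpectrum:
    def test_nine_second_tone_peaks_at_63_centihertz(self):
        t = np.arange(270) / 30.0
        sp = spectrum(trace_of(np.sin(2 * np.pi * 0.63 * t)), pad_to_resolution=0.01)
        assert sp.freqs[np.argmax(sp.magnitude)] == pytest.approx(0.63, abs=0.01)

    def test_zero_trace_gives_zero_magnitude(self):
        sp = spectrum(trace_of(np.zeros(100)))
        assert sp.magnitude.max() == 0.0

    def test_grid_runs_to_nyquist(self):
        sp = spectrum(trace_of(np.ones(128)), pad_to_resolution=0.01)
        assert sp.freqs[0] == 0.0
        assert sp.freqs[-1] == pytest.approx(15.0)
        assert np.all(np.diff(sp.freqs) > 0)

    def test_coarser_than_native_padding_rejected(self):
        with pytest.raises(ValueError, match="coarser"):
            spectrum(trace_of(np.zeros(300)), pad_to_resolution=0.5)

    def test_parseval_energy_identity(self):
        """Total two-sided spectral energy equals trace energy (zero padding
        adds none)."""
        rng = np.random.default_rng(3)
        x = rng.normal(size=270)
        x -= x.mean()
        n_pad = 3000
        full = np.fft.fft(x, n=n_pad)
        assert (np.abs(full) ** 2).sum() / n_pad == pytest.approx((x**2).sum(), rel=1e-6)

    def test_white_noise_rarely_clears_threshold(self):
        """Monte-Carlo calibration: the 4.0 prominence threshold yields a
        false 'clear peak' on white noise in at most 5% of seeds."""
        band = Passband(0.1, 3.5)
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=270)
            sp = spectrum(trace_of(x - x.mean()))
            if dominant_peak(sp, band).clear:
                hits += 1
        assert hits / n_seeds <= 0.05


class TestDominantPeak:
    def constructed_spectrum(self, lines):
        freqs = np.arange(0.0, 15.0, 0.01)
        mag = np.full_like(freqs, 0.1)
        for f, a in lines:
            mag[np.argmin(np.abs(freqs - f))] = a
        return Spectrum(freqs=freqs, magnitude=mag, resolution=0.01)

    def test_dominance_beats_frequency_order(self):
        sp = self.constructed_spectrum([(0.63, 10.0), (1.64, 6.0)])
        peak = dominant_peak(sp, Passband(0.1, 3.5))
        assert peak.freq == pytest.approx(0.63)
        assert peak.clear

    def test_flat_spectrum_is_not_clear(self):
        sp = Spectrum(np.arange(0, 15, 0.01), np.ones(1500), 0.01)
        peak = dominant_peak(sp, Passband(0.1, 3.5))
        assert peak.prominence_ratio == pytest.approx(1.0)
        assert not peak.clear

    def test_agrees_with_exhaustive_scan(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            mag = rng.uniform(0, 1, size=1500)
            sp = Spectrum(np.arange(0, 15, 0.01), mag, 0.01)
            band = Passband(0.2, 3.0)
            peak = dominant_peak(sp, band)
            idx = [
                i
                for i, f in enumerate(sp.freqs)
                if max(band.f_lo, DC_GUARD_HZ) - 1e-9 <= f <= band.f_hi + 1e-9
            ]
            best = max(idx, key=lambda i: mag[i])
            assert peak.freq == pytest.approx(sp.freqs[best])

    def test_exclusion_intervals_remove_harmonic(self):
        """A respiration harmonic inside the band wins by default; with the
        harmonic interval excluded, the cardiac line is found."""
        sp = self.constructed_spectrum([(1.26, 12.0), (1.64, 8.0)])  # 2x0.63 vs cardiac
        band = Passband(1.0, 2.0)
        assert dominant_peak(sp, band).freq == pytest.approx(1.26)
        notched = dominant_peak(sp, band, exclude=[(1.21, 1.31)])
        assert notched.freq == pytest.approx(1.64)

    def test_dc_guard_excludes_near_zero_bins(self):
        sp = self.constructed_spectrum([(0.02, 100.0), (0.63, 5.0)])
        peak = dominant_peak(sp, Passband(0.0, 3.5))
        assert peak.freq == pytest.approx(0.63)

    def test_empty_band_rejected(self):
        sp = self.constructed_spectrum([])
        with pytest.raises(ValueError, match="empty"):
            dominant_peak(sp, Passband(0.0, 0.02))


class TestFreqToRate:
    @pytest.mark.parametrize("f,rate", [(0.63, 37.8), (1.64, 98.4), (0.0, 0.0)])
    def test_conversion(self, f, rate):
        assert freq_to_rate(f) == pytest.approx(rate)

    def test_reported_rounding_convention(self):
        # the numeric value stays unrounded; display rounds 37.8 -> 38
        assert round(freq_to_rate(0.63)) == 38

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            freq_to_rate(-0.1)


class TestSelectNarrowBand:
    @pytest.mark.parametrize(
        "rr,expected",
        [(0.6, (1.0, 2.0)), (0.63, (1.0, 2.0)), (1.2, (2.0, 3.0)), (0.1, (0.5, 1.5))],
    )
    def test_snapping_rule(self, rr, expected):
        band = select_narrow_band(rr)
        assert (band.f_lo, band.f_hi) == pytest.approx(expected)

    def test_never_contains_rr(self):
        for rr in np.arange(0.05, 2.51, 0.01):
            band = select_narrow_band(rr)
            assert not band.contains(rr), rr

    def test_fallback_above_ceiling_warns(self):
        with pytest.warns(NarrowBandFallbackWarning):
            band = select_narrow_band(3.4)
        assert band.f_lo == pytest.approx(3.75)
        assert not band.contains(3.4)
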