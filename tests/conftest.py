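import numpy as np
import pytest

from thermovitals import RunConfig, measure_hr, measure_rr
from thermovitals.stats import load_packaged_records
from thermovitals.synthetic import SynthParams, generate_clip


@pytest.fixture(scope="session")
def seal_clip():
    """Default worked-example clip: 0.63 Hz respiration, 1.64 Hz cardiac, SNR 5."""
    return generate_clip(SynthParams(seed=7))


@pytest.fixture(scope="session")
def clean_clip():
    """Noise-free, drift-free clip (pure two-tone scene)."""
    return generate_clip(SynthParams(noise_sd=0.0, seed=7))


@pytest.fixture(scope="session")
def seal_measurements(seal_clip):
    """Shared wide- and narrow-pass measurements on the worked-example clip."""
    seq, truth = seal_clip
    cfg = RunConfig()
    rr_est, rr_peak = measure_rr(seq, truth.window_roi, cfg)
    assert rr_est is not None
    hr_est, hr_peak = measure_hr(seq, truth.window_roi, rr_est.source_freq, cfg)
    return {"rr": rr_est, "rr_peak": rr_peak, "hr": hr_est, "hr_peak": hr_peak}


@pytest.fixture(scope="session")
def records():
    """Packaged 58-session validation table."""
    return load_packaged_records()
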