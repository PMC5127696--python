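import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import multiqrs as mq

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def clean_labeled():
    """Noise-free 60 s, 8-channel recording (no artifacts, fixed seed)."""
    cfg = mq.SynthConfig(duration=60.0, noise_sd=0.0, artifact_rate=0.0, seed=7)
    return mq.generate_recording(cfg)


@pytest.fixture(scope="session")
def artifact_labeled():
    """120 s movement-surrogate recording: bursts at 6/min, 3x R, 3 of 8 channels."""
    return mq.generate_recording(mq.SynthConfig(seed=1))


@pytest.fixture(scope="session")
def clean_template(clean_labeled):
    fs = clean_labeled.recording.sampling_rate
    y = mq.highpass_detrend(clean_labeled.recording.channel("ch0"), fs)
    tpl = mq.extract_qrs_template(y, clean_labeled.true_peak_samples, fs, channel="ch0")
    tpl.quality = mq.channel_quality(tpl)
    return tpl


def make_gaussian_template(fs=1000.0, sigma_ms=8.5, channel="a"):
    """Synthetic unit-amplitude Gaussian QRS template for detector unit tests."""
    half = round(0.045 * fs)
    t = (np.arange(2 * half + 1) - half) / fs
    wave = np.exp(-0.5 * (t / (sigma_ms / 1000.0)) ** 2)
    return mq.QRSTemplate(
        waveform=wave,
        per_sample_sd=np.full(wave.size, 0.1),
        n_cycles_used=20,
        quality=None,
        channel=channel,
        sampling_rate=fs,
    )
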