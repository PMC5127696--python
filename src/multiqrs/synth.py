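"""Synthetic multichannel face-lead ECG, respiration and EEG-response generator.

The generator produces labelled recordings with the statistical structure the
multichannel detector assumes:

* a chest-reference beat sequence whose RR intervals are modulated by
  respiration (respiratory sinus arrhythmia, RSA) plus small lognormal jitter;
* per-channel face-lead projections of the ECG cycle with small gains
  (face-lead amplitudes are substantially smaller than chest ECG) and
  per-channel millisecond-scale conduction delays;
* baseline wander and white sensor noise;
* motion-artifact bursts — band-limited noise transients that hit only a
  random subset of channels per event, so artifacts are unsynchronised across
  channels while heartbeats are synchronous;
* narrowband EEG responses (alpha, ASSR, SSVEP) for the spectral checks.

Each ECG cycle is a sum of three Gaussian bumps (P, QRS, T) with amplitude
ratio 0.15 : 1 : 0.3 — enough morphology to exercise matched filtering
without a full dipole-level forward model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps

from ._util import ms_to_samples, round_half_up
from .io import Recording

__all__ = [
    "SynthConfig",
    "LabeledRecording",
    "generate_rr_series",
    "generate_recording",
    "generate_eeg_response",
]

#: P : R : T amplitude ratio of the Gaussian-bump cycle model.
P_AMP, R_AMP, T_AMP = 0.15, 1.0, 0.3
#: Bump centres relative to the R-peak (seconds).
P_OFFSET, T_OFFSET = -0.16, 0.25
#: Gaussian widths (sd, seconds) of the P and T bumps.
P_SIGMA, T_SIGMA = 0.025, 0.05
#: Gaussian FWHM -> sd conversion.
_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class SynthConfig:
    """Parameters of the synthetic multichannel recording.

    Defaults emulate the movement protocol used throughout the package's
    evaluation: a 120 s, 8-channel, 1 kHz face-lead recording with mean RR
    interval 0.8 s, 5 % RSA depth, and motion-artifact bursts at 6 events/min
    with amplitude 3x the R-peak hitting 3 of 8 channels per event, after a
    20 s artifact-free rest epoch used for template extraction.
    """

    sampling_rate: float = 1000.0  # Hz
    duration: float = 120.0  # s
    n_channels: int = 8
    mean_rri: float = 0.8  # s
    rsa_depth: float = 0.05  # fraction of mean RRI
    resp_freq: float = 0.25  # Hz
    channel_gains: Sequence[float] | None = None  # default 0.1 per channel
    channel_delays: Sequence[float] | None = None  # ms, default 1..6 ms spread
    qrs_width: float = 20.0  # ms, FWHM of the R bump
    noise_sd: float = 0.01  # amplifier units
    artifact_rate: float = 6.0  # events / min
    artifact_channel_fraction: float = 0.375  # 3 of 8
    artifact_amplitude: float = 3.0  # multiple of the per-channel R amplitude
    rest_duration: float = 20.0  # s, artifact-free initial epoch
    jitter_sd: float = 0.01  # lognormal RRI jitter, fraction of mean
    baseline_amplitude: float = 0.5  # multiple of R amplitude
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not 0 <= self.rsa_depth < 1:
            raise ValueError("rsa_depth must be in [0, 1)")
        if not 0 < self.artifact_channel_fraction <= 1:
            raise ValueError("artifact_channel_fraction must be in (0, 1]")
        if self.duration < 2 * self.mean_rri:
            raise ValueError("duration must cover at least two mean RR intervals")
        if self.n_channels < 1:
            raise ValueError("need at least one channel")
        if self.channel_gains is None:
            # face-lead amplitudes ~10x smaller than chest reference
            self.channel_gains = [0.1] * self.n_channels
        if self.channel_delays is None:
            if self.n_channels == 1:
                self.channel_delays = [2.0]
            else:
                self.channel_delays = [
                    1.0 + 5.0 * i / (self.n_channels - 1)
                    for i in range(self.n_channels)
                ]
        if len(self.channel_gains) != self.n_channels:
            raise ValueError("channel_gains length must equal n_channels")
        if len(self.channel_delays) != self.n_channels:
            raise ValueError("channel_delays length must equal n_channels")


@dataclass
class LabeledRecording:
    """A synthetic recording together with its ground truth.

    Attributes
    ----------
    recording : Recording
        The multichannel signal matrix.
    true_peaks : ndarray
        R-peak times in seconds, strictly increasing (chest-reference truth,
        i.e. before per-channel delays).
    respiration : ndarray
        Respiration trace sampled on the recording grid.
    artifact_intervals : list of (label, start_s, end_s)
        Channels and time spans hit by each artifact burst.
    channel_delays : list of float
        The per-channel delays (ms) actually applied.
    """

    recording: Recording
    true_peaks: np.ndarray
    respiration: np.ndarray
    artifact_intervals: list[tuple[str, float, float]] = field(default_factory=list)
    channel_delays: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.true_peaks = np.asarray(self.true_peaks, dtype=float)
        if self.true_peaks.size and np.any(np.diff(self.true_peaks) <= 0):
            raise ValueError("true_peaks must be strictly increasing")
        dur = self.recording.duration
        for _, start, end in self.artifact_intervals:
            if not (0 <= start <= end <= dur + 1e-9):
                raise ValueError("artifact interval outside recording")

    @property
    def true_peak_samples(self) -> np.ndarray:
        fs = self.recording.sampling_rate
        return np.array(
            [round_half_up(t * fs) for t in self.true_peaks], dtype=np.int64
        )


# ---------------------------------------------------------------------------
# RR series with RSA


def generate_rr_series(
    n_beats: int,
    mean_rri: float,
    rsa_depth: float,
    resp_freq: float,
    seed: int,
    jitter_sd: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate an RSA-modulated RR-interval series.

    The interval following beat ``k`` is
    ``mean_rri * (1 + rsa_depth * sin(phi_k)) * j_k`` where ``phi_k`` is the
    respiration phase at the beat time and ``j_k`` is mean-one lognormal
    jitter, so RRI extrema co-occur with respiration extrema.

    Returns
    -------
    rris : ndarray, shape (n_beats,)
        The RR intervals in seconds (all positive).
    resp_phase : ndarray, shape (n_beats,)
        Respiration phase (radians) at each beat.
    """
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    if not 0 <= rsa_depth < 1:
        raise ValueError("rsa_depth must be in [0, 1): non-positive RRI possible")
    rng = np.random.default_rng(seed)
    sigma = np.log1p(jitter_sd) if jitter_sd > 0 else 0.0
    rris = np.empty(n_beats)
    phases = np.empty(n_beats)
    t = 0.0
    for k in range(n_beats):
        phi = 2.0 * np.pi * resp_freq * t
        phases[k] = phi
        jitter = np.exp(rng.normal(0.0, sigma) - 0.5 * sigma**2) if sigma else 1.0
        rris[k] = mean_rri * (1.0 + rsa_depth * np.sin(phi)) * jitter
        t += rris[k]
    return rris, phases


def _ecg_cycle(t: np.ndarray, qrs_sigma: float) -> np.ndarray:
    """Evaluate the three-bump ECG cycle at times ``t`` (seconds from R)."""
    return (
        P_AMP * np.exp(-0.5 * ((t - P_OFFSET) / P_SIGMA) ** 2)
        + R_AMP * np.exp(-0.5 * (t / qrs_sigma) ** 2)
        + T_AMP * np.exp(-0.5 * ((t - T_OFFSET) / T_SIGMA) ** 2)
    )


def generate_recording(config: SynthConfig) -> LabeledRecording:
    """Generate a labelled multichannel face-lead ECG recording.

    Each channel is ``gain_c * cycle_train(delayed by delay_c) + baseline
    wander + white noise + artifact bursts``.  Ground-truth R-peak times are
    the undelayed (chest-reference) peak samples, stored in seconds.
    Fixed ``config.seed`` gives bit-identical output.
    """
    fs = config.sampling_rate
    n = int(round(config.duration * fs))
    rng = np.random.default_rng(config.seed)
    qrs_sigma = (config.qrs_width / 1000.0) / _FWHM

    # --- beat times (sample-aligned so truth is exact)
    sigma = np.log1p(config.jitter_sd) if config.jitter_sd > 0 else 0.0
    margin = 0.25  # keep the full T wave inside the record
    t = 0.5 * config.mean_rri
    peak_samples: list[int] = []
    while t < config.duration - margin:
        peak_samples.append(round_half_up(t * fs))
        phi = 2.0 * np.pi * config.resp_freq * t
        jitter = np.exp(rng.normal(0.0, sigma) - 0.5 * sigma**2) if sigma else 1.0
        t += config.mean_rri * (1.0 + config.rsa_depth * np.sin(phi)) * jitter
    peaks = np.asarray(peak_samples, dtype=np.int64)

    # --- reference (undelayed, unit-amplitude) cycle train
    reference = np.zeros(n)
    half = int(round(0.45 * fs))  # covers P..T comfortably
    rel_t = np.arange(-half, half + 1) / fs
    cycle = _ecg_cycle(rel_t, qrs_sigma)
    for p in peaks:
        lo, hi = p - half, p + half + 1
        clo, chi = max(0, lo), min(n, hi)
        reference[clo:chi] += cycle[clo - lo : chi - lo]

    time = np.arange(n) / fs
    respiration = np.sin(2.0 * np.pi * config.resp_freq * time)

    # --- per-channel signals
    data = np.zeros((config.n_channels, n))
    for c in range(config.n_channels):
        d = ms_to_samples(config.channel_delays[c], fs)
        delayed = np.zeros(n)
        if d >= 0:
            delayed[d:] = reference[: n - d] if d else reference
        else:
            delayed[:d] = reference[-d:]
        gain = config.channel_gains[c]
        chan = gain * delayed
        # baseline wander: slow sinusoid, random frequency/phase per channel
        f_b = rng.uniform(0.2, 0.4)
        phi_b = rng.uniform(0, 2 * np.pi)
        chan = chan + config.baseline_amplitude * gain * np.sin(
            2 * np.pi * f_b * time + phi_b
        )
        if config.noise_sd > 0:
            chan = chan + rng.normal(0.0, config.noise_sd, size=n)
        data[c] = chan

    labels = [f"ch{c}" for c in range(config.n_channels)]

    # --- artifact bursts, hitting random channel subsets after the rest epoch
    intervals: list[tuple[str, float, float]] = []
    window = config.duration - config.rest_duration
    if config.artifact_rate > 0 and window > 1.0:
        n_events = rng.poisson(config.artifact_rate * window / 60.0)
        n_hit = max(1, round_half_up(config.artifact_channel_fraction * config.n_channels))
        n_hit = min(n_hit, config.n_channels)
        for _ in range(n_events):
            burst_dur = rng.uniform(0.2, 1.0)
            start = rng.uniform(config.rest_duration, config.duration - burst_dur)
            hit = rng.choice(config.n_channels, size=n_hit, replace=False)
            i0 = int(start * fs)
            m = int(burst_dur * fs)
            taper = sps.windows.tukey(m, 0.25)
            for c in sorted(hit):
                burst = rng.normal(0.0, 1.0, size=m)
                burst = _bandlimit(burst, fs)
                peak = np.max(np.abs(burst))
                if peak > 0:
                    burst *= (
                        config.artifact_amplitude * config.channel_gains[c] / peak
                    )
                data[c, i0 : i0 + m] += burst * taper
                intervals.append((labels[c], start, start + burst_dur))

    rec = Recording(sampling_rate=fs, labels=labels, data=data)
    return LabeledRecording(
        recording=rec,
        true_peaks=peaks / fs,
        respiration=respiration,
        artifact_intervals=intervals,
        channel_delays=list(config.channel_delays),
    )


def _bandlimit(x: np.ndarray, fs: float, lo: float = 2.0, hi: float = 40.0) -> np.ndarray:
    """Band-limit a burst to the motion-artifact band (2-40 Hz)."""
    hi = min(hi, 0.45 * fs)
    sos = sps.butter(3, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


# ---------------------------------------------------------------------------
# EEG responses


def generate_eeg_response(
    kind: str,
    f0: float,
    snr: float,
    duration: float,
    sampling_rate: float,
    seed: int,
    carrier: float = 1000.0,
):
    """Generate a narrowband EEG response (and for ASSR also the stimulus).

    Parameters
    ----------
    kind : {"alpha", "assr", "ssvep"}
        Response type.  ``alpha``/``ssvep`` return a single channel: a
        sinusoid at ``f0`` buried in pink noise at the requested SNR.
        ``assr`` returns a ``(stimulus, response)`` tuple: the stimulus is a
        unit-depth amplitude-modulated carrier (components at
        ``carrier ± f0`` and ``carrier``, *no* component at ``f0``), the
        response is the demodulated neural answer — a sinusoid at ``f0`` in
        pink noise.
    snr : float
        Signal-to-noise ratio in dB of the sinusoidal response.
    """
    if kind not in ("alpha", "assr", "ssvep"):
        raise ValueError(f"unknown response kind {kind!r}")
    if f0 >= sampling_rate / 2:
        raise ValueError("f0 must be below the Nyquist frequency")
    rng = np.random.default_rng(seed)
    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate

    noise = _pink_noise(n, rng)
    amp = np.sqrt(2.0 * 10.0 ** (snr / 10.0))  # unit-variance noise
    response = amp * np.sin(2 * np.pi * f0 * t) + noise

    if kind == "assr":
        if carrier + f0 >= sampling_rate / 2:
            raise ValueError("carrier + f0 must be below the Nyquist frequency")
        stimulus = (1.0 + np.sin(2 * np.pi * f0 * t)) * np.sin(2 * np.pi * carrier * t)
        # -60 dB measurement noise floor: a recorded stimulus is never
        # mathematically noise-free, and spectral ratios far from the
        # carrier are only meaningful above a physical floor
        stimulus = stimulus + rng.normal(0.0, 1e-3, size=n)
        return stimulus, response
    return response


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f noise via spectral shaping."""
    white = rng.normal(size=n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n)
    sd = np.std(x)
    return x / sd if sd > 0 else x
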