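"""Welch spectra and band presets for steady-state EEG response checks.

Power spectral densities use Welch's method with 4.8 s Hann segments and
80 % overlap.  Band-pass presets reproduce the standard visualisation
bands for the three responses of interest: alpha rhythm (1-30 Hz), the
40 Hz auditory steady-state response (1-45 Hz) and the 15 Hz steady-state
visual evoked potential (1-25 Hz), all 4th-order Butterworth.  The
``response_peak_score`` quantifies how sharply a response frequency stands
out of its spectral neighbourhood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = ["PSDEstimate", "welch_psd", "band_preset", "response_peak_score"]

_BAND_PRESETS = {
    "alpha": (1.0, 30.0, 4),
    "assr": (1.0, 45.0, 4),
    "ssvep": (1.0, 25.0, 4),
}


@dataclass
class PSDEstimate:
    """A Welch power spectral density estimate."""

    frequencies: np.ndarray
    power: np.ndarray
    window_length: float  # s
    overlap: float  # fraction

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")
        if self.frequencies.size > 1 and np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")


def welch_psd(
    signal: np.ndarray,
    sampling_rate: float,
    window_length: float = 4.8,
    overlap: float = 0.8,
) -> PSDEstimate:
    """Welch PSD with Hann segments (defaults: 4.8 s windows, 80 % overlap)."""
    x = np.asarray(signal, dtype=float)
    if x.size / sampling_rate < window_length:
        raise ValueError("signal shorter than one Welch window")
    nperseg = int(round(window_length * sampling_rate))
    noverlap = int(round(overlap * nperseg))
    f, p = sps.welch(
        x, fs=sampling_rate, window="hann", nperseg=nperseg, noverlap=noverlap,
        detrend="constant", scaling="density",
    )
    return PSDEstimate(frequencies=f, power=p, window_length=window_length, overlap=overlap)


def band_preset(kind: str) -> tuple[float, float, int]:
    """(f_min, f_max, filter order) preset for a response kind."""
    try:
        return _BAND_PRESETS[kind]
    except KeyError:
        raise ValueError(f"unknown response kind {kind!r}") from None


def response_peak_score(
    psd: PSDEstimate,
    f0: float,
    neighborhood: float = 5.0,
    guard: float = 0.5,
) -> float:
    """Peak power at f0 relative to the median of its neighbourhood.

    The numerator is the power in the grid bin nearest ``f0``; the
    denominator the median power within ``+-neighborhood`` Hz excluding a
    ``+-guard`` Hz band around ``f0``.  A broadband signal scores near 1,
    a sharp spectral line well above 1.  Scale-invariant by construction.
    """
    f = psd.frequencies
    if not f[0] <= f0 <= f[-1]:
        raise ValueError(f"f0={f0} Hz outside the PSD range [{f[0]}, {f[-1]}]")
    peak_bin = int(np.argmin(np.abs(f - f0)))
    near = (np.abs(f - f0) <= neighborhood) & (np.abs(f - f0) > guard)
    if not near.any():
        raise ValueError("neighbourhood contains no bins; widen it")
    denom = float(np.median(psd.power[near]))
    if denom == 0:
        raise ValueError("neighbourhood power is zero")
    return float(psd.power[peak_bin]) / denom
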