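"""Small shared helpers (sample/ms conversions, rounding conventions)."""

from __future__ import annotations

import math

__all__ = ["round_half_up", "ms_to_samples", "s_to_samples"]


def round_half_up(x: float) -> int:
    """Round to the nearest integer with ties going up (0.5 -> 1).

    Python's built-in ``round`` uses banker's rounding; all millisecond ->
    sample conversions in this package use round-half-up so that window
    lengths are stable across sampling rates.
    """
    return int(math.floor(x + 0.5))


def ms_to_samples(ms: float, sampling_rate: float) -> int:
    """Convert a duration in milliseconds to a sample count (round-half-up)."""
    return round_half_up(ms * sampling_rate / 1000.0)


def s_to_samples(seconds: float, sampling_rate: float) -> int:
    """Convert a duration in seconds to a sample count (round-half-up)."""
    return round_half_up(seconds * sampling_rate)
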