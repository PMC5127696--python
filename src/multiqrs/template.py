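"""QRS template extraction, channel quality scoring and virtual channels.

A per-channel QRS template is the mean of up to 20 de-trended signal windows
spanning 45 ms before to 45 ms after each reference R-peak, with outlier
cycles excluded.  The per-sample standard deviation over the retained cycles
feeds the channel quality score

    Q = (R_bar - S_bar) / mean(per-sample sd)

where R_bar is the mean template amplitude within +-3 ms of the R sample and
S_bar within +-3 ms of R + 30 ms.  Channels are ranked by Q and the best k
are used for multichannel detection.  Virtual channels (pairwise sums and
re-standardised products of neighbouring electrodes) can be appended to
enrich the channel set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._util import ms_to_samples
from .io import Recording, as_peak_train

__all__ = [
    "QRSTemplate",
    "extract_qrs_template",
    "channel_quality",
    "rank_channels",
    "make_virtual_channels",
]

HALF_WINDOW_MS = 45.0  # template spans R +- 45 ms
MAX_CYCLES = 20
CORR_THRESHOLD = 0.8  # outlier rule: correlation with median cycle
AMP_Z_THRESHOLD = 2.5  # outlier rule: robust z of the peak amplitude


@dataclass
class QRSTemplate:
    """Averaged QRS waveform for one channel.

    ``waveform`` has odd length ``2*round(45 ms * fs) + 1`` and is centred on
    the R sample; ``per_sample_sd`` is the same-length spread over the
    contributing cycles; ``quality`` is the Q score (filled in by
    :func:`channel_quality`, may be None straight after extraction).
    """

    waveform: np.ndarray
    per_sample_sd: np.ndarray
    n_cycles_used: int
    quality: float | None
    channel: str
    sampling_rate: float

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=float)
        self.per_sample_sd = np.asarray(self.per_sample_sd, dtype=float)
        if self.waveform.size % 2 != 1:
            raise ValueError("template waveform length must be odd")
        if self.per_sample_sd.shape != self.waveform.shape:
            raise ValueError("per_sample_sd must match waveform length")
        if self.n_cycles_used > MAX_CYCLES:
            raise ValueError(f"n_cycles_used exceeds {MAX_CYCLES}")
        if np.any(self.per_sample_sd < 0):
            raise ValueError("per_sample_sd must be non-negative")

    @property
    def half_length(self) -> int:
        return self.waveform.size // 2


def _robust_z(values: np.ndarray) -> np.ndarray:
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    scale = max(1.4826 * mad, 1e-12)
    return (values - med) / scale


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = np.std(a), np.std(b)
    if sa == 0 or sb == 0:
        return 1.0 if np.allclose(a, b) else 0.0
    return float(np.corrcoef(a, b)[0, 1])


def extract_qrs_template(
    channel_signal: np.ndarray,
    reference_peaks,
    sampling_rate: float,
    channel: str = "",
) -> QRSTemplate:
    """Extract the averaged QRS pattern of one (de-trended) channel.

    The first 20 reference beats with full +-45 ms context are collected;
    cycles whose correlation with the elementwise median cycle is below 0.8,
    or whose peak amplitude deviates more than 2.5 robust z-scores from the
    median, are excluded before averaging.

    Raises
    ------
    ValueError
        If fewer than 20 beats have full context (the count is reported), or
        if outlier exclusion leaves fewer than 2 cycles.
    """
    x = np.asarray(channel_signal, dtype=float)
    peaks = as_peak_train(reference_peaks)
    half = ms_to_samples(HALF_WINDOW_MS, sampling_rate)
    usable = peaks[(peaks >= half) & (peaks + half < x.size)]
    if usable.size < MAX_CYCLES:
        raise ValueError(
            f"need {MAX_CYCLES} beats with full context, found {usable.size}"
        )
    cycles = np.stack([x[p - half : p + half + 1] for p in usable[:MAX_CYCLES]])

    median_cycle = np.median(cycles, axis=0)
    corr = np.array([_safe_corr(c, median_cycle) for c in cycles])
    amp_z = _robust_z(cycles[:, half])
    keep = (corr >= CORR_THRESHOLD) & (np.abs(amp_z) <= AMP_Z_THRESHOLD)
    if keep.sum() < 2:
        raise ValueError("outlier exclusion left fewer than 2 cycles")
    retained = cycles[keep]
    return QRSTemplate(
        waveform=retained.mean(axis=0),
        per_sample_sd=retained.std(axis=0, ddof=0),
        n_cycles_used=int(keep.sum()),
        quality=None,
        channel=channel,
        sampling_rate=sampling_rate,
    )


def channel_quality(template: QRSTemplate) -> float:
    """Compute the channel quality Q from a template.

    Q = (R_bar - S_bar) / mean(per-sample sd), with R_bar the mean template
    amplitude within +-3 ms of the centre and S_bar within +-3 ms of
    centre + 30 ms (sample counts scale with the sampling rate; at 1 kHz
    these are the classic +-3 samples and +30 samples).
    """
    fs = template.sampling_rate
    denom = float(np.mean(template.per_sample_sd))
    if denom == 0:
        raise ValueError("degenerate template: per-sample sd is all zero")
    centre = template.half_length
    n3 = ms_to_samples(3.0, fs)
    s_off = ms_to_samples(30.0, fs)
    w = template.waveform
    r_bar = float(np.mean(w[centre - n3 : centre + n3 + 1]))
    lo, hi = centre + s_off - n3, centre + s_off + n3 + 1
    if hi > w.size:
        raise ValueError("template too short for the S-wave window")
    s_bar = float(np.mean(w[lo:hi]))
    return (r_bar - s_bar) / denom


def rank_channels(templates: Sequence[QRSTemplate], k: int) -> list[str]:
    """Labels of the k highest-quality channels, descending Q.

    Ties are broken by input order (stable sort).  Templates must have their
    ``quality`` filled in.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(templates):
        raise ValueError(f"k={k} exceeds {len(templates)} templates")
    for t in templates:
        if t.quality is None:
            raise ValueError(f"template for {t.channel!r} has no quality score")
    order = sorted(range(len(templates)), key=lambda i: -templates[i].quality)
    return [templates[i].channel for i in order[:k]]


def make_virtual_channels(
    recording: Recording, neighbor_pairs: Sequence[tuple[str, str]]
) -> Recording:
    """Append pairwise sum and product channels for neighbouring electrodes.

    For each pair (a, b) two channels are appended: the sample-wise sum
    labelled ``"a+b"`` and the sample-wise product labelled ``"a*b"``,
    the latter centred and re-standardised to unit variance (raw products
    change units, which would distort matched-filter amplitudes).  All-zero
    results are kept but flagged with a warning.
    """
    seen = set()
    for a, b in neighbor_pairs:
        if a == b:
            raise ValueError(f"pair ({a!r}, {a!r}) is degenerate")
        if a not in recording.labels or b not in recording.labels:
            raise ValueError(f"unknown label in pair ({a!r}, {b!r})")
        key = frozenset((a, b))
        if key in seen:
            raise ValueError(f"duplicate pair ({a!r}, {b!r})")
        seen.add(key)

    new_rows = []
    new_labels = []
    for a, b in neighbor_pairs:
        xa, xb = recording.channel(a), recording.channel(b)
        total = xa + xb
        if not np.any(total):
            warnings.warn(f"virtual channel {a}+{b} is identically zero")
        prod = xa * xb
        prod = prod - prod.mean()
        sd = prod.std()
        if sd > 0:
            prod = prod / sd
        else:
            warnings.warn(f"virtual channel {a}*{b} is constant")
        new_rows.extend([total, prod])
        new_labels.extend([f"{a}+{b}", f"{a}*{b}"])
    return Recording(
        sampling_rate=recording.sampling_rate,
        labels=recording.labels + new_labels,
        data=np.vstack([recording.data] + new_rows),
        start_time=recording.start_time,
    )
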