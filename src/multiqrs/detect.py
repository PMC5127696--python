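"""Matched filtering, trapezoid-kernel channel fusion and the combined
prediction + detection R-peak algorithm.

The multichannel idea: heartbeats appear near-simultaneously in every
channel while motion artifacts hit only a few channels at a time.  Per
channel, the de-trended signal is cross-correlated with that channel's QRS
template; candidate peak locations are stamped into a channels x samples
fusion matrix as isosceles trapezoids (lower base 21 ms, upper base 3 ms,
height 9 at 1 kHz) which absorb small inter-channel delays; summing over
channels yields a consensus trace whose significant peaks are beats.  A
location must be supported by a majority of channels to clear the consensus
threshold, so unsynchronised noise peaks of any amplitude are ignored.

Beat-to-beat prediction: starting from a known peak R_l with expected
interval RR_e (mean of the 7 most recent RR intervals), the correlation
trace over the next 2*RR_e seconds is weighted by a Hanning window raised to
the power w whose maximum sits at R_l + RR_e; the per-channel weighted
maximum becomes that channel's candidate, candidates are fused, and the
consensus peak with the best height + area score becomes the next beat.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal as sps

from ._util import ms_to_samples, round_half_up, s_to_samples
from .io import Recording, as_peak_train
from .template import QRSTemplate

__all__ = [
    "DetectionParams",
    "PredictionState",
    "matched_filter",
    "detect_peaks_single",
    "trapezoid_kernel",
    "build_fusion_matrix",
    "fuse_channels",
    "prediction_window",
    "update_expected_rri",
    "detect_combined",
]


@dataclass
class DetectionParams:
    """Tunables of the multichannel detector.

    ``consensus_threshold`` defaults to (k/2) * trapezoid_height, i.e. a
    candidate location must be supported by more than half of the fused
    channels.  ``candidate_gate`` rejects per-channel candidates whose raw
    correlation falls below this fraction of the running median correlation
    amplitude at recently accepted beats (guards against lone T-waves being
    promoted when no true beat lies in the search window).
    """

    k_channels: int = 7
    trapezoid_base_ms: float = 21.0
    trapezoid_top_ms: float = 3.0
    trapezoid_height: float = 9.0
    w: float = 2.0  # prediction-window weight (Hanning power)
    rr_history: int = 7
    min_peak_distance_ms: float = 200.0  # physiological refractory period
    consensus_threshold: float | None = None
    candidate_gate: float = 0.5
    score_height_weight: float = 1.0
    score_area_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.trapezoid_top_ms > self.trapezoid_base_ms:
            raise ValueError("trapezoid top must not exceed its base")
        if self.w < 0:
            raise ValueError("prediction weight w must be non-negative")
        if self.rr_history < 1:
            raise ValueError("rr_history must be >= 1")
        if self.k_channels < 1:
            raise ValueError("k_channels must be >= 1")

    def threshold(self, n_channels: int) -> float:
        if self.consensus_threshold is not None:
            return self.consensus_threshold
        return 0.5 * n_channels * self.trapezoid_height


@dataclass
class PredictionState:
    """Running state of the beat predictor."""

    last_peak: int  # sample index of R_l
    expected_rri: float  # RR_e in seconds
    initial_rri: float  # rest-phase mean, pads a short history
    recent_rris: deque = field(default_factory=lambda: deque(maxlen=7))
    rr_history: int = 7

    def __post_init__(self) -> None:
        if self.expected_rri <= 0 or self.initial_rri <= 0:
            raise ValueError("expected RR interval must be positive")
        if not isinstance(self.recent_rris, deque) or self.recent_rris.maxlen != self.rr_history:
            self.recent_rris = deque(self.recent_rris, maxlen=self.rr_history)


def matched_filter(signal: np.ndarray, template: QRSTemplate) -> np.ndarray:
    """Sliding cross-correlation of a channel with its QRS template.

    Centred alignment: ``trace[i]`` is the correlation of the template with
    the signal window centred at sample ``i``, so the trace index of a
    maximum is directly the candidate R sample.
    """
    x = np.asarray(signal, dtype=float)
    v = template.waveform
    if v.size > x.size:
        raise ValueError("template longer than signal")
    return sps.correlate(x, v, mode="same", method="auto")


def detect_peaks_single(
    trace: np.ndarray, sampling_rate: float, min_peak_distance_ms: float = 200.0
) -> np.ndarray:
    """Detect local maxima above an adaptive threshold in one trace.

    The threshold is ``median + 0.4 * (max - median)``, which adapts to the
    overall correlation scale without assuming amplifier units; peaks closer
    than ``min_peak_distance_ms`` are pruned (largest kept).
    """
    if min_peak_distance_ms <= 0:
        raise ValueError("min_peak_distance must be positive")
    x = np.asarray(trace, dtype=float)
    if x.size == 0:
        return np.empty(0, dtype=np.int64)
    med = float(np.median(x))
    hi = float(np.max(x))
    if hi <= med:
        return np.empty(0, dtype=np.int64)
    height = med + 0.4 * (hi - med)
    distance = max(1, ms_to_samples(min_peak_distance_ms, sampling_rate))
    peaks, _ = sps.find_peaks(x, height=height, distance=distance)
    return peaks.astype(np.int64)


def trapezoid_kernel(params: DetectionParams, sampling_rate: float) -> np.ndarray:
    """Isosceles trapezoid weight window.

    Length ``round(base_ms * fs)``, central plateau ``round(top_ms * fs)``
    samples at ``trapezoid_height``, linear flanks towards zero.  At 1 kHz
    with defaults: 21 samples long, 3-sample plateau, height 9.
    """
    length = ms_to_samples(params.trapezoid_base_ms, sampling_rate)
    plateau = min(ms_to_samples(params.trapezoid_top_ms, sampling_rate), length)
    if length < 1:
        raise ValueError("trapezoid base shorter than one sample")
    h = params.trapezoid_height
    n_left = (length - plateau) // 2
    n_right = length - plateau - n_left
    left = h * np.arange(1, n_left + 1) / (n_left + 1)
    right = h * np.arange(n_right, 0, -1) / (n_right + 1)
    return np.concatenate([left, np.full(plateau, h), right])


def build_fusion_matrix(
    peak_lists: Sequence[np.ndarray], length: int, kernel: np.ndarray
) -> np.ndarray:
    """Stamp per-channel peak locations into an N x L trapezoid matrix.

    Overlapping trapezoids within one row take the elementwise max, so a
    single channel cannot double-vote for one location; trapezoids are
    clipped at the matrix edges.
    """
    n = len(peak_lists)
    mat = np.zeros((n, length))
    half = (kernel.size - 1) // 2
    for row, peaks in enumerate(peak_lists):
        for p in np.asarray(peaks, dtype=np.int64):
            if not 0 <= p < length:
                raise ValueError(f"peak {p} outside [0, {length})")
            lo, hi = p - half, p - half + kernel.size
            clo, chi = max(0, lo), min(length, hi)
            seg = kernel[clo - lo : chi - lo]
            mat[row, clo:chi] = np.maximum(mat[row, clo:chi], seg)
    return mat


def fuse_channels(
    peak_lists: Sequence[np.ndarray],
    length: int,
    params: DetectionParams,
    sampling_rate: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Fuse per-channel peak lists into a consensus trace and peak train.

    Returns the column-summed fusion matrix (consensus trace) and the
    consensus peaks: local maxima at or above the consensus threshold,
    spaced by the refractory distance.  Unsynchronised noise peaks never
    accumulate enough column mass to clear the threshold.
    """
    if len(peak_lists) == 0:
        raise ValueError("need at least one channel")
    kernel = trapezoid_kernel(params, sampling_rate)
    mat = build_fusion_matrix(peak_lists, length, kernel)
    consensus = mat.sum(axis=0)
    thr = params.threshold(len(peak_lists))
    distance = max(1, ms_to_samples(params.min_peak_distance_ms, sampling_rate))
    # tolerate float round-off at exactly-threshold plateaus
    peaks, _ = sps.find_peaks(consensus, height=thr * (1 - 1e-12), distance=distance)
    return consensus, peaks.astype(np.int64)


def prediction_window(RR_e: float, w: float, sampling_rate: float) -> np.ndarray:
    """Hanning-derived beat-prediction weight window.

    Length ``round(2 * RR_e * fs)`` with its maximum exactly at sample
    ``round(RR_e * fs)`` (the expected next beat); raising the Hanning shape
    to the power ``w`` sharpens the prior ("applied w times"); ``w = 0``
    yields an all-ones window, i.e. no prediction bias.
    """
    if RR_e <= 0:
        raise ValueError("RR_e must be positive")
    if w < 0:
        raise ValueError("w must be non-negative")
    m = s_to_samples(RR_e, sampling_rate)
    length = s_to_samples(2 * RR_e, sampling_rate)
    if w == 0:
        return np.ones(length)
    i = np.arange(length)
    base = 0.5 * (1.0 - np.cos(np.pi * i / m))
    return base**w


def update_expected_rri(state: PredictionState, new_rri: float) -> PredictionState:
    """Push a new RR interval and refresh RR_e.

    RR_e is the mean of the ``rr_history`` most recent intervals; while
    fewer have been observed, the remaining slots are padded with the
    rest-phase mean (``initial_rri``).
    """
    if new_rri <= 0:
        raise ValueError("RR interval must be positive")
    recent = deque(state.recent_rris, maxlen=state.rr_history)
    recent.append(new_rri)
    n = len(recent)
    pad = state.rr_history - n
    rr_e = (sum(recent) + pad * state.initial_rri) / state.rr_history
    return replace(state, recent_rris=recent, expected_rri=rr_e)


def detect_combined(
    recording: Recording,
    templates: Sequence[QRSTemplate],
    params: DetectionParams,
    initial_peak: int,
    initial_RR_e: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Combined multichannel R-peak prediction and detection.

    Starting from a known beat (``initial_peak``, trials start at rest), the
    algorithm iterates: weight each channel's correlation trace over
    ``(R_l, R_l + 2*RR_e]`` with the prediction window, take the per-channel
    weighted maximum as its location marker, fuse the markers with the
    trapezoid consensus, pick the consensus peak with the best
    height + area score, update RR_e, and continue to the end of the record.

    When no consensus clears the threshold (all candidates gated out or
    unsynchronised), a flagged gap is emitted: the detector re-anchors at
    the best raw consensus location in the window so it can recover lock,
    and the re-anchor point is marked in the returned flag array.

    Parameters
    ----------
    recording : Recording
        De-trended multichannel recording.
    templates : sequence of QRSTemplate
        One template per channel to fuse (the selected best-k channels).
    initial_peak : int
        Sample index of a known R-peak near the start.
    initial_RR_e : float
        Mean RR interval (s) of the rest / pattern-finding phase.

    Returns
    -------
    peaks : ndarray of int64
        Strictly increasing beat sample indices (first entry is the anchor).
    flags : ndarray of bool
        True where the entry is a re-anchored gap rather than a confident
        detection.
    """
    if not templates:
        raise ValueError("need at least one template")
    fs = recording.sampling_rate
    n = recording.n_samples
    if not 0 <= initial_peak < n:
        raise ValueError("initial_peak outside the recording")

    traces = [matched_filter(recording.channel(t.channel), t) for t in templates]
    k = len(traces)

    # per-channel running amplitude history for the candidate gate,
    # seeded from the anchor beat
    amp_hist = [deque([abs(tr[initial_peak])], maxlen=8) for tr in traces]

    state = PredictionState(
        last_peak=int(initial_peak),
        expected_rri=initial_RR_e,
        initial_rri=initial_RR_e,
        rr_history=params.rr_history,
    )
    peaks = [int(initial_peak)]
    flags = [False]

    while True:
        r_l = state.last_peak
        rr_e = state.expected_rri
        full_len = s_to_samples(2 * rr_e, fs)
        avail = n - r_l
        # stop when the next expected beat would fall beyond the record
        if avail <= s_to_samples(rr_e, fs):
            break
        win_len = min(full_len, avail)
        window = prediction_window(rr_e, params.w, fs)[:win_len]

        gated: list[int | None] = []
        raw_best: list[int] = []
        for c in range(k):
            seg = traces[c][r_l : r_l + win_len] * window
            j = int(np.argmax(seg[1:])) + 1  # half-open: exclude R_l itself
            raw_best.append(j)
            raw_val = traces[c][r_l + j]
            gate = params.candidate_gate * float(np.median(amp_hist[c]))
            gated.append(j if raw_val >= gate else None)

        accepted = [j for j in gated if j is not None]
        if accepted:
            consensus, cpeaks = fuse_channels(
                [np.array([j]) for j in accepted], win_len, params, fs
            )
            # threshold is based on the full channel count, not just the
            # gated survivors: abstaining channels still count as absent votes
            thr = params.threshold(k)
            cpeaks = cpeaks[consensus[cpeaks] >= thr * (1 - 1e-12)]
        else:
            cpeaks = np.empty(0, dtype=np.int64)

        if cpeaks.size:
            j_star = int(cpeaks[_best_consensus(consensus, cpeaks, params, fs)])
            new_peak = r_l + j_star
            rri = (new_peak - r_l) / fs
            state = update_expected_rri(state, rri)
            state.last_peak = new_peak
            for c in range(k):
                amp_hist[c].append(abs(traces[c][new_peak]))
            peaks.append(new_peak)
            flags.append(False)
        else:
            # gap: re-anchor on the raw (ungated) consensus so the predictor
            # can recover, but mark the emission as unreliable
            consensus, _ = fuse_channels(
                [np.array([j]) for j in raw_best], win_len, params, fs
            )
            j_star = int(np.argmax(consensus))
            if j_star <= 0:
                state.last_peak = r_l + s_to_samples(rr_e, fs)
                continue
            new_peak = r_l + j_star
            state.last_peak = new_peak  # re-anchor without touching RR_e
            peaks.append(new_peak)
            flags.append(True)

    return as_peak_train(peaks), np.asarray(flags, dtype=bool)


def _best_consensus(
    consensus: np.ndarray, cpeaks: np.ndarray, params: DetectionParams, fs: float
) -> int:
    """Index into ``cpeaks`` of the best height + area score."""
    half = ms_to_samples(params.trapezoid_base_ms, fs) // 2
    best, best_score = 0, -np.inf
    for idx, p in enumerate(cpeaks):
        lo, hi = max(0, p - half), min(consensus.size, p + half + 1)
        score = (
            params.score_height_weight * consensus[p]
            + params.score_area_weight * consensus[lo:hi].sum() / (2 * half + 1)
        )
        if score > best_score:
            best, best_score = idx, score
    return best
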