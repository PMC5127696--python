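"""Detection metrics: tolerance matching, Se / +P, heart-rate deviation,
and the classic Pan-Tompkins detector as a single-channel baseline.

A detected peak counts as a true positive when it falls within
``[t_R - dt, t_R + dt]`` of a reference peak (default dt = 10 ms), with
greedy one-to-one nearest matching — provably optimal whenever inter-peak
spacing exceeds 2*dt, which holds for every physiological train.

    Se = TP / (TP + FN)        +P = TP / (TP + FP)

Heart-rate deviation (HRD) is the RMSE between the detected and reference
instantaneous heart rate evaluated every second.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from ._util import ms_to_samples
from .io import as_peak_train
from .preprocess import butterworth_bandpass

__all__ = [
    "MatchResult",
    "match_peaks",
    "sensitivity",
    "positive_predictivity",
    "heart_rate_deviation",
    "pan_tompkins",
]


@dataclass
class MatchResult:
    """Outcome of tolerance-based peak matching.

    Invariants: ``tp == len(matched_pairs)``, ``tp + fn`` equals the number
    of truth peaks and ``tp + fp`` the number of detected peaks.
    """

    tp: int
    fp: int
    fn: int
    matched_pairs: list[tuple[int, int]]
    delta_t_ms: float

    def __post_init__(self) -> None:
        if self.tp != len(self.matched_pairs):
            raise ValueError("tp must equal the number of matched pairs")


def match_peaks(
    detected,
    truth,
    sampling_rate: float,
    delta_t_ms: float = 10.0,
) -> MatchResult:
    """Greedy one-to-one nearest matching within +-delta_t.

    Truth peaks are processed in order; each is matched to the nearest
    still-unused detected peak within the tolerance (ties to the earlier
    candidate).  Each peak on either side is used at most once.
    """
    det = as_peak_train(detected)
    tru = as_peak_train(truth)
    tol = delta_t_ms * sampling_rate / 1000.0
    used = np.zeros(det.size, dtype=bool)
    pairs: list[tuple[int, int]] = []
    lo = 0
    for ti, t in enumerate(tru):
        # candidate window in the detected train
        while lo < det.size and det[lo] < t - tol:
            lo += 1
        best, best_d = -1, math.inf
        j = lo
        while j < det.size and det[j] <= t + tol:
            if not used[j]:
                d = abs(int(det[j]) - int(t))
                if d < best_d:
                    best, best_d = j, d
            j += 1
        if best >= 0:
            used[best] = True
            pairs.append((ti, best))
    tp = len(pairs)
    return MatchResult(
        tp=tp,
        fp=int(det.size - tp),
        fn=int(tru.size - tp),
        matched_pairs=pairs,
        delta_t_ms=delta_t_ms,
    )


def sensitivity(result: MatchResult) -> float:
    """Se = TP / (TP + FN); NaN when no truth peaks exist (undefined)."""
    denom = result.tp + result.fn
    return result.tp / denom if denom else math.nan


def positive_predictivity(result: MatchResult) -> float:
    """+P = TP / (TP + FP); NaN when nothing was detected (undefined)."""
    denom = result.tp + result.fp
    return result.tp / denom if denom else math.nan


def _hr_at(grid: np.ndarray, peaks_s: np.ndarray) -> np.ndarray:
    """Step-interpolated instantaneous heart rate (bpm) at grid times.

    Each time inside ``[first_peak, last_peak)`` takes 60 / RRI of the
    interval containing it; times outside coverage are NaN.
    """
    rri = np.diff(peaks_s)
    idx = np.searchsorted(peaks_s, grid, side="right") - 1
    hr = np.full(grid.shape, np.nan)
    inside = (idx >= 0) & (idx < rri.size)
    hr[inside] = 60.0 / rri[idx[inside]]
    return hr


def heart_rate_deviation(
    detected,
    truth,
    sampling_rate: float,
    duration: float,
) -> float:
    """RMSE between detected and true instantaneous heart rate, per second.

    Both trains are converted to per-second heart-rate series by
    step-interpolating the RR intervals at 1 Hz grid midpoints; boundary
    seconds not covered by both trains are dropped from the RMSE.
    """
    det = as_peak_train(detected)
    tru = as_peak_train(truth)
    if det.size < 2 or tru.size < 2:
        raise ValueError("heart-rate deviation needs at least 2 peaks per train")
    grid = np.arange(0.5, duration, 1.0)
    hr_d = _hr_at(grid, det / sampling_rate)
    hr_t = _hr_at(grid, tru / sampling_rate)
    mask = ~np.isnan(hr_d) & ~np.isnan(hr_t)
    if not mask.any():
        raise ValueError("no common heart-rate coverage between the trains")
    diff = hr_d[mask] - hr_t[mask]
    return float(np.sqrt(np.mean(diff**2)))


# ---------------------------------------------------------------------------
# Pan-Tompkins baseline


def pan_tompkins(channel: np.ndarray, sampling_rate: float) -> np.ndarray:
    """Classic Pan-Tompkins QRS detector (single channel baseline).

    Stages: 5-15 Hz band-pass, five-point derivative, squaring, 150 ms
    moving-window integration, then adaptive signal/noise thresholds with
    search-back.  R-peak locations are refined to the band-passed maximum
    inside each integration event, so timings are comparable at the 10 ms
    matching tolerance.

    Returns an empty train for an all-zero signal.
    """
    fs = sampling_rate
    if fs < 200:
        raise ValueError("Pan-Tompkins requires sampling_rate >= 200 Hz")
    x = np.asarray(channel, dtype=float)
    if x.size == 0 or not np.any(x):
        return np.empty(0, dtype=np.int64)

    bp = butterworth_bandpass(x, fs, 5.0, 15.0, order=2)
    # five-point derivative (1/8)(2x[n] + x[n-1] - x[n-3] - 2x[n-4])
    der = sps.lfilter(np.array([2, 1, 0, -1, -2]) / 8.0, [1.0], bp)
    sq = der**2
    win = max(1, ms_to_samples(150.0, fs))
    mwi = np.convolve(sq, np.ones(win) / win, mode="same")

    refractory = ms_to_samples(200.0, fs)
    cand, _ = sps.find_peaks(mwi, distance=refractory)
    if cand.size == 0:
        return np.empty(0, dtype=np.int64)

    # threshold initialisation from the first two seconds
    init = mwi[: int(2 * fs)] if mwi.size > int(2 * fs) else mwi
    spki = 0.25 * float(np.max(init))
    npki = 0.5 * float(np.mean(init))

    accepted: list[int] = []
    recent_rr: list[int] = []

    def threshold1() -> float:
        return npki + 0.25 * (spki - npki)

    last_accepted_cand = -1
    for ci, p in enumerate(cand):
        if mwi[p] > threshold1():
            spki = 0.125 * mwi[p] + 0.875 * spki
            accepted.append(p)
            if len(accepted) >= 2:
                recent_rr.append(accepted[-1] - accepted[-2])
                recent_rr = recent_rr[-8:]
            last_accepted_cand = ci
        else:
            npki = 0.125 * mwi[p] + 0.875 * npki
            # search-back with the lower threshold when a beat seems missed
            if accepted and recent_rr:
                avg_rr = float(np.mean(recent_rr))
                if (p - accepted[-1]) > 1.66 * avg_rr and mwi[p] > 0.5 * threshold1():
                    spki = 0.25 * mwi[p] + 0.75 * spki
                    accepted.append(p)
                    recent_rr.append(accepted[-1] - accepted[-2])
                    recent_rr = recent_rr[-8:]
                    last_accepted_cand = ci

    # refine: locate the R-peak as the band-passed maximum in the
    # integration window preceding each accepted integrator peak
    out: list[int] = []
    for p in accepted:
        lo = max(0, p - win)
        hi = min(bp.size, p + win // 4)
        r = lo + int(np.argmax(bp[lo:hi]))
        out.append(r)
    out_arr = np.unique(np.asarray(out, dtype=np.int64))

    # enforce the refractory period on the refined train (keep the larger)
    pruned: list[int] = []
    for r in out_arr:
        if pruned and r - pruned[-1] < refractory:
            if bp[r] > bp[pruned[-1]]:
                pruned[-1] = int(r)
        else:
            pruned.append(int(r))
    return np.asarray(pruned, dtype=np.int64)
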