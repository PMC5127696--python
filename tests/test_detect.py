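"""Matched filtering, trapezoid fusion, beat prediction, combined detector."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import multiqrs as mq
from multiqrs.detect import (
    DetectionParams,
    PredictionState,
    build_fusion_matrix,
    detect_combined,
    detect_peaks_single,
    fuse_channels,
    matched_filter,
    prediction_window,
    trapezoid_kernel,
    update_expected_rri,
)

from conftest import make_gaussian_template

FS = 1000.0


class TestMatchedFilter:
    def test_embedded_template_found_at_embedding_point(self):
        tpl = make_gaussian_template()
        sig = np.zeros(2000)
        sig[500 - 45 : 500 + 46] = tpl.waveform
        trace = matched_filter(sig, tpl)
        assert np.argmax(trace) == 500

    def test_inverted_template_gives_minimum(self):
        tpl = make_gaussian_template()
        sig = np.zeros(2000)
        sig[500 - 45 : 500 + 46] = -tpl.waveform
        trace = matched_filter(sig, tpl)
        assert np.argmin(trace) == 500
        assert np.argmax(trace) != 500

    def test_noise_correlation_below_self_match(self):
        tpl = make_gaussian_template()
        sig = np.zeros(2000)
        sig[500 - 45 : 500 + 46] = tpl.waveform
        self_match = matched_filter(sig, tpl).max()
        noise = np.random.default_rng(0).normal(size=2000)
        assert matched_filter(noise, tpl).max() < self_match

    def test_template_longer_than_signal_rejected(self):
        tpl = make_gaussian_template()
        with pytest.raises(ValueError):
            matched_filter(np.zeros(10), tpl)


class TestSinglePeakDetection:
    def _bumps(self, positions, n=1000):
        x = np.zeros(n)
        t = np.arange(-30, 31)
        for i, p in enumerate(positions):
            x[p - 30 : p + 31] += (1.0 - 0.3 * i) * np.exp(-0.5 * (t / 8.0) ** 2)
        return x

    def test_both_bumps_found_when_spacing_allows(self):
        x = self._bumps([300, 700])
        assert list(detect_peaks_single(x, FS, 200.0)) == [300, 700]

    def test_refractory_keeps_only_larger(self):
        x = self._bumps([300, 700])
        peaks = detect_peaks_single(x, FS, 500.0)
        assert list(peaks) == [300]

    def test_flat_trace_gives_empty_train(self):
        assert detect_peaks_single(np.zeros(1000), FS, 200.0).size == 0


class TestTrapezoidKernel:
    def test_reference_geometry_at_1khz(self):
        k = trapezoid_kernel(DetectionParams(), FS)
        assert k.size == 21
        assert (k == 9.0).sum() == 3
        assert k.max() == 9.0

    def test_rounded_geometry_at_500hz(self):
        k = trapezoid_kernel(DetectionParams(), 500.0)
        assert k.size == 11
        assert (k == 9.0).sum() == 2

    def test_symmetric_at_1khz(self):
        k = trapezoid_kernel(DetectionParams(), FS)
        assert np.allclose(k, k[::-1])

    def test_top_wider_than_base_rejected(self):
        with pytest.raises(ValueError):
            DetectionParams(trapezoid_base_ms=3.0, trapezoid_top_ms=21.0)


class TestFusion:
    def test_unanimous_location_sums_heights(self):
        lists = [np.array([400])] * 8
        consensus, peaks = fuse_channels(lists, 1000, DetectionParams(), FS)
        assert list(peaks) == [400]
        assert consensus[400] == pytest.approx(72.0)

    def test_majority_beats_singleton(self):
        params = DetectionParams(consensus_threshold=20.0)
        lists = [np.array([300])] * 5 + [np.array([700])]
        _, peaks = fuse_channels(lists, 1000, params, FS)
        assert list(peaks) == [300]

    def test_empty_lists_give_empty_consensus(self):
        consensus, peaks = fuse_channels([np.array([], dtype=int)] * 3, 500,
                                         DetectionParams(), FS)
        assert peaks.size == 0 and np.all(consensus == 0)

    def test_no_channels_rejected(self):
        with pytest.raises(ValueError):
            fuse_channels([], 100, DetectionParams(), FS)

    @given(st.permutations(list(range(5))))
    def test_permutation_invariance(self, order):
        rng = np.random.default_rng(4)
        lists = [np.sort(rng.choice(900, size=3, replace=False)) + 50 for _ in range(5)]
        base, _ = fuse_channels(lists, 1000, DetectionParams(), FS)
        permuted, _ = fuse_channels([lists[i] for i in order], 1000,
                                    DetectionParams(), FS)
        assert np.allclose(base, permuted)

    def test_monotone_adding_coincident_channel_keeps_peak(self):
        params = DetectionParams(consensus_threshold=20.0)
        lists = [np.array([300])] * 4
        _, before = fuse_channels(lists, 1000, params, FS)
        _, after = fuse_channels(lists + [np.array([300])], 1000, params, FS)
        assert 300 in before and 300 in after

    def test_trace_conservation_against_brute_force(self):
        # with per-channel peaks spaced beyond the kernel, the consensus trace
        # mass equals the sum of (possibly edge-clipped) trapezoid areas
        kernel = trapezoid_kernel(DetectionParams(), FS)
        rng = np.random.default_rng(5)
        for _ in range(20):
            n_ch = rng.integers(1, 6)
            length = int(rng.integers(200, 2000))
            lists = []
            for _ in range(n_ch):
                peaks = np.sort(rng.choice(length, size=rng.integers(0, 5),
                                           replace=False))
                # enforce spacing > kernel so row overlaps cannot occur
                keep: list[int] = []
                for p in peaks:
                    if not keep or p - keep[-1] > kernel.size:
                        keep.append(int(p))
                lists.append(np.array(keep, dtype=int))
            consensus, _ = fuse_channels(lists, length, DetectionParams(), FS)
            expected = 0.0
            half = (kernel.size - 1) // 2
            for peaks in lists:
                for p in peaks:
                    lo, hi = p - half, p - half + kernel.size
                    expected += kernel[max(0, -lo): kernel.size - max(0, hi - length)].sum()
            assert consensus.sum() == pytest.approx(expected)

    def test_row_overlap_takes_max_not_sum(self):
        kernel = trapezoid_kernel(DetectionParams(), FS)
        mat = build_fusion_matrix([np.array([100, 101])], 300, kernel)
        assert mat.max() == 9.0  # one channel cannot double-vote

    def test_minority_never_outscores_unanimity(self):
        k = 7
        params = DetectionParams()
        lists = [np.array([200]) for _ in range(k)]
        minority = (k - 1) // 2
        for i in range(minority):
            lists[i] = np.array([200, 600])
        consensus, peaks = fuse_channels(lists, 1000, params, FS)
        assert consensus[200] > consensus[600]
        assert 600 not in peaks  # below the k/2 threshold


class TestPredictionWindow:
    def test_zero_weight_gives_flat_window(self):
        assert np.allclose(prediction_window(0.8, 0, FS), 1.0)

    def test_unit_weight_peaks_at_expected_beat(self):
        w = prediction_window(1.0, 1, FS)
        assert w.size == 2000
        assert np.argmax(w) == 1000

    def test_power_identity(self):
        w1 = prediction_window(0.7, 1, FS)
        w2 = prediction_window(0.7, 2, FS)
        assert np.allclose(w2, w1**2)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            prediction_window(0.0, 1, FS)
        with pytest.raises(ValueError):
            prediction_window(1.0, -1, FS)


class TestExpectedRRI:
    def _state(self, history, initial=0.8):
        s = PredictionState(last_peak=0, expected_rri=initial, initial_rri=initial)
        for r in history:
            s = update_expected_rri(s, r)
        return s

    def test_constant_history_is_fixed_point(self):
        s = self._state([0.8] * 7)
        s = update_expected_rri(s, 0.8)
        assert s.expected_rri == pytest.approx(0.8)

    def test_window_mean_drops_oldest(self):
        s = self._state([1.0] * 7, initial=1.0)
        s = update_expected_rri(s, 0.3)
        assert s.expected_rri == pytest.approx((6 * 1.0 + 0.3) / 7)

    def test_short_history_padded_with_initial_mean(self):
        s = self._state([0.6, 0.6], initial=0.9)
        # 2 observed intervals + 5 padding slots at the rest-phase mean
        assert s.expected_rri == pytest.approx((2 * 0.6 + 5 * 0.9) / 7)

    def test_non_positive_rri_rejected(self):
        s = self._state([])
        with pytest.raises(ValueError):
            update_expected_rri(s, 0.0)


class TestCombinedDetector:
    def test_single_channel_reduction_tracks_clean_beats(self, clean_labeled):
        rep = mq.detect_and_score(
            clean_labeled, DetectionParams(k_channels=1), channels=["ch0"]
        )
        assert rep["se"] == 1.0 and rep["positive_predictivity"] == 1.0

    def test_output_strictly_increasing_with_positive_rris(self, artifact_labeled):
        rep = mq.detect_and_score(artifact_labeled, DetectionParams())
        peaks = rep["peaks"]
        assert np.all(np.diff(peaks) > 0)

    def test_anchor_outside_record_rejected(self, clean_labeled, clean_template):
        rec = mq.Recording(FS, ["ch0"], clean_labeled.recording.data[:1])
        with pytest.raises(ValueError):
            detect_combined(rec, [clean_template], DetectionParams(k_channels=1),
                            initial_peak=10**9, initial_RR_e=0.8)
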