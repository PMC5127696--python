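"""QRS template extraction, quality scoring, ranking, virtual channels."""

import numpy as np
import pytest

import multiqrs as mq
from multiqrs.template import (
    QRSTemplate,
    channel_quality,
    extract_qrs_template,
    make_virtual_channels,
    rank_channels,
)

FS = 1000.0


def cycle_signal(n_beats=25, rri_samples=800, fs=FS, sigma_ms=8.5, amp=1.0):
    """Signal of identical Gaussian QRS bumps; returns (signal, peak samples)."""
    n = (n_beats + 1) * rri_samples
    x = np.zeros(n)
    peaks = np.arange(1, n_beats + 1) * rri_samples
    half = 120
    t = (np.arange(-half, half + 1)) / fs
    bump = amp * np.exp(-0.5 * (t / (sigma_ms / 1000.0)) ** 2)
    for p in peaks:
        x[p - half : p + half + 1] += bump
    return x, peaks


class TestExtraction:
    def test_identical_cycles_reproduced_exactly(self):
        x, peaks = cycle_signal()
        tpl = extract_qrs_template(x, peaks, FS, channel="a")
        assert tpl.waveform.size == 91  # 45 + 45 + 1 at 1 kHz
        assert np.allclose(tpl.per_sample_sd, 0.0)
        assert np.allclose(tpl.waveform, x[peaks[0] - 45 : peaks[0] + 46])
        assert tpl.n_cycles_used == 20

    def test_burst_cycle_excluded_from_average(self):
        x, peaks = cycle_signal()
        # corrupt the 5th cycle with a 10x amplitude burst
        rng = np.random.default_rng(0)
        p = peaks[4]
        x_burst = x.copy()
        x_burst[p - 45 : p + 46] += rng.normal(0, 10.0, 91)
        tpl = extract_qrs_template(x_burst, peaks, FS, channel="a")
        clean = extract_qrs_template(x, peaks, FS, channel="a")
        assert tpl.n_cycles_used == 19
        denom = np.abs(clean.waveform).max()
        assert np.abs(tpl.waveform - clean.waveform).max() / denom < 0.01

    def test_too_few_cycles_rejected_with_count(self):
        x, peaks = cycle_signal(n_beats=15)
        with pytest.raises(ValueError, match="found 15"):
            extract_qrs_template(x, peaks, FS)

    def test_shift_consistency(self):
        x, peaks = cycle_signal()
        shift = 137
        x2 = np.concatenate([np.zeros(shift), x])
        t1 = extract_qrs_template(x, peaks, FS)
        t2 = extract_qrs_template(x2, peaks + shift, FS)
        assert np.allclose(t1.waveform, t2.waveform)


def make_template(waveform, sd, fs=FS):
    return QRSTemplate(
        waveform=np.asarray(waveform, float),
        per_sample_sd=np.asarray(sd, float),
        n_cycles_used=20,
        quality=None,
        channel="a",
        sampling_rate=fs,
    )


class TestQuality:
    def test_direct_formula(self):
        # R window (centre +-3) at 10, S window (+30 ms +-3) at 2, sd 4
        w = np.zeros(91)
        w[42:49] = 10.0
        w[72:79] = 2.0
        tpl = make_template(w, np.full(91, 4.0))
        assert channel_quality(tpl) == pytest.approx(2.0)

    def test_zero_when_r_equals_s(self):
        w = np.full(91, 5.0)
        tpl = make_template(w, np.full(91, 1.0))
        assert channel_quality(tpl) == pytest.approx(0.0)

    def test_all_zero_sd_rejected(self):
        tpl = make_template(np.zeros(91), np.zeros(91))
        with pytest.raises(ValueError):
            channel_quality(tpl)

    def test_scale_invariance(self):
        w = np.zeros(91)
        w[45] = 8.0
        tpl = make_template(w, np.full(91, 2.0))
        scaled = make_template(3.5 * w, 3.5 * np.full(91, 2.0))
        assert channel_quality(tpl) == pytest.approx(channel_quality(scaled))

    def test_noise_lowers_quality(self):
        x, peaks = cycle_signal()
        rng = np.random.default_rng(1)
        # noise mild enough that cycles still pass the outlier filter
        noisy = x + rng.normal(0, 0.2, x.size)
        q_clean = channel_quality(extract_qrs_template(x + rng.normal(0, 1e-6, x.size), peaks, FS))
        q_noisy = channel_quality(extract_qrs_template(noisy, peaks, FS))
        assert q_clean > q_noisy


class TestRanking:
    def _tpl(self, q, channel):
        t = make_template(np.zeros(91), np.ones(91))
        t.quality = q
        t.channel = channel
        return t

    def test_descending_quality_order(self):
        tpls = [self._tpl(5, "a"), self._tpl(1, "b"), self._tpl(3, "c")]
        assert rank_channels(tpls, 2) == ["a", "c"]

    def test_ties_broken_by_input_order(self):
        tpls = [self._tpl(2, "x"), self._tpl(2, "y"), self._tpl(2, "z")]
        assert rank_channels(tpls, 2) == ["x", "y"]

    def test_full_k_returns_permutation(self):
        tpls = [self._tpl(1, "a"), self._tpl(9, "b"), self._tpl(4, "c")]
        assert sorted(rank_channels(tpls, 3)) == ["a", "b", "c"]

    def test_invalid_k_rejected(self):
        tpls = [self._tpl(1, "a")]
        with pytest.raises(ValueError):
            rank_channels(tpls, 0)
        with pytest.raises(ValueError):
            rank_channels(tpls, 2)

    def test_artifact_free_channels_outrank_corrupted_on_average(self):
        # artifacts injected during the template epoch depress Q: across seeds
        # the mean quality of untouched channels must exceed the mean quality
        # of channels that carried bursts (outlier-cycle exclusion makes the
        # per-channel effect robust but not a strict total ordering)
        wins = 0
        for seed in range(10):
            cfg = mq.SynthConfig(
                duration=20.0,
                rest_duration=0.0,  # allow artifacts from t=0
                artifact_rate=30.0,
                artifact_channel_fraction=0.125,
                seed=seed,
            )
            lab = mq.generate_recording(cfg)
            fs = lab.recording.sampling_rate
            hit = {c for c, _, _ in lab.artifact_intervals}
            clean = [l for l in lab.recording.labels if l not in hit]
            if not clean or len(hit) == 0:
                wins += 1  # degenerate draw, nothing to distinguish
                continue
            qs = {}
            for label in lab.recording.labels:
                y = mq.highpass_detrend(lab.recording.channel(label), fs)
                t = extract_qrs_template(y, lab.true_peak_samples, fs, channel=label)
                qs[label] = channel_quality(t)
            wins += np.mean([qs[l] for l in clean]) > np.mean(
                [qs[l] for l in sorted(hit)]
            )
        assert wins >= 8


class TestVirtualChannels:
    def _rec(self):
        rng = np.random.default_rng(0)
        return mq.Recording(FS, ["a", "b", "c", "d"], rng.normal(size=(4, 500)))

    def test_five_pairs_append_ten_channels(self):
        rng = np.random.default_rng(0)
        rec = mq.Recording(FS, list("abcdef"), rng.normal(size=(6, 400)))
        pairs = [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e"), ("e", "f")]
        out = make_virtual_channels(rec, pairs)
        assert out.n_channels == 16
        assert "a+b" in out.labels and "a*b" in out.labels

    def test_sum_and_standardised_product_values(self):
        rec = self._rec()
        out = make_virtual_channels(rec, [("a", "b")])
        assert np.allclose(out.channel("a+b"), rec.channel("a") + rec.channel("b"))
        assert np.std(out.channel("a*b")) == pytest.approx(1.0)

    def test_degenerate_and_unknown_pairs_rejected(self):
        rec = self._rec()
        with pytest.raises(ValueError):
            make_virtual_channels(rec, [("a", "a")])
        with pytest.raises(ValueError):
            make_virtual_channels(rec, [("a", "zz")])

    def test_cancelling_pair_kept_but_flagged(self):
        x = np.random.default_rng(2).normal(size=300)
        rec = mq.Recording(FS, ["p", "q"], np.vstack([x, -x]))
        with pytest.warns(UserWarning):
            out = make_virtual_channels(rec, [("p", "q")])
        assert np.allclose(out.channel("p+q"), 0.0)
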