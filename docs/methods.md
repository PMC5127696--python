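# Methods

## Detection model and assumptions

The detector rests on two physiological assumptions. First, heartbeats
appear in every channel of a multichannel biopotential recording at almost
the same instant (residual inter-channel delays of a few milliseconds come
from electrode geometry), while motion artifacts — however large — strike
only subsets of channels and are not synchronised across them. Second,
consecutive RR intervals vary slowly around their local mean, so the next
beat can be predicted from recent history. The first assumption drives the
trapezoid-consensus fusion; the second the Hanning prediction window. The
prediction prior deliberately trades the ability to catch ectopic beats for
robustness to noise; records dominated by arrhythmia are out of scope.

Matched filtering uses per-channel templates extracted against a *common*
reference clock (the chest-reference annotations), so each channel's
conduction delay is baked into its template and the per-channel correlation
maxima align on the reference timeline without explicit delay correction.
This is why the consensus peak of a clean recording is sample-exact.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| template window | ±45 | ms | QRS span averaged per channel |
| cycles averaged | 20 | – | rest beats per template |
| quality windows | ±3 around R, ±3 around R+30 | ms | numerator of Q |
| k_channels | 7 | – | channels fused |
| trapezoid base/top/height | 21 / 3 / 9 | ms, ms, units | fusion stamp; base absorbs inter-channel delays |
| consensus threshold | (k/2)·height | units | majority rule |
| w | 2 | – | Hanning window power; higher = stronger rhythm prior |
| rr_history | 7 | beats | RR_e = mean of the last 7 RRIs |
| min peak distance | 200 | ms | physiological refractory period |
| candidate gate | 0.5 | fraction | per-channel vote amplitude floor |
| Δt | 10 | ms | matching tolerance for Se / +P |

Millisecond-specified windows are converted to samples with round-half-up,
so the classic counts (21/3-sample trapezoid, 91-sample template) hold
exactly at 1 kHz and scale consistently at other rates.

Numerical conventions: sample indices are 0-based; on-disk annotations are
seconds (rate-portable); the beat search interval (R_l, R_l + 2·RR_e] is
half-open so a boundary candidate belongs to the next interval; all filters
are Butterworth applied forward–backward (zero phase) so peak times carry no
systematic group delay — the sources describing this pipeline do not fix the
phase convention, and zero-phase keeps timing unbiased at the 10 ms
tolerance. Overlapping trapezoids within one channel take the elementwise
max, not the sum, so a single channel can never double-vote a location.
Before a short RR history exists, RR_e is the mean of the observed intervals
padded with the rest-phase mean.

Two further choices were genuinely open:

* **Per-channel candidate gate.** The per-channel vote inside a search
  window is an argmax and always exists, even when no beat is present (end
  of record, deep signal loss). A vote is therefore only accepted when its
  raw correlation exceeds 0.5× the running median correlation amplitude of
  recently accepted beats (last 8, seeded from the anchor beat). For the
  synthetic morphology the T-wave cross-correlates at ≈0.42 of the R
  self-correlation, so 0.5 separates lone T-waves from genuine beats while
  leaving noisy true beats untouched. When every vote is gated out or votes
  do not reach consensus, the detector emits a *flagged gap*: it re-anchors
  at the best raw consensus so it can recover lock, and the flag marks the
  entry as unreliable. Flagged entries are excluded from Se/+P scoring.
* **Consensus scoring.** "Height and area" of the consensus peak are
  combined 1:1 (height plus mean consensus within one trapezoid base);
  both weights are exposed in `DetectionParams`.
* **Outlier cycles** during template extraction (the sources say only that
  outliers are excluded) are defined as cycles correlating < 0.8 with the
  elementwise median cycle or whose peak amplitude deviates > 2.5 robust
  z-scores from the median — robust and parameter-light.

## The synthetic generator

The generator emulates the recording conditions the detector is designed
for, with defaults fixed to the movement-protocol conditions used in the
acceptance run: 1 kHz, 120 s, 8 channels, mean RRI 0.8 s, RSA depth 0.05 at
0.25 Hz respiration, channel gains 0.1 (face-lead amplitudes ≈10× smaller
than chest; the exact ratio is a modelling choice, exposed in config),
channel delays spread over 1–6 ms, white noise sd 0.01, and artifact bursts
at 6 events/min with amplitude 3× the R-peak hitting round(0.375·8) = 3
random channels per event after a 20 s artifact-free rest epoch.

Component models:

* ECG cycle: three Gaussian bumps (P, QRS, T) with amplitudes
  0.15 : 1 : 0.3, QRS FWHM 20 ms, P at −160 ms (sd 25 ms), T at +250 ms
  (sd 50 ms). Sufficient morphology for matched filtering; no dipole-level
  (Heart Vector) forward model.
* RR intervals: RRI_k = mean·(1 + depth·sin φ_k)·j_k with φ_k the
  respiration phase at the beat and j_k mean-one lognormal jitter
  (sd 1 % of the mean), keeping intervals positive and RRI extrema locked
  to respiration extrema (the RSA signature).
* Baseline wander: per-channel sinusoid at 0.2–0.4 Hz, amplitude 0.5× the
  channel's R amplitude.
* Artifacts: 2–40 Hz band-limited noise bursts of 0.2–1.0 s, Tukey-tapered,
  drawn independently per hit channel (artifacts in different channels are
  unrelated), event count Poisson at the configured rate.
* EEG responses: alpha/SSVEP are a sinusoid in pink noise at the requested
  SNR; the ASSR case returns both the amplitude-modulated stimulus (1 kHz
  carrier, unit modulation depth — spectral lines at carrier and
  carrier ± f0, none at f0) and the demodulated neural response (sinusoid
  at f0 in pink noise). The stimulus carries a −60 dB white noise floor:
  a recorded stimulus is never mathematically noise-free, and spectral
  ratios far from the carrier are only meaningful above a physical floor.

Ground truth R-peak times are sample-aligned before per-channel delays and
stored in seconds. Fixed seeds give bit-identical output.

What the generator does **not** model — and hence what passing tests do not
establish for real data: realistic EEG background mixtures, electrode-
impedance drift, beat-morphology variability (amplitude and shape are
constant within a record), ectopic beats, simultaneous whole-array impacts,
and PPG/BCG modalities. Performance numbers on this generator are
simulation surrogates, not clinical claims.

## Evaluation

Greedy one-to-one nearest matching within ±Δt processes truth beats in
order; it is provably optimal (equal to exhaustive assignment) whenever
inter-peak spacing exceeds 2·Δt, which every physiological train satisfies
at Δt = 10 ms, and runs in O(n log n). HRD step-interpolates each train's
RR intervals at 1 Hz grid midpoints, converts to bpm, and takes the RMSE
over seconds covered by both trains (uncovered boundary seconds dropped).
The Pan–Tompkins baseline follows the classic stages (5–15 Hz band-pass,
five-point derivative, squaring, 150 ms integration, adaptive dual
thresholds with search-back) with R locations refined to the band-passed
maximum of each integration event so its timing is comparable at the 10 ms
tolerance.

The grid search scans all 510 integer band-pass ranges (f_min 1–20 Hz,
f_max from max(f_min+5, 6) to 40 Hz), scoring each by sensitivity on a
ground-truthed channel; ranking ties break toward narrower bandwidth. Other
decompositions (e.g. multivariate empirical mode decomposition, published
elsewhere) can be plugged in through the `decompose` callback but are not
implemented.

## Problem sizes

The test suite and the acceptance script use 60 s recordings for the clean
checks and ten 120 s recordings for the movement protocol — long enough
that each record contains ~75/150 beats and ~10 artifact events, which is
where the multichannel/single-channel contrast and the ≥90 % bounds are
meaningfully exercised, while the whole suite completes in well under a
minute on one core.

## Known limitations

* Template morphology is assumed stationary within a session (templates are
  extracted once from the rest epoch; no adaptive updating).
* The prediction prior delays recovery after a run of missed beats by
  design; gaps are flagged rather than silently interpolated.
* Virtual channels (pairwise sums and re-standardised products of
  neighbouring electrodes) are supported but which electrode pairs are
  "neighbours" is geometry-dependent and must be supplied by the user.
* Se/+P become undefined (reported as NaN) on empty trains; callers must
  check.
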