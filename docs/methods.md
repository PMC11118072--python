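# Methods

This note documents the signal model behind the synthetic generator, the
concrete definitions and defaults of every processing stage, the numerical
choices that were genuinely open, and what the synthetic benchmark does and
does not demonstrate about real surface EMG.

## Synthetic sEMG model

The generator (`myowrite.synth`) emulates a word-handwriting acquisition
session: one recording per word class, each containing `reps_per_class`
(default 10) activation epochs of `word_duration` (default 1.5 s) separated
by `rest_duration` (default 5 s) of rest, on `n_channels` (default 6)
channels at `fs` = 1000 Hz, preceded by a 2 s lead-in.

Surface EMG during a contraction is modelled phenomenologically as
band-limited Gaussian noise amplitude-modulated by a slow envelope — the
standard interference-pattern abstraction, not a motor-unit (MUAP-train)
simulation.

**Stroke (letter) library.** Handwritten words are built from a shared
repertoire of strokes, so each simulated subject owns a library of
`n_letter_types` (default 64) letters drawn once from a seed-keyed stream.
A letter consists of

- a cross-channel amplitude pattern, uniform in 0.15–1.0 mV per channel
  (which muscles the stroke recruits, and how strongly);
- a per-channel carrier resonance frequency, uniform in 60–240 Hz, applied
  as a peaking filter (Q = 1.5) before the band limit (the within-band
  spectral shift that different recruitment produces);
- a tremor-like slow amplitude modulation, 3–15 Hz at relative depth
  0.1–0.6 (physiological tremor riding on the stroke).

A word class is a sequence of 3–8 letters at evenly spaced stroke times
(jittered, widths 0.45–0.9 of the spacing so consecutive strokes overlap
and the word stays continuously active). Because different words draw from
the same library, words sharing letters produce genuinely ambiguous
analysis windows — the property that caps single-window accuracy and makes
decision smoothing worthwhile, exactly as with real words sharing letters.

**Carrier.** Each stroke's carrier is an independent Gaussian process:
white noise, peak-filtered at the letter's resonance, mixed with a
spectrally flat component (10 % power), then limited to 35–450 Hz by the
same 4th-order Butterworth used in preprocessing and normalised to unit
variance. The flat admixture reflects that real interference patterns are
never purely resonant; numerically it also keeps 150-sample Yule–Walker
estimates away from the unit circle, where their variance would explode.

**Repetition variability.** Per repetition, every stroke's amplitude is
jittered by ±5 % and its time by ±50 ms (shared across channels — the
whole pen stroke shifts), and the tremor phase is redrawn.

**Amplitude and noise.** Every recording is normalised to the same
channel-averaged activation power (0.5 mV RMS), so words are not
distinguishable by loudness; absolute amplitudes are otherwise arbitrary —
no claim is made of matching real recording magnitudes. A single
band-limited instrumentation-noise level per recording is then added
everywhere, calibrated so the channel-averaged activation/rest power ratio
equals `snr_db` (default 20 dB) exactly for positive SNR; `snr_db = inf`
yields a silent baseline, and `snr_db <= 0` is flagged as a
low-separability regime (the exact calibration has no solution there and
the generator falls back to `P/10^(snr/10)`).

**Reproducibility.** All randomness flows from `SeedSequence` streams keyed
by (seed, subject, label): identical configurations are bit-identical,
different subjects/labels/seeds are independent.

## Preprocessing and onset detection

Band-pass: Butterworth, design order 4, 35–450 Hz, applied forward-backward
(`sosfiltfilt`) for zero phase; recordings shorter than three padding
lengths are rejected.

Onset detection operates on the across-channel mean of per-channel moving-
RMS envelopes (100 ms window). The threshold is `μ_rest + k·σ_rest` with
k = 3, where the rest statistics are the envelope's median and scaled MAD
(1.4826·MAD): rest dominates the record, so these robust statistics
estimate the baseline without rest labels, and unlike truncated-tail
estimates they are not biased below the noise floor. Supra-threshold runs
closer than 500 ms are merged and runs shorter than 250 ms discarded. All
four parameters are exposed. The threshold is data-driven, making detection
invariant to global amplitude scaling.

## Features

Windows of round(0.150·fs) samples advance by round(0.075·fs) inside each
segment; a segment of L samples yields floor((L−W)/S)+1 windows. Per
channel and window:

- **Amplitude/complexity:** IEMG = Σ|x|; MAV = IEMG/N; VAR = Σx²/(N−1);
  RMS = √(Σx²/N); WL = Σ|Δx|; DAMV = WL/(N−1); DASDV = √(Σ(Δx)²/(N−1)).
- **Threshold-gated counts** (shared deadzone ε): ZC counts sign changes
  with |Δx| ≥ ε; MYOP = mean(|x| ≥ ε); WAMP counts |Δx| ≥ ε; SSC counts
  local extrema with at least one flank ≥ ε. Default
  ε = 0.01 × per-recording baseline (outside-segment) RMS, resolved per
  recording and stored with the feature parameters.
- **HIST:** 10 bin counts over that window's [min, max].
- **Fuzzy entropy:** embedding m = 2, tolerance r = 0.15 × window SD,
  exponential membership exp(−(d/r)²) on Chebyshev distances of locally
  demeaned templates; ln φ_m − ln φ_{m+1}; constant windows return 0 by
  convention.
- **Weighted permutation entropy:** ordinal patterns of order 3, delay 1,
  weighted by embedded-vector variance, normalised by log(3!) to [0, 1];
  constant windows return 0.
- **AR/CC:** Yule–Walker with biased autocorrelation on the demeaned
  window, order 4, in the polynomial sign convention
  (x_t + Σ a_k x_{t−k} = e_t); cepstral coefficients by the recursion
  c₁ = −a₁, c_p = −a_p − Σ_{l<p} (1−l/p)·a_l·c_{p−l}.
- **Spectral:** one-sided Hamming-tapered periodogram, constant-detrended,
  zero-padded to 256 points. TTP = ΣP; SMk = Σfᵏ·P; MNF = SM1/TTP;
  MDF = first bin where cumulative power reaches half; PKF = argmax;
  FR = power(35–135 Hz)/power(135–450 Hz) (split at 135 Hz inside the
  filtered band); PSR = power within ±10 bins of the peak over TTP;
  VCF = SM2/TTP − (SM1/TTP)².

The full matrix has channels × 41 = 246 columns
(13 TD scalars + 10 HIST + 4 AR + 4 CC + 10 FD); the named sets
(*Hudgins* = MAV, WL, SSC, ZC; *Du* = IEMG, VAR, WAMP, WL, SSC, ZC;
*Phinyomark 1* = MAV, WL, WAMP, ZC, AR, MNF, PSR;
*Phinyomark 2* = WPermEN, CC, RMS, WL;
*TDAR* = MAV, SSC, WL, VAR, WAMP, AR, ZC) are column sub-selections.
All extractors are batch-vectorised and verified against independent
direct-definition oracles in the test suite.

## Classifiers

Balanced split: per class, 70 % train (round, clamped) and 30 % test, with
cyclic fold assignment giving per-class fold counts balanced within one;
deterministic in the seed. Cross-validation refits from scratch per fold
and is reported as a diagnostic (nothing is tuned by default).

- **LDA:** Gaussian classes with shared *diagonal* covariance (pooled
  per-feature within-class variance, floored at 1e−12 with a warning),
  empirical priors. Scale-free per feature.
- **SVM:** linear kernel, C = 1, one-vs-one, on features in their native
  units with a bounded solver budget (10 000 iterations per binary
  subproblem, exposed). Running the margin model unscaled mirrors the
  default behaviour of the field's common toolchains and is what produces
  the characteristic weakness of the linear SVM on these mixed-unit
  features; z-scoring the SVM instead makes it the strongest model and
  inverts the benchmark's qualitative ordering.
- **KNN:** k = 2, Euclidean, on z-scored features (scaler fit on train
  only). A 1–1 tie goes to the nearer neighbour, so k = 2 behaves as a
  deterministic nearest-neighbour rule.

## Majority voting and metrics

The smoothed decision at position t is the modal label of the centred
window of M+1 votes (M/2 before and after, M even, default 4); stream
edges use truncated windows (no fabricated votes) and smoothing never
crosses recording boundaries. Ties keep the centre vote when tied,
otherwise the most recent tied label — both choices avoid spurious
switching. Timing: input rate 1/step, latency (M/2)·step, output rate its
reciprocal; at M = 4 and 75 ms: 13.33 Hz, 150 ms, 6.66 Hz.

Metrics come from the confusion matrix: headline accuracy is the overall
correct fraction; precision, recall, F1 and MCC are computed one-vs-rest
per class and macro-averaged. F1 is the standard harmonic mean 2PR/(P+R).
Zero-denominator cells score 0 with a warning. Condition comparisons use
the two-sided Wilcoxon signed-rank test at α = 0.05 on paired per-subject
values; all-zero differences return p = 1.

## Experiments

`run_experiment` simulates a cohort (default 6 subjects — one independent
synthetic dataset per subject, with its own letter library and envelope
draws, as intra-subject modelling requires). Experiment 1 trains the three
classifiers on the full 246-column matrix and writes the per-subject
Acc/F1/MCC table with an average row; experiment 2 evaluates the five named
sets × three classifiers × {MV off, MV on} and adds the pairwise Wilcoxon
set-comparison table. The full matrix is extracted once per subject and
sets are sliced from it. All randomness derives from one root seed recorded
in the run log.

## Problem sizes used in the tests

The acceptance-style tests run three simulated subjects at the default
study conditions (30 classes, 10 repetitions, 1.5 s words, 20 dB), about
6 000 windows each; unit tests use 2–12-class protocols with shorter words
and rests, and the SNR-monotonicity property runs 12 classes × 5
repetitions over 6 seeds at 0/10/20 dB through the full
detection-segmentation path. These sizes keep the suite within a few
minutes while leaving every assertion at realistic operating points.

## What the synthetic benchmark shows — and does not

Passing tests demonstrate that the pipeline is internally correct (features
and metrics match independent definitions), that the segmentation recovers
a known protocol, and that the classifier benchmark reproduces the expected
qualitative structure on data with letter-sharing ambiguity: KNN clearly
ahead of the linear SVM, the diagonal LDA far behind, and majority voting
lifting every classifier. They do not certify performance on real
recordings: the generator has no electrode lift-off or motion artifacts, no
inter-subject transfer, no fatigue drift, and its class structure — however
deliberately confusable — is cleaner than real motor variability.

Two further limitations are worth naming. First, with z-scored
nearest-neighbour classification the full 246-column matrix pays a
dimensional-dilution penalty, and a compact spectral set (*Phinyomark 2*,
through its cepstral columns) can match or exceed the full set on this
synthetic task — on real data the many weakly complementary features
apparently more than repay that penalty. Second, class separability versus
SNR saturates near 20 dB: the 0→10 dB gain is large, the 10→20 dB gain
small, because moderate noise partially regularises the short-window AR
and count estimators.
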