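# Methods

## Signal model and preprocessing

Recordings are 8-channel signed sEMG sampled at 1 kHz (channels C1/C3:
left/right biceps; C2/C4: triceps; C5/C8: brachioradialis; C6/C7: flexor
carpi).  Preprocessing applies a zero-phase (forward–backward) 4th-order
Butterworth band-pass at 20–250 Hz.  No power-line notch is applied: the
band-pass already brackets the usable EMG band and a digital notch removes
useful energy.  Half-wave rectification followed by a centred 5-point moving
average produces the envelope used *only* by the event detector; all feature
computation uses the band-passed signal.  Moving-average endpoints use
shrinking symmetric windows (length preserved, constants reproduced
exactly); this edge rule is a package choice where several are defensible.

Epoch normalization divides every sample of every detected epoch by the
maximum *absolute* epoch sample per (subject, channel), storing the divisor.
The absolute-value reading keeps normalized samples in [−1, 1] for signed
signals.

## Sample-entropy event detection

SampEn(m, r, N) = −ln(A/B), with B the count of length-m template pairs
within Chebyshev distance r (self-matches excluded) and A the count at
length m+1, both over the first N−m template positions.  Degenerate windows
(A = 0 or B = 0) return the finite ceiling −ln(2/((N−m−1)(N−m))) — the
smallest conditional probability resolvable from N points — and are flagged,
so a sliding series never contains infinities.

The detector computes SampEn in a 64-sample rectangular window stepped by
30 samples over the rectified/smoothed biceps envelope, with a *global*
tolerance r = 0.25·SD(whole trial).  The global r is what turns an
amplitude-agnostic irregularity measure into an activity detector: baseline
segments vary on a scale ≪ r (nearly all templates match, SampEn ≈ 0) while
burst segments vary on a scale ≫ r (SampEn large).

Start marks require 3 consecutive windows above `0.02 · max(series)`, end
marks 2 consecutive windows below `0.01 · max(series)` (the anti-shake
rule).  The threshold reference is the series maximum — a relative reading,
since no absolute reference is defined for SampEn values; an absolute
threshold mode is available by configuration.  Window indices map to sample
indices conservatively: epoch start = first window start of the opening run;
epoch end = first window start of the closing run + window length.  An
unterminated start is closed at the final sample.  Candidates are kept only
if they are longer than 1050 samples, their peak |amplitude| exceeds
0.35 × the trial's peak |amplitude|, and they span less than 95% of the
trial — the last filter discards the no-contrast detection produced when an
activity-free trial never crosses the end threshold.

Intervals accepted on a biceps channel are cut from all four same-arm
channels (C1→{C1,C2,C5,C6}, C3→{C3,C4,C7,C8}).

**Operating point.** With relative thresholds of 2%/1% of the series
maximum, epoch closure requires the baseline SampEn to sit below 1% of the
in-burst values.  Empirically this holds when burst amplitudes exceed the
baseline by roughly 22 dB at curl-like duty cycles (~40–50% of the trial
active); at 20 dB the detector still counts events correctly but boundary
placement degrades beyond the window/step quantization (±154 samples at the
default parameters).  The synthetic generator's default operating point is
~24 dB, consistent with clean recordings of loaded contractions.

## Feature bank

Each epoch yields 63 values: 41 time-domain catalog features (AR(4)
expands to 4 coefficients) and 9 frequency-domain features (SM expands to
SM0–SM3; the level-3 wavelet packet decomposition expands to 8 node norms),
i.e. 44 TD + 19 FD values.  The registry order is the catalog order; the
compact groups used in evaluation are

* `F12B`: ASM, AR4, AAC, DAMV, LTKEO, SSI, SD, WL, DUR, PKF, SM0, WP5
  (nine TD + three FD), and
* `F16B` = F12B + {ASS, AR2, CARD, MNF}.

Notable conventions (all surfaced in `registry_json()`):

* Fractional-power features (ASM, ASS, EMAV, EWL, MSR) act on |x| — the
  band-passed signal is signed and non-integer powers of negatives are
  undefined.  ASM's exponent is 0.5 for 1-based indices in
  [0.25 N, 0.75 N] and 0.75 outside.
* CARD sorts the epoch before counting adjacent gaps > 0.01 (the count of
  distinguishable amplitude levels); sorting keeps the feature
  deterministic, and a literal random-permutation mode exists behind the
  `order="shuffle"` argument.
* AR coefficients are Yule–Walker (adjusted autocovariances, demeaned
  signal) with the convention y(n) = Σ a(k) y(n−k) + e(n).
* The spectrum is a one-sided periodogram of the detrended epoch with the
  DC bin excluded.  FR splits the 20–250 Hz band at 135 Hz (configurable);
  PSR integrates ±10 Hz around the peak; SMk = Σ P f^k for k = 0..3
  (four moments — the only expansion consistent with the 63-value total);
  VCF = SM2/SM0 − (SM1/SM0)².
* Wavelet packet features use `db1` with periodized boundaries on the epoch
  truncated to a multiple of 8, making the transform exactly orthogonal:
  node norms preserve the epoch's energy.  Nodes are in natural order, so
  `WP5` is node (3, 4).
* Thresholded features (ZC, SSC, WA, MYOP, CARD) default their threshold to
  0.01 on normalized (unit-peak) amplitude.
* Degenerate cases produce documented sentinels instead of exceptions:
  LTKEO of a non-positive Teager–Kaiser sum is NaN; COV/LCOV of a zero-mean
  epoch is NaN; LD of an epoch containing an exact zero is 0 (the limit of
  exp(mean log |x|)).
* Catalog names without a unique published formula (AE, MAS, VARe, VO,
  LDMA, LDASDA, FZC) are implemented per the closest standard definitions
  and flagged `interpretation: true` in the registry: AE = mean(x²),
  MAS = mean |x − x̄|, VARe = Σx²/(N−1), VO = √mean(x²),
  LDMA = ln(DAMV), LDASDA = ln(DASDV), FZC = ungated zero crossings.

Feature tables are standardized per (feature, channel) pooled over both
groups; zero-variance cells are flagged and centred only, and the
transformation is exactly invertible.

## Feature reduction

The per-(feature, channel) group-difference matrix uses pooled-variance
two-sample t-tests at α = 0.05 (Welch optional); no multiple-testing
correction is applied by default (a Benjamini–Hochberg option exists).  The
consistency matrix averages each epoch's features over its channels, then
z-scores the averaged columns — one-way ICC compares absolute values, so the
columns must share location and scale — and computes the pairwise one-way
random-effects single-rater ICC with epochs as targets.

The staged reduction:

* **Stage 1** keeps features with H = 1 in at least
  ⌈0.25 · n_consulted⌉ consulted channels (configurable).  The breadth
  fraction was fixed by calibrating on the default synthetic cohort so the
  stage ladder lands near 63 → ~50 → ~15 → 12, the shape this reduction is
  designed to produce; the exact stage conditions are otherwise open, and
  every threshold used is echoed in `SelectionResult.config`.
* **Stage 2** groups survivors by ICC > 0.8 using greedy leader grouping in
  registry order (transitive connected components would chain nearly all
  amplitude-driven features into one group) and keeps one representative
  per group: the feature with the lowest mean p over consulted channels,
  ties broken by registry index.
* **Stage 3** keeps the 12 (configurable) features with the lowest mean p.

Method A consults all 8 channels; Method B drops C6 from every p/H
condition, so its output is provably invariant to corruption of C6
statistics.  Stages are strictly nested and Z1 ∪ Z2 ∪ Z3 ∪ selected
partition the 63 features.

## Classification protocol

Per (channel, feature group, model): 20 repeats of stratified 10-fold
cross-validation, each repeat reshuffling with a seed derived from the
configured shuffle seed.  Accuracy is the fold mean of (TP+TN)/(P+N), held
as a fraction and ×100 only for display.  Models (hyperparameters fixed and
recorded): LDA; SVC with inhomogeneous quadratic kernel (degree 2, coef0 1,
C 1, scaled gamma); SVC with RBF kernel (C 1, scaled gamma); and a
subspace-discriminant ensemble of 30 LDA learners on random feature subsets
of size ⌈d/2⌉ voting by averaged posterior (a soft vote; the standard
construction uses majority voting, which differs negligibly for
well-calibrated LDA posteriors).  Aggregates pool per-repeat accuracies
across channels, with the pooling mode recorded in the report header.

Group comparisons use dB = |log10 p| of a pooled two-sample t-test on
accuracy collections; dB ≤ 1.301 (p ≥ 0.05) flags "no significant
difference".  Identical zero-variance collections take the p = 1 path.
Within one subject group and channel, a one-way ANOVA across the 12
standardized feature columns (observations = epochs) is followed, when
significant, by Tukey's HSD pairwise matrix (NaN diagonal).

## Synthetic data generator

The generator emulates the acquisition design: per trial, six cycles of
4–5 s (drawn uniformly), left-arm burst at each cycle start, right-arm burst
half a cycle later, ~2 s bursts, 1 s lead-in/out, ~30 s total; five trials
per subject; channels of an arm share burst timing with channel-specific
amplitude factors (biceps 1.0, triceps 0.55, brachioradialis 0.7, flexor
0.45) and independent noise.

A burst is white Gaussian noise band-passed to ±40 Hz around the subject's
median frequency (clipped inside 20–250 Hz), shaped by a two-lobe envelope
(high flexion peak, lower extension peak).  Bursts ride on unit-variance
20–250 Hz baseline noise.  The amplitude scale is the burst's **peak**
relative to the baseline SD (default 90, burst SNR ≈ 24 dB; envelope and
crest factor put burst RMS near peak/6).  Peak control makes the
normalization divisor (a per-subject maximum) essentially deterministic;
if burst RMS were controlled instead, the divisor's extreme-value scatter
becomes a subject-level random effect that a pooled-epoch cross-validation
can memorize, lifting null-cohort accuracy above chance.

Per-burst gains jitter downward from a ceiling of 1
(`exp(−|N(0, 0.1)|)`), and per-subject jitter (log-normal amplitude σ 0.15,
median frequency σ 5 Hz, duration σ 0.05 s — artifact choices, echoed in
the cohort metadata) is drawn once per subject *slot* and shared between
groups: professional subject *i* is amateur subject *i* with the class
effects (amplitude ratio, median-frequency shift, duration ratio; defaults
2.0, +30 Hz, 1.1) applied on top.  Identity effects therefore make the two
groups distributionally exchangeable, and downstream classification is at
chance.

What the generator does **not** model: motor-unit physiology, electrode
artifacts, movement crosstalk between arms, fatigue-related spectral drift
within a trial, and power-line interference.  Passing tests therefore
demonstrate the pipeline's correctness and its behavior under controlled
class effects — not classification accuracy on real recordings.

## Problem sizes and determinism

The default cohort (5+5 subjects × 5 trials × 6 cycles, 1 kHz) yields
300 epochs per channel; a full simulate→detect→features pass takes on the
order of a minute on one core, and the test suite exercises reduced cohorts
(2+2 × 2 trials) where the full design is not needed.  All randomness flows
from explicit seeds (cohort seed → subject/trial streams; CV shuffle seed →
per-repeat streams), so every stage is bit-reproducible.

## Known limitations

* The detector's relative thresholds presuppose dominant bursts; recordings
  with weak activity (≲ 20 dB burst SNR) or near-continuous activity need
  the absolute-threshold mode or adjusted factors.
* Epochs from the same subject appear in both CV folds (the protocol pools
  epochs before stratifying); with real between-subject variability this
  inflates absolute accuracies relative to a subject-held-out design.
* The ICC matrix is computed on channel-averaged, re-standardized features;
  features whose sign flips across channels could cancel in the average.
* Feature identities flagged `interpretation` in the registry follow
  plausible published definitions but are not uniquely fixed by name.
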