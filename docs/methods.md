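# Methods

This note documents the models, numerical choices and limitations behind
`mirrortrail`. It is written for a reader who wants to know exactly what the
code computes and why each open design point was resolved the way it was.

## Signal preprocessing

Mirror-game traces arrive with variable sampling (90–140 Hz Solo, 40–70 Hz
leader–follower) and positions in arbitrary units saturating at ±0.5. The
chain, in fixed order:

1. **Resampling** to a uniform 100 Hz grid by linear interpolation, never
   extrapolating beyond the recorded span. For leader–follower trials both
   traces are interpolated onto one shared grid covering the intersection of
   their spans.
2. **Low-pass filtering**: second-order Butterworth, 5 Hz cut-off, applied
   forward–backward (`filtfilt`). "Second order" names the filter design;
   the zero-phase double pass has a fourth-order magnitude response. Human
   horizontal hand motion in this task lives well below 5 Hz, so the
   passband distortion of behaviourally relevant content is negligible
   (verified: <1 % amplitude error and no phase lag for a 1 Hz tone).
3. **Margin trimming**: the first and last 5 s are discarded (task onset and
   offset artefacts).
4. **Velocity**: fourth-order central differences,
   `v_i = (−x_{i+2} + 8x_{i+1} − 8x_{i−1} + x_{i−2})/(12h)`. The two samples
   at each end where the stencil does not fit are dropped (margins are
   already trimmed, so a one-sided stencil would buy 40 ms at the cost of
   non-uniform accuracy); position, velocity and the validity mask are
   cropped to the same grid. The truncation bound `max|x⁽⁵⁾| h⁴/30` is
   attained in tests.

**Saturation excision.** Samples with `|x| ≥ 0.5 − 10⁻⁶` (the tolerance
absorbs floating-point representation of the rails) are marked invalid on
the *raw* trace; the mask is carried onto the uniform grid by interpolating
the saturation indicator, so any grid point influenced by a saturated raw
sample is excluded. Exclusion happens at feature-pooling time — the masked
samples still pass through the filter (a gap-aware filter would be a much
larger intervention), and their wavelet leakage into neighbouring samples is
accepted; the margin trim removes the strongest edge effects, and no
cone-of-influence masking is applied beyond it.

## Wavelet features

**Transform.** Analytic Morlet wavelet, centre parameter ω₀ = 6, evaluated
in the frequency domain: one FFT of the demeaned signal zero-padded to the
next power of two ≥ 2n, Gaussian windows
`(πB)^{-1/4}·sqrt(2πs/dt)·exp(−(sω−ω₀)²/2)` per scale (zero at ω ≤ 0), one
batched inverse FFT. Scale↔frequency uses the exact Morlet Fourier factor
`(ω₀ + sqrt(2+ω₀²))/4π`. Demeaning makes invariance to constant position
offsets exact — without it a DC offset would leak through the padding edges.

**Grids.** Logarithmic, 16 voices per octave, anchored at the top of each
band so that the "power at 5 Hz" and "censored at 2 Hz" feature values sit
exactly on grid points: [0.25, 5] Hz for global spectra (70 points),
[1/15, 2] Hz for relative phase (79 points). "Within one grid step" in tests
means a factor of 2^{1/16} ≈ 4.4 %.

**Global wavelet spectrum.** Per trial, wavelet power is averaged over valid
(unmasked) times; trials are pooled weighted by their valid duration; the
pooled spectrum is normalised to unit trapezoidal integral over the band, so
the mean frequency `∫ f·GWS(f) df` is a proper weighted mean and the peak is
a density mode. Minimum pooled valid support: 15 s (GWS band), 30 s (RP
band, whose floor is a 15 s period). Below that, or for a constant trace
(zero total power), the features are flagged missing rather than computed.

**Relative phase.** Cross-spectrum `W_follower · conj(W_leader)`, so a
follower lagging by τ has phase −2πfτ — negative phase means lagging, which
the "drops below −π/4" feature requires. Two reductions:

* per frequency, the circular mean over time of cell phases (unit phasors
  summed over all valid cells of all pooled trials); scanning this profile
  from low to high frequency, the first grid point below −π/4 is the
  crossing feature. A profile that never crosses is censored at the 2 Hz
  band top — censoring is genuinely informative here (fast, tight trackers
  never accumulate π/4 of lag inside the band).
* per time, the circular mean over band frequencies, concatenated across
  trials; the features are the *linear* mean/SD/median of these wrapped
  values. Linear rather than circular statistics are used deliberately: in a
  tracking task the phase concentrates near 0, far from the wrap point, and
  linear moments are then both unbiased and more familiar. This choice
  matters only if a participant's phase spreads over more than a half-circle
  (not observed under the generator's parameter ranges).

**Trial inclusion.** The entire first session is a familiarisation block and
is excluded by default (`include_first_session=False` reproduces the
protocol; the flag exists because the session-versus-first-game reading of
the exclusion rule is ambiguous in the source protocol).

## TMT features

Inter-click times are successive differences of all click times; the
on-target variant differences the on-target subsequence (an off-target click
between two correct clicks lengthens no interval — the subsequence reading).
The first of three repetitions is excluded; parts A and B are pooled into a
single interval list per participant before taking mean, unbiased SD and
median. Any missing part/repetition flags all six features missing.

## Effect sizes and tests

Cliff's delta is computed by exact pair enumeration (cohort sizes here make
O(nm) trivial); KS, Mann–Whitney (asymptotic, midrank ties) and Pearson χ²
(no continuity correction, as in the source analysis) are scipy.stats calls
behind the module surface. Effect tables orient delta so that a clinical
cohort that is slower or more variable than the reference gets positive
values; no multiple-testing correction is applied, and raw KS p-values are
reported. The `change` column between two contrasts is
`|δ_strong| − |δ_weak|`.

## Classification

All classifiers consume features z-scored with training-split statistics
(unbiased SD; zero-SD columns guarded to 1). Uniform scaling is applied to
every family, not only the distance-based one — it cannot hurt
scale-invariant learners and makes the no-leakage audit uniform.

Fixed, documented hyperparameters rather than any other toolbox's defaults:
kNN with cosine distance and k = 1 (k is configurable; published fractional
AUCs suggest the original k is larger, but it is not recoverable);
Gaussian naive Bayes; linear-kernel SVM at unit cost; bagged trees = 100
bootstrap-resampled trees with √p feature subsampling and leaf size 1;
linear discriminant with pooled covariance and empirical priors. Effect
sizes, not classifier minutiae, drive performance at these sample sizes —
the recovery tests confirm every family separates the synthetic cohorts once
the configured effects reach study scale.

Feature selection per training split: mode 3 takes the |δ|-maximiser within
each of TMT/Solo/LF (mode 2 skips Solo, mode 18 takes all); ties resolve to
the earlier feature in the canonical feature order, deterministically.

Protocols: stratified repeated hold-out (default 8 of 32 per class held out;
1000 folds in a full run, 200 in the bundled end-to-end checks — medians are
stable well below that) summarised by per-metric median and 2.5–97.5
centiles; and leave-one-out with the n per-fold predictions pooled into one
confusion matrix and AUC computed from the pooled scores (scores from
different leave-one-out fits are treated as comparable — the standard pooled
reading; a per-fold AUC is undefined for single-row test sets). Every fold
records its training indices, selected features and scaler statistics so the
no-leakage audit can recompute them from the training rows alone.

AUC is the rank-based probability that a positive outscores a negative with
ties counted ½ (verified against scikit-learn's ROC implementation).

## Severity-pattern randomization test

For a split of the clinical cohort into halves, each feature's change is
`|δ(CC, half₂)| − |δ(CC, half₁)|`. The pattern of interest — movement
features change with severity, TMT features do not — is summarised by

    T = min(median Solo change, median LF change) − median TMT change,

large only when *both* mirror-game groups change more than TMT. The p-value
is the fraction of random equal-size splits with `T ≥ T_observed` (+1/+1
small-sample correction optional). This is an exact randomization test under
exchangeability of the clinical cohort: calibration simulations show p
approximately uniform with ~5 % of null tests below 0.05. A reading that
compares each group's median change against the overall median was
considered and rejected: it is nearly powerless, because under random splits
the three group medians straddle the overall median with high probability
regardless of structure. Descriptive booleans of that overall-median pattern
are still reported alongside the statistic. The per-member delta
contributions against the fixed control cohort are precomputed, making each
split a matrix product and 10 000 splits essentially free.

## Synthetic cohort generator

The generator defines the study conditions for every end-to-end check; real
recordings are not publicly deposited. It reproduces the session structure
(three MG sessions of [Solo, 3 × LF, Solo] one-minute games, six TMT runs),
the sensor conventions (per-trial mean rate uniform in 90–140 Hz Solo /
40–70 Hz LF with ±10 % inter-sample jitter; clipping at ±0.5), and
configurable cohort differences:

* **Leader patterns** (shared by all participants, as in the study): sums of
  6 sinusoids with random frequencies in [0.1, 0.75] Hz and random phases,
  normalised to amplitude 0.45.
* **Solo motion**: a sinusoid whose instantaneous frequency and amplitude
  wander as slow Ornstein–Uhlenbeck processes around participant-specific
  values (characteristic frequency N(0.7, 0.15²) Hz for controls, mean 0.95
  for the clinical cohort; amplitude N(0.40, 0.06²), draws above 0.5
  saturate). No distributional account of real solo motion exists in the
  source; this narrowband-oscillation model is a stand-in, not a population
  claim.
* **Tracking**: follower = leader delayed by a participant-specific lag
  (controls 0.12 ± 0.04 s, clinical 0.26 ± 0.06 s) plus white noise
  low-passed at 2 Hz (human-motion bandwidth; SD 0.015 vs 0.045 units), with
  an occasional per-trial gain overshoot that drives the trace into the
  rails (15 % vs 25 % of trials) so saturation excision is exercised.
* **TMT**: on-target intervals log-normal with participant-specific median
  (log-normal between-subject spread 0.25 around 900 ms controls / 1400 ms
  clinical; within-subject log-SD 0.30); off-target clicks inserted between
  correct clicks at rate 0.04 vs 0.10.

Within the clinical cohort, mirror-game effect parameters (solo frequency
and amplitude, lag, tracking noise, overshoot) are interpolated halfway back
toward control values for the CAARMS = 0 half, while TMT parameters are
shared — producing graded movement effects with flat TMT effects, the
pattern the randomization test targets. Magnitudes were chosen so the
measured Cliff's deltas land in the published regime (TMT ≈ 0.8, Solo ≈
0.4–0.6, LF strong) — they are fixed study conditions, not tuning knobs.

Everything is a pure function of (parameters, seed) via `SeedSequence`
substreams, so identical configurations give bit-identical datasets.

**What passing tests do and do not show.** The generator exercises the
session structure, sampling variability, saturation, lag/noise structure and
effect-size geometry, so green end-to-end tests demonstrate that the
pipeline measures what it claims on data with those properties. Real
recordings differ in ways the generator does not model: non-stationary
strategy changes within a trial, asymmetric or multi-modal solo styles,
correlated TMT error bursts, sensor dropouts longer than single-sample
saturation, and any dependence structure between tasks within a participant.
Performance numbers on synthetic cohorts therefore validate the machinery,
not the clinical effect sizes themselves.

## Problem sizes in the bundled checks

End-to-end checks run at the study scale (32 participants per cohort, the
full trial inventory), with 200 hold-out folds, 10 000 bootstrap splits for
the power check and 100 × 2000 splits for the calibration check; the
analytic-delay checks use a 240 s broadband probe (150 log-spaced tones)
with 30 s edge guards. These sizes give comfortable statistical resolution
for every asserted band; a full 1000-fold hold-out run is a one-line config
change (`holdout_folds=1000`) and scales linearly.

## Known limitations

* The CWT has no cone-of-influence handling; the 5 s trim and the RP band's
  30 s support floor mitigate but do not eliminate edge bias at the lowest
  frequencies.
* Saturated samples are excluded from averaging but still filtered, so
  heavy saturation (> ~20 % of a trial) biases neighbouring samples.
* Pooled leave-one-out AUC mixes scores from different fits; its small
  pessimistic bias at chance level is visible in the null checks.
* The kNN default k = 1 yields 0/1 scores and hence coarse AUCs.
* Linear phase statistics are inappropriate if relative phase disperses
  over more than a half-circle.
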