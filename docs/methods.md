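# Methods

This note records the scientific and numerical choices behind `hfdeeg`: what
each stage computes, which parameters matter, what the synthetic generator
does and does not emulate, and where the design was genuinely open.

## Higuchi fractal dimension

For a window S(t), t = 0..N−1, and interval k, the estimator builds k
decimated curves, one per phase m = 0..k−1, and measures each curve's
normalised length

    L_m(k) = ( Σ_{i=1..n_m} |S(m + i·k) − S(m + (i−1)·k)| ) · (N−1) / (n_m · k²),
    n_m = ⌊(N−1−m)/k⌋,

then averages, L(k) = (1/k) Σ_m L_m(k). The fractal dimension D is minus the
slope of the least-squares fit of log L(k) on log k (natural log; the slope
is base-invariant). For a timeseries D ∈ [1, 2].

*Indexing.* Published statements of the estimator mix 1-based time with
phase offsets starting at 0. We use a 0-based time axis throughout and pin
the convention with an exact identity: for a linear ramp the decimated
increments are all equal, giving L(k) = (N−1)/k exactly and hence D = 1, the
lower bound of the range. The N=10 ramp values L(2) = 4.5 and L(3) = 3.0 are
hand-checked and frozen in the tests, and the vectorised implementation is
tested to 1e−12 relative agreement against a literal double-loop
transcription.

*k grid.* Default k = 2..7 (k_max = 7). The guidance "exponentially
increasing k" is ambiguous below k_max ≈ 8 — every integer grid and every
exponential grid coincide or nearly coincide — so the full integer grid is
the default and `HfdConfig.k_grid` exposes the choice. Accuracy of the
estimator on EEG-like signals is best for k_max near 6–7; larger k_max on
2-s windows mostly adds bias.

*Degenerate windows.* A constant window has L(k) = 0 for every k and no
defined log-log slope. The scalar estimator raises; the table extractor
records the cell as missing (NaN) and logs the count. Downstream stages drop
missing cells pairwise (bootstrap) or drop the trial (classification), each
with a logged count.

*Windowing.* Trials are 5 s; analysis windows are 2 s at offsets 0, 1, 2,
3 s (50% overlap). Sample counts are `round(length × rate)` and starts
`round(offset × rate)`, exact at both 250 and 256 Hz (500- and 512-sample
windows).

## Synthetic data: fBm with planted complexity differences

The generator emulates the *structure* of a two-dataset motor-imagery study
— groups × participants × trials × tasks × channels × samples — not its
physiology. Every trial/channel signal is fractional Brownian motion,
chosen because its fractal dimension is known exactly (D = 2 − H), which
turns every downstream stage into a parameter-recovery problem with ground
truth. Paths are sampled by exact Davies–Harte circulant embedding of
fractional Gaussian noise (eigenvalues by FFT of the embedded covariance;
Hermitian complex Gaussian weights; O(n log n) per batch, exact to floating
point). The embedding is non-negative definite for fGn over the whole
H ∈ (0, 1) range; a guard raises if floating-point jitter ever exceeds
tolerance rather than silently clipping structure.

Per-trial Hurst exponents follow

    H(participant, channel) = clip(H₀ + u_participant + ΔH_group(channel), 0.05, 0.95)

* `base_hurst` H₀ = 0.3 by default, i.e. baseline HFD ≈ 1.7, inside the
  1.5–2.0 band that windowed EEG complexity estimates occupy, with headroom
  for effects of −0.15 before the clip binds.
* `participant_sd` = 0.03: Gaussian participant-level random effect shared
  across that participant's channels and trials. This is what makes
  classification errors correlate within participants — the reason all
  evaluation is leave-one-*subject*-out.
* `group_effect`: a per-group map channel → ΔH. Negative ΔH raises
  complexity. The monotonicity of |group mean HFD difference| in |ΔH| is a
  tested property.

What the generator does **not** emulate: oscillatory rhythms and their
task-locked dynamics, 1/f-plus-peaks spectra, artifacts, volume conduction
(channels are independent given H), non-stationarity within a trial, and
real cohort demographics. Passing tests therefore demonstrate that the
*procedures* are correct and calibrated — not that real EEG carries effects
of any particular size. In particular the per-channel clinical accuracy
figures reported on real cohorts cannot be reproduced or refuted here.

A consequence worth stating plainly: the bootstrap below treats trials as
exchangeable within a group. With a nonzero participant random effect, the
10 participants per group yield a genuine sampling-level group difference
(≈ sd·√(2/10) in Hurst units) at *every* channel, and with 600 features per
group the test has power to detect it. That is a property of the procedure
on clustered data, not a bug in the generator; null-calibration checks
therefore either draw iid features directly or set `participant_sd = 0`,
and channel-recovery checks compare affected against unaffected channels
within the same run.

## Bootstrap group comparison

One test per channel, for a chosen pair of groups, task and window offset.
Each of M replicates resamples every group at its own feature count with
replacement (600 in the canonical design) and records the difference of
group means. With ECDF the empirical CDF of the M differences, H₀:
μ_a = μ_b is rejected at level p iff ECDF(0) ≤ p/2 or ECDF(0) ≥ 1 − p/2.
Family-wise control is Bonferroni: the corrected decision uses p/n_channels
(0.05/61 ≈ 8.2×10⁻⁴ per channel in the 61-channel montage; 0.05/48 in the
48-channel one).

* M defaults to 1,000,000 to match the published procedure; tests and the
  default pipeline use 10,000, which fixes ECDF(0) to ±0.005 — far finer
  than any decision boundary exercised here. Resampling is blocked so at
  most ~8M values are materialised at once.
* The decision rule evaluates the percentile of zero under the *unshifted*
  resampled difference distribution. A recentred alternative (compare
  |observed| against the distribution recentred to zero) is exposed behind
  `recentred=True` for sensitivity analysis but is never the default: the
  unshifted rule is the procedure as published. For a location-shift
  alternative the two give very similar answers; the unshifted rule's
  type-I calibration is verified directly (empirical rejection rate at
  p = 0.05 within [0.03, 0.07] over 500 null repetitions).
* Determinism: every channel's replicate stream is derived from the run
  seed and the channel's position via `SeedSequence` spawning. Streams are
  keyed to the lexicographically sorted group pair, so reversing the pair
  returns exactly negated differences with identical flags.

## Classification

Linear ν-SVC (scikit-learn's `NuSVC`, the standard implementation of the
ν-parameterised soft-margin classifier) on per-trial HFD feature vectors
from a channel subset at one window offset. ν ∈ (0, 1] bounds the margin
-error fraction from above and the support-vector fraction from below.
Features are z-scored with statistics from the training split only
(margin classifiers are scale-sensitive; the flag `standardize` exposes it).

* **Greedy forward channel selection**: start empty; evaluate each candidate
  channel by inner leave-one-participant-out accuracy (participants weighted
  equally); add the best; repeat with the selected set fixed; halt when no
  candidate *strictly* improves. "Without reducing" would permit indefinite
  growth along ties, so strict improvement is required and ties break in
  montage order (first listed wins). The first pick provably equals the
  exhaustive single-channel argmax, which is tested.
* **Nested leave-one-subject-out CV**: outer loop holds out each participant
  once; inside each outer fold, (offset, ν) are grid-searched with greedy
  channel re-selection at every grid point and inner leave-one-participant-
  out accuracy as criterion (grid order breaks ties). The winner is refitted
  on the whole outer-training set and applied to the held-out participant.
  The inner scheme is leave-one-participant-out because errors are
  participant-correlated; a trial-level inner CV would leak participant
  identity into model selection.
* **Default grids**: ν over the 0.025 lattice {0.05, …, 0.95}; offsets
  {0, 1, 2, 3} s. Folds where a requested ν is infeasible score 0 so they
  can never win selection. Reduced grids (a single offset, one or two ν
  values) are used in tests and calibration runs to keep a 100-permutation
  nested-CV study at desk scale; grid size changes search breadth, not the
  nesting structure being validated.
* **Reporting**: per-trial accuracy of each held-out participant, summarised
  as mean ± sd across participants; sensitivity/specificity pooled over
  trials; majority-vote participant-level accuracy ("participants correct",
  a percentage), with an exact vote tie conservatively counted incorrect;
  per-fold winning hyper-parameters plus their modal configuration.
* **Transfer**: channels and offset are frozen to source-cohort values and
  only ν is re-optimised per outer fold — the test of whether markers
  learned on one cohort (chronic pain) transfer to another (subacute).

Leakage is auditable: the evaluator can emit every (inner-train set,
inner-held-out, outer-held-out) triple, and a test asserts the outer
held-out participant never appears inside any inner split.

## Problem sizes

Unit tests run on small studies (3–10 participants per group, 4–20 trials,
2–6 channels) chosen so each property is decidable in seconds. The
calibration studies use: 500 null repetitions at M = 10,000 and n = 600 per
group for bootstrap type-I error; 20 seeded studies (10 participants per
group, 20 trials, 6 channels) for channel recovery at ΔH = −0.15; and 100
balanced label permutations of a 10-per-group, 60-trial, 2-channel null
study at a reduced grid (ν = 0.1, offset 0 s) for chance calibration.

## Known limitations

* The generator's channels are conditionally independent; no spatial
  correlation structure, so montage geometry is bookkeeping and display
  only.
* The bootstrap ignores participant clustering (see above); a hierarchical
  or cluster-resampling variant would be the principled extension.
* Greedy selection is a wrapper method: with tiny inner folds its selected
  accuracy trace is optimistically biased. Only the outer LOSO estimates
  are reported as performance.
* Multiclass (three-group) classification and non-linear kernels are out of
  scope; comparisons are pairwise and linear throughout.
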