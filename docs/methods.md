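# Methods

This note documents the models, estimators and numerical choices behind
`ssralpha`, and what the synthetic-data experiments do and do not show.

## Spectral measures

Each 3-s trial is detrended (mean and linear trend removed per
trial/channel), multiplied by a Tukey window (taper ratio 0.1, i.e. 5%
cosine ramps; the ratio is configurable and 0 gives a rectangular
window), zero-padded to `srate / 0.25 Hz` samples and Fourier
transformed.  Coefficients are scaled to sinusoid amplitude (an on-grid
unit cosine gives |Z| = 1), which keeps maps comparable across epoch
lengths; all downstream statistics are differences of dB values or
ITCz values and are invariant to this scaling.  From the per-trial
coefficients Z(trial, channel, f) of the n trials of a condition:

* ongoing power `onPOW = mean |Z|²`,
* evoked power `evoPOW = |mean Z|²` (identical, to float precision, to
  the power spectrum of the time-domain trial average),
* intertrial phase coherence `ITC = |mean Z/|Z||`.

`evoPOW ≤ onPOW` holds pointwise (Jensen's inequality); the test suite
exercises it on random spectra and the acceptance suite on 1,000 of
them.  Trials with a zero-magnitude coefficient have no defined phase at
that (channel, frequency); they are excluded cell-wise from ITC and the
exclusion count is recorded on the returned map.

ITC is reported as `ITCz = n · ITC²` (Rayleigh-z convention): under
uniform random phases `E[n·ITC²] ≈ 1` for any n, which removes most of
the trial-count bias when conditions have unequal n.  An alternative
`(n−1)·ITC² − 1` variant is available behind the `itcz_variant` switch
for comparison.  Power maps are converted to dB (`10·log10`); DC is kept
in the grid but never enters band statistics (detrending zeroes it
anyway), and dB conversion refuses non-positive input rather than
flooring it.

## Scalp current density

Before decomposition, epochs are transformed to scalp current densities
with a spherical-spline surface Laplacian: the potential map is
interpolated by the Legendre-series spline kernel with term weights
`(2n+1)/(n(n+1))ᵐ`, a ridge term λ on the Gram matrix diagonal and a
zero-sum constraint; the SCD is the (negated) Laplacian kernel,
`(2n+1)/(n(n+1))^{m−1}`, evaluated at the electrodes.  Defaults:
λ = 10⁻⁴, spline order m = 4, series truncated at 20 terms or when a
term falls below 10⁻¹⁰ (for m = 4 the series converges after ~7 terms).
The transform is precomputed as a channels × channels matrix, is exactly
linear, annihilates constants (hence reference-free), and agrees with an
independent finite-difference Laplace–Beltrami oracle on a dense montage
(correlation > 0.99 in the tests).  It can be bypassed
(`scd_enabled: false`); all effect signs are unchanged on synthetic
data.  Units are input-units per square radian on the unit sphere — no
head-radius rescaling is applied because every downstream statistic is
scale-invariant.

## Cluster-based permutation tests

Paired condition contrasts of per-subject channel maps are tested with
the cluster-mass permutation scheme: per-channel paired t values are
thresholded at the two-tailed α = 0.05 critical value (configurable),
suprathreshold channels of equal sign are grouped into connected
components of the montage adjacency (Delaunay triangulation of the
sensor layout; minimum cluster size 1), and each cluster's summed t is
referred to the permutation distribution of the most extreme cluster
mass under per-subject sign flips — the exact permutation scheme for a
paired design.  Positive clusters are compared against the
per-permutation maximum positive mass and negative clusters against the
minimum, and the one-tailed Monte-Carlo p is doubled (capped at 1) for
two-sided correction; the observed labeling is included in the null, so
p ≥ 1/(n_perm + 1).  This convention keeps the family-wise error at the
nominal 5% (verified over 500 null simulations) — pooling both signs
into a single |mass| null *and* doubling would halve the nominal rate.
Cluster membership is a deterministic function of the data; only p is
Monte-Carlo, reproducible via the seed.  Zero-variance channels receive
a large finite t (±10⁶) instead of ±∞ and are logged.

With very small cohorts the permutation floor (e.g. 2·2⁻⁵ for five
subjects) makes p < 0.05 unattainable; the pipeline therefore separates
the *sensor sets* used for quantification (strongest hemispheric
cluster, whatever its p) from *detection* (p < 0.05), and sign-recovery
bookkeeping counts only detections.

## Bayesian inference

**JZS t test.** BF₁₀ is the ratio of the marginal likelihood of the
observed t under a Cauchy(0, r) prior on the standardized effect size
(default r = 0.5, emphasizing smaller effects) to its likelihood under
δ = 0.  The integral is evaluated by adaptive quadrature after
substituting the prior CDF as integration variable, which is stable for
any prior scale (including the r → 0 limit, where BF → 1); agreement
with brute-force fine-grid quadrature is at machine precision, and with
an independent implementation (pingouin) to ~10⁻¹².  One-sided variants
truncate and renormalize the prior.  Posterior summaries (median and 95%
credible interval, truncated for one-sided tests) come from a dense grid
over the effect size.  Evidence labels follow the convention BF > 3
(support), 1–3 (anecdotal).

**Kendall rank correlation.** τ_b uses the standard tie-corrected
estimator.  The Bayes factor places a stretched-beta(1/w, 1/w) prior on
τ over (−1, 1) — "β prior width" w = 0.75 by default, read as the width
parameter of that prior, the only plausible interpretation of the
convention — and uses the asymptotic normality of the standardized
statistic T* = τ̂·√(9n(n−1)/(2(2n+5))), distributed ≈ N(1.5·τ·√n, 1), to
form the posterior; BF₁₀ is the Savage–Dickey density ratio at τ = 0.
One-sided tests truncate prior and posterior at 0.  Credible intervals
are reported from the (possibly truncated) posterior; more than 50%
tied pairs triggers a warning because the normal approximation degrades.

## Subject-level single-trial regression

ITC has no single-trial definition, so single-trial estimates are
obtained by the jackknife: estimate i is the measure recomputed on all
trials but i (leave-one-out values are used directly, not pseudovalues).
Closed forms make this O(n): running complex sums for evoPOW/ITC and
running power sums for band alpha.  Per subject, the attention effect is
expressed as **all pairwise differences** between trials of the two cue
conditions, with identical (i, j) pair ordering for the alpha and SSR
measures so the two difference vectors align pair-for-pair.  The alpha
variable is the hemispheric lateralization (left-cluster minus
right-cluster band alpha, cluster sets taken from the group alpha
analysis, falling back to hemisphere halves when absent).  Both
z-scored vectors enter a per-sensor robust regression.

Because *both* variables are jackknifed, the two leave-one-out sign
inversions cancel and the slope keeps its natural sign; a
`jackknife_sign_invert` switch covers the mixed jackknifed/raw case
where a single inversion would be required.  The pairwise pools are
massively dependent (n_a·n_b pairs from n_a+n_b trials), so inference
happens only at the subject level: per-subject slopes are tested against
zero by the cluster permutation test and by per-sensor JZS Bayes
factors.

Robust regression is iteratively reweighted least squares with the Tukey
bisquare weight (tuning constant 4.685), scale = median absolute
residual / 0.6745, intercept included, iterated to relative coefficient
change < 10⁻⁸ or 50 iterations (non-convergence returns the last iterate
with a cleared flag, logged).  It is vectorized over response columns
(all sensors of a subject at once, sharing the design vector), and
cross-checked against statsmodels' RLM in the tests.  On data with 10%
gross outliers it beats OLS slope recovery in ≥ 95% of seeded runs.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
with ground-truth effect signs for recovery tests.  Defaults define the
study conditions (amplitudes in arbitrary "µV-equivalent" units):

| parameter | default | meaning |
|---|---|---|
| trials/condition | 34 | retained trials per cue condition |
| channels | 32 | quasi-uniform upper-hemisphere cap, Delaunay adjacency |
| srate, epoch | 256 Hz, 3 s | analysis segment |
| alpha band, amp | 8–13 Hz, 1.0 | band-passed Gaussian noise (order-4 zero-phase Butterworth), per-trial random phase, unit-SD normalized |
| alpha suppression / enhancement | 0.20 / 0.10 | contralateral / ipsilateral amplitude change with attention |
| SSR freqs, amp | 10 & 12 Hz, 0.09 | sinusoids; left stimulus 10 Hz → right-hemisphere topography and vice versa |
| SSR attended gain | 0.30 | amplitude factor 1.3 when the driving stimulus is attended |
| SSR phase jitter (sd) | 0.4 rad | trial-to-trial phase scatter; ×0.45 when attended |
| 1/f noise | β = 1, amp 0.25 | independent across channels and trials |
| trial amplitude sd | 0.2 | per-trial multiplicative amplitude fluctuation |

Scalp profiles are Gaussians on the sphere (angular sd 0.35 rad for
alpha, 0.6 rad for the broader SSR foci) centred on parieto-occipital
(alpha) and occipital (SSR) seed directions; left/right alpha profiles
overlap < 20% across the midline.  Cohorts share one fixed cap (the
montage is equipment, not subject randomness); per-subject heterogeneity
is multiplicative jitter on amplitudes (±15%) and on effect fractions
(±12%), with an optional correlation between a subject's alpha and SSR
effect sizes (`effect_coupling`) and an optional trial-level coupling of
SSR amplitude to the alpha left–right asymmetry (`trial_coupling`) for
coupling-recovery experiments; both default to 0 (independent effects).

Free parameters the literature does not pin down (noise amplitude,
jitter level, topography geometry, per-trial variability) were
calibrated once so that the stated condition regime — ongoing alpha
~11–12 dB above evoked SSR power, 20%/10% alpha modulation, 30% SSR
gain, 17 subjects — yields reliable qualitative sign recovery, and then
frozen.  Attention modulates the SSR through both amplitude gain and
phase-jitter reduction by default: at a realistic 12 dB evoked/ongoing
gap, an amplitude-only modulation changes ITC only indirectly (through
signal-to-noise at the driving bin) and is too weak to form reliable
sensor clusters on a 32-channel cap, whereas attention effects on phase
stability are exactly what the ITC analysis is designed to capture.
Both pathways are independently configurable.

What the generator does **not** emulate: volume-conducted forward-model
mixing from realistic sources, artifacts (blinks, saccades, muscle),
non-stationarity within trials, target/distractor transients, and the
quasirhythmic stimulation regime.  Passing tests therefore show that the
*analysis chain* behaves correctly under its own assumptions — not that
those assumptions exhaust real EEG.

A known and deliberate realism: because 10 and 12 Hz lie inside the
alpha band, evoked power at the driving bins contains a residual of the
(incompletely cancelled) alpha, so alpha modulation leaks into evoPOW
contrasts with the opposite sign at alpha-dominant sensors — small
negative side-clusters can accompany the genuine positive SSR gain
clusters, and the single-trial evoPOW regression is more susceptible to
alpha leakage than the ITC regression (whose amplitude normalization
suppresses it).  The spurious-coupling (type-I) experiment therefore
uses the ITC measure.

## Problem sizes and numerical choices

Simulation-based checks use scaled sizes chosen for tight Monte-Carlo
error at moderate cost: 20 master seeds × 17 subjects for conundrum
recovery (2,000 permutations per cluster test; the p floor of 10⁻³ is
far below the 0.05 decisions being made), 10,000 replicates for ITC
calibration, complete 2⁸ enumeration vs 5,000 permutations for cluster
exactness, 500 null runs for the family-wise rate, 200 runs for robust
regression, and 100 independent-injection cohorts (8 subjects, 16
channels, 12 trials/condition) for the null-coupling rate.  Quadrature
tolerances are 10⁻¹⁰ relative; posterior grids use 4,001 (effect size)
and 20,001 (τ) points.  Ties in cluster formation cannot occur with
continuous data; equal-|t_sum| clusters are ordered by descending
magnitude.

## Known limitations

* The spherical cap and spline Laplacian ignore real head geometry;
  missing-channel interpolation is out of scope.
* The Kendall posterior relies on the asymptotic normal approximation of
  T*; for n < ~10 or heavy ties the Bayes factor is approximate (the
  prior-predictive simulation check bounds the error at ~5% for n = 17).
* The pipeline analyses clean epochs; artifact rejection and continuous
  preprocessing are out of scope.
* With 32 channels, SCD sharpening shrinks cluster extents; detection
  margins on real 128-channel data would differ.
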