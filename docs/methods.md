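# Methods

## Problem and model

The package detects driver drowsiness from steering-wheel behaviour
alone. The physiological story is simple: an alert driver holds the lane
with frequent, small corrective inputs, while a drowsy driver lets the
vehicle drift and compensates late with sparse, large corrections. On
the detrended steering-angle signal this shows up as a lower
zero-crossing rate, larger amplitude and changed spectral shape. The
pipeline turns that signature into a binary awake/drowsy decision per
3-second window, with ground truth taken from the Karolinska Sleepiness
Scale (KSS, 1–9) binarized as 1–6 = awake, 8–9 = drowsy; level 7 is
ambiguous by design of the scale and those windows are excluded
everywhere.

The contribution-bearing component is the feature selector: four filter
statistics per feature (Fisher, |Pearson correlation|, Welch T, binned
mutual information), min-max rescaled across the feature set and fused
by a zero-order Takagi–Sugeno fuzzy system — three Gaussian membership
functions per input, the complete 81-rule base, singleton consequents in
{0, 0.5, 1}, product t-norm, firing-strength-weighted average output.
The system's 24 + 81 parameters are trained as a wrapper: global-best
PSO minimizes half the squared prediction error of an RBF SVM fitted on
the currently selected columns and scored on a held-out validation
split. For binary labels that objective is half the misclassification
rate, so 0 is perfect and 0.5 is chance.

## Synthetic data: what it emulates, what it does not

No public dataset pairs steering recordings with KSS annotation, so the
generator is a first-class component. A drive is

    angle(t) = track(t) + correction(t) + noise(t)

with `track` a sinusoid (default 15° amplitude, 60 s period) standing in
for road curvature, `noise` white Gaussian measurement noise (0.1° SD),
and `correction` the regime-dependent driver process: while awake, a
piecewise-constant level re-drawn uniformly in ±0.8° at Poisson events
(4/s); while drowsy (KSS ≥ 8), a linear drift (1°/s) terminated at
sparse Poisson events (0.25/s) by a large opposing step (6° ± 25%
jitter) that overshoots zero and re-arms the drift — a sawtooth. KSS
follows a monotone step profile (default: 2→9 across the drive, with a
short KSS-7 transition band); samples at KSS 7 use the awake correction
process, since the generator must produce *something* there and those
windows are dropped downstream anyway. Velocity is the forward
difference of angle times the sampling rate, with the last sample held.
The regime asymmetry (drowsy corrections sparser and larger than awake)
is enforced at config validation because it *is* the planted effect.

What this does not emulate: vehicle dynamics, driver-to-driver
variability, circadian drift within a regime, non-stationary road
geometry, or any coupling between drowsiness and track position. A
passing recovery experiment therefore shows that the selector finds
structure of the kind the field reports — not that it would reach any
particular accuracy on real drives.

The abstract feature bench skips signal processing entirely: Gaussian
columns, a chosen few shifted by `effect_size` standard deviations
between classes, all min-max scaled. It exists to test the selector
stack in isolation under a known ground truth.

## Feature definitions

The 18 per-channel descriptors are one-line classics whose exact
conventions had to be fixed somewhere; this package fixes them as
follows. Sample SD and the class variances everywhere use the n−1
denominator. ZCR counts strict sign products (x·x′ < 0) per second of
window duration. Quartiles use linear interpolation. Katz fractal
dimension is log₁₀(n−1)/(log₁₀(n−1)+log₁₀(d/L)) over the unit-index
abscissa, which is exactly 1 for a straight line. Skewness is
m₃/m₂^1.5 and kurtosis the non-excess m₄/m₂²; both defined as 0 for a
flat window. Sample entropy uses m = 2, r = 0.2·SD, Chebyshev distance,
self-matches excluded; when no pair matches at either length — including
the zero-variance case r = 0 — it returns the maximum resolvable value
−ln(2/((n−m−1)(n−m))) so the statistic stays finite and the regularity
ordering survives. Shannon entropy bins the window into 16 equal-width
bins (0·log 0 := 0). The six spectral features come from the one-sided
Hann-tapered periodogram of the detrended window; spectral flux is the
squared difference of L1-normalized magnitude spectra between a window
and its predecessor in the same recording (0 for the first window, and
computed before dropped windows are removed so adjacency is real);
the dominant frequency excludes the DC bin because mean removal makes DC
numerically tiny but not exactly zero. An all-zero window defines the
power-weighted spectral features (variance, entropy, centroid) as 0.

Min-max normalization bounds come from training windows only; test
values are clipped to [0, 1]; a constant training feature maps to 0.5 so
the fuzzifier input stays defined (its filter indexes are ~0 anyway).

## Filter indexes

The Fisher score is implemented with the summed-variance denominator
(μ₁−μ₀)²/(σ₁²+σ₀²) — the standard form; a difference of variances is
sign-unstable and divides by zero for equal class variances. Mutual
information uses a 10-bin equal-width plug-in estimator, log base 2,
empty cells contributing nothing; the bin count is config-exposed.
Degenerate perfect separators (zero within-class variance, distinct
means) return a 10⁶ sentinel, which the per-index min-max rescaling to
[0, 1] maps to exactly 1. Correlation enters the rescaling by absolute
value; a constant index vector maps to all-0.5.

## Fuzzy system and its initialization

Membership functions start at centres (0, 0.5, 1) with common width
0.2125, which makes neighbouring Gaussians cross near 0.5 membership on
the unit domain. Consequents start from an antecedent-majority
heuristic (three or more High antecedents → α = 1, three or more Low →
α = 0, else 0.5); the heuristic only seeds the search — consequents are
part of the PSO position. Rule order is lexicographic over the
(F, R, T, I) antecedents with L < M < H, and that ordering is part of
the YAML parameter-file contract. Selection uses the strict inequality
ID > 0.5. Product t-norm and weighted-average output are the canonical
zero-order Takagi–Sugeno evaluation; with Gaussian antecedents the
normalizing sum is always positive.

## PSO training

The position concatenates centres (boxed to [0,1]), widths (boxed to
[0.05, 1] — a zero width is not a membership function), and consequents
relaxed to [0,1]. Decoding sorts each input's centre triple so the
L ≤ M ≤ H invariant survives arbitrary moves, and snaps each relaxed
consequent to the nearest of {0, 0.5, 1} with ties toward the larger
level (cutpoints 0.25 and 0.75). Velocities start at zero; positions
start uniform in the box except particle 0, which is warm-started at the
default parameters — this guarantees the optimized objective never
exceeds the untrained objective. R₁ and R₂ are componentwise uniform
(diagonal random matrices). Stopping: 100 iterations or 20 consecutive
iterations with gbest improvement below 10⁻⁶.

One numerical choice deserves emphasis. With inertia 0.95 and
C₁ = C₂ = 2 the swarm's second-moment dynamics are divergent: under a
constant velocity clamp the particles orbit the optimum at the clamp
scale indefinitely and the achievable cost floors at O(v_max²). The
clamp therefore starts at 0.2× the box width and decays geometrically by
0.93 per iteration, annealing the orbit so late iterations refine
instead of oscillate; on the 10-D sphere benchmark this reaches ~10⁻⁶
in 100 iterations where the constant clamp stalls around 10⁻³–10⁻¹.
Setting `v_clamp_decay = 1.0` recovers the constant-clamp behaviour.

Because the wrapper cost depends on the position only through the
selected-feature mask, costs are memoized per mask; the SVM fits once
per distinct subset, which makes the full 50 × 100 swarm affordable on
one CPU.

## Evaluation protocol

`run_pipeline` holds out a stratified 30% test fraction before anything
is fitted; the trainer splits the remaining 70% again internally for its
wrapper objective, so reported test numbers come from windows no stage
ever saw. The planted-recovery experiment instead scores all methods
(fuzzy selector and the single-index top-k baselines) on one shared
validation fold — the wrapper's own evaluation set — which mirrors how
wrapper selectors are compared against filter rankings on a common
bench; with easy planted effects all methods saturate near ceiling on a
truly untouched holdout and the comparison would measure noise.
Experiment scale: 36 features, 5 informative, effect size 2, n = 2000,
20 seeds, medians reported.

The published reference confusion table for this task
(TP = 9515, TN = 24212, FP = 814, FN = 538) yields 96.146% under the
accuracy formula, although the source reports 98.12% elsewhere; the
package reproduces the arithmetic and leaves the discrepancy as the
source's own.

## Known limitations

* Feature values cannot be compared numerically against any published
  study: the one-line descriptor definitions admit many conventions and
  this package documents and tests its own.
* The binned MI estimator is biased upward at small n; the null tests
  bound it below 0.02 bits at n = 5000 but it is not debiased.
* The PSO objective is piecewise constant in the parameters (it factors
  through the selection mask), so the swarm explores plateaus rather
  than following gradients; different seeds can return different masks
  of equal validation cost.
* The synthetic generator's realism limits are listed above; absolute
  accuracies on it say nothing quantitative about real driving data.
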