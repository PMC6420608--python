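# Methods

This note documents the models, defaults and numerical choices behind
`lapsewatch`, and what the simulation-based tests do and do not establish.

## Postural-instability statistic

A trial's center-of-pressure samples (x_k, y_k), k = 1..K, are reduced to

    CoP_MAD = median_k sqrt( (x_k − median x)² + (y_k − median y)² ),

the median radial deviation from the coordinate-wise median point. It is
zero iff every sample coincides with that point, invariant to sample order
and to rigid translation, and robust to isolated spikes. Medians of
even-length sets use the midpoint of the two central order statistics
(the convention shared by the brute-force oracle in the tests). CoP
coordinates are treated as abstract device length units and a units label
travels as metadata: a consumer balance board's raw output is uncalibrated
when sat upon, so attaching physical units would be spurious precision.

Across trials the per-trial values are smoothed with a trailing simple
moving average: element i is the mean of the current value and up to
`window_n` predecessors (default 2). The window truncates at the start of
the series rather than emitting missing values, so every trial keeps one
smoothed value. `smooth_sma` is deliberately series-agnostic; the session
pipeline applies it to the catch-trial subseries by default (one smoothed
value per catch trial, the layout used in lapse classification), with
`scope="all"` available, and the prospective α computation inside the
simulator uses a causal running average over *all* trials, since a live
run's posture stream does not distinguish trial kinds.

## Lapses and the lapse rate

A lapse is an incorrect response on a suprathreshold catch trial (+30 task
units by default, far above any plausible threshold). Because the task is
2AFC, a lapsing observer still answers correctly half the time, so the
session lapse rate is 2L, with L the proportion of lapsed catch trials: 0
for an ideal observer, 1 for a maximally inattentive one. Values of
L > 0.5 (possible in finite samples of a guessing observer) would map
above 1, so the rate is clamped at 1 and the raw proportion L is exposed
separately.

## Classifier evaluation

CoP_MAD is scored as a trial-level lapse classifier by sweeping a
criterion over the catch-trial scores ("score ≥ criterion ⇒ lapse" —
higher instability is hypothesized to be more lapse-like, and the
direction is recorded in every report so the inverse pattern some
observers show remains representable). The ROC sweep and trapezoidal AUC
are delegated to scikit-learn with all operating points retained; ties
contribute ½, so the AUC equals the Mann–Whitney pairwise-concordance
probability, which an independent enumeration oracle verifies exactly in
the tests.

Confidence intervals use the bias-corrected and accelerated (BCa)
percentile bootstrap (default 20,000 resamples): the bias term z₀ is the
normal quantile of the fraction of replicates below the point estimate
(ties counted ½, proportions clipped to (1/(B+1), B/(B+1)) to keep z₀
finite), and the acceleration is the jackknife skewness. The
implementation is in-package because the AUC bootstrap resamples
(score, label) rows jointly and can produce single-class replicates —
these return NaN and are dropped with a warning — and because an all-equal
replicate distribution collapses to a point interval with a warning
rather than an error. `scipy.stats.bootstrap(method="BCa")` serves as an
independent cross-check in the test suite. Simulated coverage for the
mean of an exponential sample at n = 30 sits near 0.93–0.95, the familiar
mild undercoverage of BCa under strong skew.

## Psychometric model and weighted grid posterior

The 2AFC response model is

    P(correct | x) = γ + (1 − γ − λ) · F((x − T)/s)

with guess rate γ (0.5 for 2AFC), lapse parameter λ (upper-asymptote
shortfall), threshold T and spread s. F is logistic by default — F(0) =
0.5 places T at the 75% point when γ = 0.5, λ = 0 — with a Quick/Weibull
alternative (F(T) = 0.5 likewise) selectable where magnitudes are
intrinsically positive.

The posterior lives on a threshold × slope lattice (default: 61 linear
threshold nodes over [0.5, 30], 7 geometric slope nodes over [0.5, 10], γ
fixed, λ an optional nuisance axis that defaults to off). Each trial
multiplies the mass at every node by the trial likelihood raised to a
weight α ∈ [0, 1]:

    log m ← log m + α · log P(r | x, ψ),  then renormalize.

α = 1 recovers the ordinary Bayes update (verified against a direct
probability-domain oracle to 1e−12), α = 0 leaves the posterior untouched,
and updates commute, so the final posterior is order-invariant for a fixed
set of (x, r, α) triples. All mass arithmetic is in log space; 225-trial
sessions stay comfortably away from underflow.

The reported threshold is the posterior mean of T with the slope (and λ)
axes marginalized. Stimulus placement evaluates, for each candidate
magnitude in a fixed domain (default 25 geometric steps over [0.25, 30]),
the expected posterior entropy after a tentative weighted update with a
forecast weight `alpha_forecast` (default 1: the lapse probability of a
future trial is unknown before its posture is observed), using the
posterior-predictive response probabilities; the candidate minimizing
expected entropy wins, ties breaking toward the smaller magnitude.
Stopping combines an optional trial cap with an optional entropy
criterion; the default reproduces a fixed-length (max-trials-only) design.
With the default grid the slope axis retains residual entropy (~3 bits
plateau), so entropy criteria should be read as thresholds on *joint*
parameter uncertainty, not threshold uncertainty alone.

## Score → weight mapping

α is defined as 1 − P(lapse | score): 0 for a definite lapse, 1 for
definite concentration. The lapse probability is logistic in the smoothed
CoP_MAD score, p(s) = expit(steepness · (s − midpoint)), fitted by maximum
likelihood (statsmodels Logit) on labeled catch trials — the only trials
with ground truth — and then applied to all trials. Perfect separation or
a fitted slope beyond a configurable cap (default 100) triggers a guard:
steepness is capped and the midpoint placed between the classes; raw
coefficients and standard errors are always exposed in
`mapping.diagnostics`. The returned mapping clips steepness to be
nonnegative so that α is monotone nonincreasing in instability. A default
α floor of 0.05 bounds the influence of a miscalibrated mapping — a fully
discarded trial can never be recovered — and can be set to 0.

## Synthetic sessions

The generator reproduces the statistical structure the analysis assumes,
at the nominal study conditions: 225 adaptive test trials, catch trials of
magnitude +30 scheduled with uniform gaps on {6..9} (counted over the
merged trial stream by default; a test-trials-only gap convention is
configurable — the two readings of "every six to nine trials" differ, and
the catch count is left emergent rather than forced), a per-trial
two-state Markov attention process, and per-trial AR(1) CoP traces at
50 Hz, 3.5 s, coefficient 0.95, with innovation SD `sd_lapsed` ≥
`sd_attentive` inflated during lapses. Lapsed-state responses are
Bernoulli(γ), independent of the stimulus. One master seed spawns
independent scheduling/attention/response/CoP streams, so a session is
bit-reproducible while components can be varied in isolation.

Defaults: observer threshold 11.5, slope 3.0 (task units), γ = 0.5,
λ = 0; attention p_enter = 0.006, p_exit = 0.3, giving ~2% stationary
lapse occupancy in episodes of ~3 trials — an expected lapse rate near
the ~1.9% typical of cooperative observers; sd_lapsed/sd_attentive = 2.
No published effect size pins the dispersion ratio, so it is treated as a
free parameter and swept ({1, 1.5, 2}) in the classifier-sanity tests.

What the generator does **not** emulate: biomechanically realistic sway
(no spectral structure beyond AR(1), no drift or posture shifts),
stimulus rendering, learning/fatigue trends, blocks and breaks, reward
feedback, or graded attention between the two states. Passing tests
therefore show that the pipeline recovers the structure it models — e.g.
that oracle- or calibration-weighted updates beat unweighted ones *when*
sway dispersion genuinely separates lapse trials — not that human CoP
data will separate as cleanly; empirically the separation in children is
modest (AUC well below the ratios-≥1.5 regime simulated here).

## Problem sizes and numerical choices

Simulation-based tests use: 200 runs × 225 trials for threshold
convergence and for the paired weighted-vs-unweighted comparisons (20%
lapse occupancy, oracle or calibrated α); 60 sessions per dispersion
ratio for the ROC monotonicity check; 1000 replications × 2000 resamples
for BCa coverage; 10⁴–10⁵ draws for the chance-responding and lapse-rate
endpoint checks. Exact oracle equivalences (CoP_MAD medians, pairwise
AUC, α = 1 Bayes) run over exhaustive small sizes (traces ≤ 7 samples,
label sets ≤ 8). Posterior normalization is asserted to 1e−12 after every
update; degenerate updates (zero likelihood everywhere) raise rather than
silently renormalize.

## Known limitations

- The α weights enter the likelihood as exponents, which is a principled
  down-weighting but not a full mixture model of lapsing; a λ nuisance
  axis can be enabled on the grid where residual contamination matters.
- Calibration uses catch trials only (~30 per session under the default
  schedule), so fitted mappings are noisy at single-session scale; the
  end-to-end benefit of calibrated weighting is asserted as a weak
  inequality for this reason.
- Entropy-based stopping interacts with the slope axis's residual
  entropy (see above); trial caps remain the primary stopping control.
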