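# lapsewatch

Detecting lapses in concentration from postural instability during
psychophysical testing, and putting those detections to work inside a
Bayesian adaptive threshold procedure.

## The problem

Psychophysical procedures (QUEST, Psi, staircases, ...) estimate a
perceptual threshold under the assumption that every response reflects the
stimulus. In practice observers — children especially — sometimes lapse:
their mind wanders and the response becomes a pure guess (50% correct in a
two-alternative forced choice, 2AFC), which adds noise and systematically
biases thresholds toward *worse* apparent sensitivity. The gold-standard
lapse measure, errors on interleaved suprathreshold catch trials, is molar:
it tells you an observer lapsed somewhere, not on which trial.

`lapsewatch` implements a trial-by-trial (molecular) alternative: the
observer sits on a force platform, and the within-trial dispersion of the
body's center of pressure (CoP) is used as a real-time index of
concentration — someone engaged with the task tends to sit more still.

## What the package provides

- **`copkit`** — CoP stream I/O and the postural-instability statistic

  CoP_MAD = median( sqrt[(CoP_x − median CoP_x)² + (CoP_y − median CoP_y)²] ),

  the median radial deviation of a trial's CoP samples from their
  coordinate-wise median, plus the simple-moving-average smoothing across
  trials (window N = 2 by default).
- **`session`** — trial/session containers; lapse tagging (a lapse = an
  incorrect response on a suprathreshold catch trial); the lapse rate
  2L (L = proportion of lapsed catch trials; ×2 corrects for 2AFC
  guessing, clamped at 1); mean CoP_MAD; odd/even split-half series.
- **`evalstats`** — ROC/AUC evaluation of CoP_MAD as a lapse classifier
  and bias-corrected-and-accelerated (BCa) bootstrap confidence intervals
  (default N = 20,000 resamples).
- **`adaptive`** — a QUEST-style grid posterior over the parameters of the
  2AFC psychometric function ψ, P(correct | x) = γ + (1 − γ − λ)·F((x − T)/s),
  with a **lapse-weighted likelihood**: each response's contribution is
  P(rᵢ | xᵢ, ψ)^αᵢ with αᵢ ∈ [0, 1]. α = 0 discards the trial (definite
  lapse), α = 1 is the ordinary Bayes update. Threshold = posterior mean of
  T; stimulus placement minimizes expected posterior entropy; stopping can
  combine a trial cap with an entropy criterion.
- **`engagement`** — maps (smoothed) CoP_MAD scores to α = 1 − P(lapse |
  score) through a logistic model calibrated by maximum likelihood on
  labeled catch trials.
- **`simulate`** — synthetic 2AFC sessions: 225 adaptive test trials with
  catch trials (+30 task units) every 6–9 trials, a two-state Markov
  attention process, chance responding while lapsed, and AR(1) CoP traces
  (~50 Hz) whose innovation SD is inflated in the lapsed state.

## Worked example

Simulate a deliberately fidgety session (25% chance of entering a lapse
episode per trial, sway dispersion tripled while lapsed), then evaluate
CoP_MAD as a lapse detector and calibrate a weighting function:

```bash
cat > demo.yaml <<'YAML'
n_test: 120
seed: 5
attention: {p_enter: 0.25, p_exit: 0.4}
cop: {sd_attentive: 1.0, sd_lapsed: 3.0}
YAML
lapsewatch simulate --config demo.yaml --out-dir demo_run
lapsewatch analyze --trials demo_run/trials.csv --score-field cop_mad \
    --n-resamples 2000 --seed 0 --out report.json
lapsewatch calibrate --in demo_run/trials.csv --score-field cop_mad \
    --out mapping.json
```

`demo_run/session.json` reports the molar summary:

```json
{
  "n_test": 120,
  "n_catch": 18,
  "lapse_rate": 0.3333333333333333,
  "raw_lapse_proportion": 0.16666666666666666,
  "mean_cop_mad": 5.522969573919425,
  "seed": 5
}
```

Three of 18 catch trials were answered incorrectly (L = 1/6), giving a
2AFC-corrected lapse rate of 2L = 0.33. The ROC report shows CoP_MAD
separates those lapse trials well in this high-contrast regime —
`auc = 0.933` with a BCa 95% interval `[0.69, 1.0]` over 3 lapse and 15
non-lapse catch trials — and `mapping.json` holds the fitted logistic
score→α mapping (midpoint ≈ 10.0, steepness ≈ 1.23) that
`lapsewatch simulate --alpha-source engagement --mapping mapping.json`
can feed back into the adaptive procedure.

The same machinery is available as a library; see the docstrings in
`lapsewatch.adaptive` for the weighted-update API and
`docs/methods.md` for the underlying model and its assumptions.

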