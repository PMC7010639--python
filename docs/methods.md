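# Methods

`evreg` implements, end to end and with known ground truth, the statistical
pipeline for detecting within-trial decision-evidence correlates in
event-stream neural recordings: a perceptual decision task whose stimulus
delivers a fresh piece of evidence every 100 ms, an ideal-observer
definition of momentary and accumulated evidence, event-aligned regression
designs with a strict normalization contract, second-level inference with
joint FDR correction over a time × location grid, and a spatial
pattern-difference statistic for response-aligned windows.

## Task and stimulus model

Each trial shows a single white dot jumping to a new position every 100 ms
(up to 25 positions, 2.5 s timeout).  Positions are drawn from a 2D
Gaussian centered on one of two lateral targets at (±25, 0) px with SD
70 px on both axes.  Because the targets differ only horizontally, the
signed x-coordinate is the momentary decision evidence and the
y-coordinate is a decision-irrelevant perceptual control.

The session stimulus set is constructed, not sampled freely: `n_long = 28`
base sequences are each expanded into six variants that differ only in the
x-coordinate of dot 5 (−160, −96, −32, 32, 96, 160 px), `n_catch = 72`
easy catch sequences are added, and the whole set of 240 is duplicated by
negating every x-coordinate.  Mirroring guarantees exact left/right balance;
the fifth-dot manipulation guarantees large, regular evidence variation
mid-trial.  The resulting 480 trials are ordered by a seeded constrained
shuffle that forbids runs of more than four variant trials, keeping catch
trials interleaved.  The original study drew its base sequences from a
prior experiment's response-time distribution; those stimuli are not
available, so the generator samples fresh sequences and tags their roles —
the design structure (counts, variants, mirroring, interleaving) is
preserved exactly, the specific coordinates are not.

## Observer model

For this task geometry the ideal observer's log posterior odds of right
vs. left after k dots reduces to

    logodds_k = (2 · mean_px / sd_px²) · Σ_{i≤k} x_i + prior_bias,

an affine function of the plain cumulative sum (all y-terms and quadratic
terms cancel between the symmetric targets).  The package therefore uses
the running sum as the accumulated-evidence regressor and exposes
`prior_bias` (default 0, magnitude unspecified in the underlying model)
only for completeness; the affine relation keeps the correlation between
log odds and running sum above 0.99 even with participant-specific biases.

Behavior comes from a discrete-time bounded accumulator: per 100 ms frame
the state gains `x_k + Normal(0, acc_noise_sd)`; the response is the sign
of the state at first bound crossing, at time `frame·100 + ndt_ms`; trials
that never cross within 25 frames (or whose response would land after
2.5 s) time out with choice 0 and are excluded from response-aligned
analyses.  Human accumulator parameters are unknown, so the defaults
(`acc_noise_sd = 115` px/step, `bound = 420` px, `ndt_ms = 300`) were
calibrated once by forward simulation on the default stimulus set to land
in the task's intended behavioral regime — accuracy ≈ 0.78, median RT
≈ 1.1 s, timeout rate ≈ 0.13 — and are not otherwise meaningful.

## Synthetic signals

`simulate_session` produces trials × channels × samples tensors at 100 Hz
spanning −300…2500 ms around first-dot onset, containing:

* white Gaussian noise (`noise_sd`, default 1);
* a condition-independent evoked template (damped 3 Hz oscillation) added
  identically to all trials — deliberately, so that tests can verify the
  per-slice z-scoring removes average responses exactly;
* any number of embedded linear correlates (`EffectSpec`): a z-scored
  regressor value (momentary x, y, running sums, absolute values, update
  magnitudes, or the trial's choice) times a per-channel topography and an
  amplitude, active in a lag-shifted window.  Dot-aligned effects follow
  the dot's display window by default or an explicit boxcar
  (`duration_ms`); a 10 ms boxcar gives an impulse-like correlate at a
  single latency, which is what the recovery validations use.  Choice
  effects are boxcars relative to the response and skip timeout trials.

The amplitude for a desired theoretical correlation r is
`noise_sd · r / sqrt(1 − r²)`.  Cohorts draw per-participant amplitudes
from Normal(template, `between_sd`) with child seeds spawned from the
cohort seed.

Not emulated: realistic MEG noise spectra (1/f, sensor correlations),
gradiometer/magnetometer distinction, artifacts, head movement, or forward
/inverse source mixing — "source-level" inputs are tensors whose channel
axis is labeled with parcellation areas (180 + 1 unassigned per
hemisphere, 362 labels total; generic names, since anatomical
identification is a data result, not an algorithm).  Passing tests on
these signals therefore validates the statistical machinery, not its
robustness to structured MEG noise.

## Regression designs and normalization

Three designs, all fit by plain OLS:

* **standard** — one row per trial; regressors x₁…x₆, y₁…y₆ of the first
  six dots plus response, trial counter and intercept nuisances.
* **expanded** — one row per (trial, dot) at a fixed latency t from each
  dot's onset.  A dot contributes if its onset precedes the response and
  the sample time lies strictly before `rt − 200 ms` (motor exclusion).
  For RT 880 ms at t = 120 ms this yields 9 dots shown, 8 candidate
  samples, 6 retained rows.  Regressors: momentary evidence x (or, in the
  accumulated variant, the running sum Σ_{i≤k} x_i), y, |x|, |y|, the
  perceptual update magnitudes |x_k − x_{k−1}| and |y_k − y_{k−1}|
  (dot 1's predecessor is the screen center, so update₁ = |x₁|), the
  previous-dot running sums, and an intercept.  The response is
  deliberately absent (it is constant within a trial).  The accumulated
  variant drops the previous-sum x regressor.
* **response-aligned** — one row per non-timeout trial: z-scored choice
  (−1/+1), trial-time scaled to unit SD but *not* centered, intercept;
  evaluated on a 70-point grid (−500…190 ms, a configurable default since
  only the grid size, not the window, is fixed by the analysis) and as
  window-aggregated fits that stack all samples of a window into one
  regression per channel (defaults: build-up −500…−120 ms, response
  −30…100 ms).

Normalization contract: signals are z-scored across trials within each
(channel, original time point) *before* row expansion; regressors are
z-scored on the assembled design matrix *after* concatenation.  This
asymmetry is intentional and preserved: it makes single-regressor
coefficients equal Pearson correlations exactly, and coefficients of
nearly-uncorrelated regressors approximate correlations.  Pooled expanded
rows consequently need not have unit variance, which is accepted.

On the previous-sum regressor: it is often described as the Gram-Schmidt
orthogonalization of the full running sum with respect to the current x.
That identity is exact only when x and the previous sum are empirically
uncorrelated.  Under this task's ±25 px target drift,
cov(x_k, Σ_{i<k} x_i) = mean_px²·(k−1) > 0, so the pooled correlation
between them is ≈ 0.18 and the previous-sum regressor agrees with the GS
residual at r ≈ 0.98 rather than 1.  The package verifies the exact span
identity (the previous sum is an exact linear combination of full sum and
x), the near-exact agreement (r > 0.999) on drift-free stimuli, and the
r > 0.95 agreement under task conditions.

Serial dependence between overlapping expanded rows is not modelled (no
GLS/autocorrelation correction) — within-participant dependence is
absorbed by the across-participant second level.  Cells with too few rows
(late latencies in fast trials) are stored as missing, never imputed.
Rank-deficient designs and zero-variance columns raise errors naming the
offending columns; a config flag may instead drop constants (needed e.g.
for dot-1-only row sets where the previous sum is identically zero).

## Second-level inference

Per (regressor, location, time) cell, a two-sided one-sample t-test across
participants on the first-level coefficients; BH-FDR applied jointly over
the flattened grid of all times × all locations (for the default
dot-aligned source grid: 70 × 362 = 25,340 hypotheses).  Default α: 0.01
for the momentary-evidence map, 0.05 for the accumulated map (both
configurable).  Degenerate cells (zero variance) map to t = ±inf/p = 0 for
nonzero means and t = 0/p = 1 otherwise, without overflow.  Sensor-level
summaries use grand-average coefficient magnitudes (mean over channels of
|mean over participants|, rectification after averaging); source-level
summaries use t-magnitudes; both are always computed.  Significant cells
are reported as maximal contiguous time windows, with locations ranked by
time-averaged |t| within the window.

Null calibration runs the full response-aligned fitting + second-level +
FDR path on pure-noise cohorts (34 participants, 80 trials, a 70 × 40
grid, ≥ 200 cohorts — sizes chosen to keep the Monte-Carlo cheap while the
participant count matches the design).  Under the global null the
realized false-discovery proportion per cohort is 1 exactly when the mask
is non-empty, and BH bounds its mean by α; with independent continuous
p-values the bound is attained, so the replicate mean is compared to α
plus three binomial standard errors (a Monte-Carlo allowance, not a
loosened criterion).

## Pattern differences between windows

To compare spatial patterns rather than overall levels, each participant's
per-location magnitude vector |β| from the window-aggregated fit is
normalized per window: subtract the subset minimum, divide by the subset
mean of the shifted values (subset = all locations at sensor level; only
each window's significant locations at source level, with differences then
evaluated over the union).  First-level differences B − A are tested per
location across participants, BH-corrected at α = 0.01.  Ties at the
minimum map to exactly 0; constant patterns are rejected.  The statistic
is invariant to any positive rescaling of a window's magnitudes, which the
tests exploit as the uniform-scaling control.

Two structural caveats, documented because the validation had to respect
them: (i) the mean-normalization makes a boost of total mass D leak −D/n
into every other location, so a localized change is detectable *as
localized* only when the cluster is small relative to the grid; (ii)
windows of unequal width give the two patterns unequal sampling error,
and the noisier scale estimate biases normalized differences — the
specificity validation therefore compares equal-width windows, while the
analysis defaults keep the conventional build-up/response windows.

## Behavioral analysis

Per participant and dot k, the Pearson correlation across non-timeout
trials between the signed choice and x_k (momentary), Σ_{i≤k} x_i
(accumulated), or the y analogues.  Zero-variance inputs yield NaN, never
silent zeros.  The across-dot test is a one-way ANOVA treating
participant × dot cells as independent observations — with 14 dots and 34
participants, dof (13, 462) — followed by paired t-tests between dots
(dof 33 at n = 34).  Correlations enter untransformed by default (a
Fisher-z switch would be a trivial extension; untransformed matches the
printed degrees of freedom and the bounded range of the observed values).

## Reproducibility and problem sizes

Every random quantity flows from explicit seeds via `SeedSequence`
spawning; reruns are byte-identical.  The validation suite uses scaled
problem sizes chosen to make each property measurable with comfortable
statistical margins at interactive runtimes: full 480-trial sessions with
6–8 channels for recovery checks (≥ 2000 expanded rows), 34-participant
cohorts on a 70 × 40 grid for FDR calibration, 15 participants × 102
channels for pattern specificity, and 64-trial mini-sessions for unit
tests.  Channel counts are free parameters throughout; 102 mirrors a
magnetometer grid and is the default for sensor-style simulations.

## Known limitations

* OLS ignores serial dependence of overlapping rows; first-level SEs are
  optimistic, which is why inference is exclusively second-level.
* The accumulator is a stand-in for human behavior: no collapsing bounds,
  urgency, or fitted parameters; its calibration targets summary behavior
  only.
* White noise makes power estimates optimistic relative to real MEG.
* The pattern-difference statistic inherits the normalization caveats
  above; conclusions about locations near the pattern minimum are fragile.
* The response regressor in the standard design excludes timeout trials
  (the convention is unstated in the source analysis; exclusion matches
  the response-aligned design).
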