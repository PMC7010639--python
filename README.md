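# evreg

Event-related evidence regression for fast, within-trial perceptual
decision stimuli — a tested, fully synthetic-data-validated implementation
of the analysis stack used to ask *where and when neural signals track
decision evidence* in tasks whose stimulus delivers a new piece of
evidence every 100 ms.

It is written for researchers who analyze event-stream M/EEG-style
recordings (trials × channels × time at 100 Hz) and want the complete
chain — task simulation with known ground truth, evidence definitions,
overlapping-epoch regression designs, mass-univariate group statistics
with FDR, and pattern-difference tests — as a reusable, seeded library.

## The analysis in brief

A dot jumps to a new position every 100 ms; its signed x-coordinate is the
momentary decision evidence and, for targets at (±μ, 0) with isotropic
Gaussian scatter σ, the ideal observer's log posterior odds after k dots
is affine in the running sum:

    logodds_k = (2μ/σ²) · Σ_{i≤k} x_i + bias        (μ = 25 px, σ = 70 px)

so the cumulative sum serves as the accumulated-evidence regressor.

The core statistical object is the **expanded (overlapping-epoch)
regression**: for a latency t from dot onset, every (trial, dot) pair
contributes one signal sample at `onset + t` — provided the dot appeared
before the response and the sample falls more than 200 ms before it — and
the pooled rows are regressed on the per-dot evidence regressors.  Data
are z-scored across trials within each (channel, time point) *before*
pooling and regressors are z-scored *after* assembly, so coefficients read
as (approximate) correlations.  Example: a trial answered at 880 ms shows
9 dots, has 8 candidate samples at t = 120 ms, and keeps 6 rows after the
motor exclusion.

Per-participant coefficient maps are tested across participants with
two-sided t-tests and Benjamini–Hochberg FDR applied jointly over the full
time × location grid (70 × 362 = 25,340 hypotheses for the default
dot-aligned source grid).  Response-aligned analyses add a
window-difference statistic on min-0/mean-1 normalized magnitude patterns
that is exactly invariant to global amplitude changes.

All of it is exercised against a synthetic-data generator that embeds
linear, lag-specific correlates with known topography and amplitude, so
recovery, specificity and null calibration are testable properties rather
than hopes.  See `docs/methods.md` for the full model description and
design decisions.

## Worked example

`examples/03_expanded_regression.py` embeds a momentary-evidence correlate
at 120 ms after every dot onset with a theoretical signal correlation of
0.1, then recovers it with the expanded regression:

```
rows entering the regression at the peak: 3801
recovered peak latency:  120 ms (truth: 120 ms)
recovered coefficient:   0.1178 (truth: 0.1, SE ~ 0.0162)
```

The peak falls exactly at the embedded lag and the coefficient equals the
planted correlation within sampling error — with both sides z-scored, the
coefficient *is* the correlation.  The other examples walk through
stimulus construction and simulated behavior (480 trials, accuracy ≈ 0.78,
median RT ≈ 1.1 s), the log-odds/cumulative-sum equivalence (r ≈ 0.995),
group-level FDR inference, pattern differences, and the one-config
end-to-end pipeline (`evreg run-all --out dir` on the CLI).

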