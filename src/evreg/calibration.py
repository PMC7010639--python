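"""Ground-truth validation routines: recovery, null calibration, specificity.

These drive the full analysis stack on synthetic data whose truth is known
and summarize how well it is recovered:

* evidence_recovery       — embeds a lag-specific momentary-evidence effect
                            with a chosen theoretical correlation and checks
                            that the expanded regression finds it at the
                            right latency and magnitude;
* null_fdr_calibration    — measures the realized false-discovery
                            proportion of the second-level BH-FDR pipeline
                            on cohorts with no effect at all;
* pattern_specificity     — checks that the window-difference statistic
                            ignores global amplitude changes and localizes
                            cluster-confined boosts.
"""

from __future__ import annotations

import numpy as np

from .design import DesignConfig
from .firstlevel import (
    BUILDUP_WINDOW_MS,
    RESPONSE_WINDOW_MS,
    run_expanded,
    run_response,
    run_window_aggregate,
)
from .group import fdr_correct, second_level
from .observer import TrialOutcome, simulate_outcomes
from .pattern import compare_windows, window_magnitudes
from .simulate import EffectSpec, SignalTensor, amplitude_for_correlation, simulate_session
from .stimulus import StimulusSet, build_stimulus_set


def evidence_recovery(
    seed: int,
    correlation: float = 0.1,
    lag_ms: int = 120,
    n_channels: int = 6,
    stimuli: StimulusSet | None = None,
    times_ms: np.ndarray | None = None,
) -> dict:
    """Embed and recover a momentary-evidence effect at one latency.

    A 10 ms impulse correlate of the dot x-coordinate is embedded at
    lag_ms with amplitude chosen for the requested theoretical correlation;
    the expanded regression is run over the full dot-aligned grid and the
    peak latency and coefficient of the evidence regressor are returned.
    """
    ss = np.random.SeedSequence(seed)
    r_stim, r_beh, r_sig = [np.random.default_rng(c) for c in ss.spawn(3)]
    if stimuli is None:
        stimuli = build_stimulus_set(rng=r_stim)
    outcomes = simulate_outcomes(stimuli, rng=r_beh)
    eff = EffectSpec("x", lag_ms, np.ones(n_channels),
                     amplitude_for_correlation(correlation), duration_ms=10)
    tensor = simulate_session(stimuli, outcomes, [eff], noise_sd=1.0,
                              rng=r_sig, n_channels=n_channels)
    if times_ms is None:
        times_ms = np.arange(0, 700, 10)
    fl = run_expanded(tensor, stimuli, outcomes, DesignConfig(), times_ms)
    trace = np.abs(fl.coef("x")).mean(axis=0)
    j = int(np.nanargmax(trace))
    n = int(fl.n_rows[j])
    return {
        "peak_lag_ms": int(fl.times_ms[j]),
        "coefficient": float(fl.coef("x")[:, j].mean()),
        "target_correlation": correlation,
        "n_rows": n,
        "se": 1.0 / np.sqrt(n),
    }


def _null_cohort_tensors(n_participants: int, n_trials: int, n_channels: int,
                         rng: np.random.Generator):
    """Pure-noise response-locked sessions: every trial responds at 600 ms.

    The fixed RT keeps the full -500..190 ms response-aligned grid inside
    the simulated span so all cells of the grid are estimated.
    """
    times = np.arange(100, 800, 10)
    choices = np.where(np.arange(n_trials) % 2 == 0, 1, -1)
    outcomes = [TrialOutcome(i, int(c), 600.0, False, bool(c == 1))
                for i, c in enumerate(rng.permutation(choices))]
    tensors = [
        SignalTensor(p, rng.normal(size=(n_trials, n_channels, times.size)),
                     times, [f"A{c:03d}" for c in range(n_channels)])
        for p in range(n_participants)
    ]
    return tensors, outcomes


def null_fdr_calibration(
    seed: int,
    n_cohorts: int = 250,
    n_participants: int = 34,
    n_trials: int = 80,
    n_channels: int = 40,
    alphas: tuple[float, ...] = (0.01, 0.05),
) -> dict:
    """Realized false-discovery proportion of the full second-level path.

    Each cohort runs the response-aligned univariate grid (70 time points x
    n_channels locations) per participant on signal tensors containing no
    effect, then second-level t-tests and joint BH-FDR.  Under the global
    null every rejection is false, so the per-cohort FDP is 1 whenever the
    mask is non-empty; its mean over cohorts estimates the FDR, which BH
    bounds by alpha.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    fdp = {a: [] for a in alphas}
    for _ in range(n_cohorts):
        tensors, outcomes = _null_cohort_tensors(n_participants, n_trials,
                                                 n_channels, rng)
        firstlevel = [run_response(t, outcomes) for t in tensors]
        grp = second_level(firstlevel)
        p = grp.p[grp.regressors.index("choice")]
        for a in alphas:
            fdp[a].append(float(fdr_correct(p, a).any()))
    return {
        "alphas": alphas,
        "mean_fdp": {a: float(np.mean(fdp[a])) for a in alphas},
        "n_cohorts": n_cohorts,
        "mc_se": {a: float(np.sqrt(a * (1 - a) / n_cohorts)) for a in alphas},
    }


def pattern_specificity(
    seed: int,
    n_participants: int = 15,
    n_channels: int = 102,
    cluster: tuple[int, ...] = (40, 41),
    base_correlation: float = 0.25,
    boost: float = 0.8,
    alpha: float = 0.01,
    window_a: tuple[int, int] = (-420, -290),
    window_b: tuple[int, int] = RESPONSE_WINDOW_MS,
) -> dict:
    """Window-difference specificity on a cohort with known pattern change.

    Every participant carries a choice-locked effect with a smooth channel
    profile in both the build-up and the response window; in the response
    window the profile is additionally boosted on a small channel cluster.
    The uniform-scaling control multiplies one window's magnitudes by a
    constant, which pattern normalization must cancel exactly.

    The cluster is kept small relative to the sensor grid: because the
    normalization fixes each pattern's mean, a boost of total mass D leaks
    -D/n into every other location, so specificity requires the leak to be
    well below the across-participant noise while the per-cluster-channel
    change stays well above it (ratio ~ n / (cluster size * norm value)).
    The two compared windows have equal width so that both first-level
    magnitude patterns carry the same sampling error; unequal widths would
    let the noisier window's scale estimate bias the normalized difference.
    """
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    stimuli = build_stimulus_set(n_long=4, n_catch=8, rng=rng)
    profile = 1.0 + 0.5 * np.sin(np.linspace(0, 3 * np.pi, n_channels))
    amp = amplitude_for_correlation(base_correlation)
    boosted = profile.copy()
    boosted[list(cluster)] += boost
    fits_a, fits_b = [], []
    for child in ss.spawn(n_participants):
        prng = np.random.default_rng(child)
        outcomes = simulate_outcomes(stimuli, rng=prng)
        effects = [
            EffectSpec("choice", window_a[0] - 10, amp * profile, 1.0,
                       align="response",
                       duration_ms=window_a[1] - window_a[0] + 30),
            EffectSpec("choice", window_b[0] - 10, amp * boosted, 1.0,
                       align="response",
                       duration_ms=window_b[1] - window_b[0] + 30),
        ]
        tensor = simulate_session(stimuli, outcomes, effects, noise_sd=1.0,
                                  rng=prng, n_channels=n_channels)
        fits_a.append(run_window_aggregate(tensor, outcomes, window_a))
        fits_b.append(run_window_aggregate(tensor, outcomes, window_b))
    mags_a = window_magnitudes(fits_a)
    mags_b = window_magnitudes(fits_b)
    ids = fits_a[0].channel_ids
    # control: a global amplitude change must be invisible
    uniform = compare_windows(mags_a, 2.0 * mags_a, ids, alpha=alpha)
    localized = compare_windows(mags_a, mags_b, ids, alpha=alpha)
    flagged = set(np.nonzero(localized.significant)[0].tolist())
    return {
        "uniform_n_flagged": int(uniform.significant.sum()),
        "flagged": sorted(flagged),
        "cluster": sorted(cluster),
        "flags_outside_cluster": sorted(flagged - set(cluster)),
        "flags_inside_cluster": sorted(flagged & set(cluster)),
        "mean_diff_cluster": float(
            localized.mean_diff[list(cluster)].mean()),
    }
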