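"""Ideal-observer evidence definitions and bounded-accumulator behavior.

For two targets at (±mean_px, 0) with isotropic Gaussian dot scatter, the
ideal observer's momentary evidence is the signed dot x-coordinate and the
log posterior odds of right vs. left after k dots reduces to a scaled
cumulative sum of x-coordinates:

    logodds_k = (2 * mean_px / sd_px**2) * sum_{i<=k} x_i + prior_bias

(the symmetric targets cancel all y-terms and the quadratic terms of the
Gaussian log-likelihoods).  Simulated choices come from a discrete-time
bounded accumulator that adds one noisy evidence sample per 100 ms frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stimulus import (
    DEFAULT_MEAN_PX,
    DEFAULT_SD_PX,
    DOT_DURATION_MS,
    TIMEOUT_MS,
    DotSequence,
    StimulusSet,
)

# Accumulator defaults, calibrated once by forward simulation on the default
# 480-trial stimulus set to land in the task's behavioral regime
# (accuracy ~75-80%, median RT ~1.1 s); see docs/methods.md.
DEFAULT_ACC_NOISE_SD = 115.0   # px per 100 ms step
DEFAULT_BOUND = 420.0          # px
DEFAULT_NDT_MS = 300.0         # non-decision time


@dataclass
class EvidenceSeries:
    """Per-dot evidence quantities for one trial."""

    momentary: np.ndarray         # signed x-coordinate, px
    accumulated: np.ndarray       # running sum up to and including dot k, px
    accumulated_prev: np.ndarray  # running sum up to the previous dot, px
    logodds: np.ndarray           # ideal-observer log posterior odds


@dataclass
class TrialOutcome:
    """Simulated (or recorded) behavior for one trial."""

    trial_id: int
    choice: int        # -1 left, +1 right, 0 timeout
    rt_ms: float       # from first dot onset
    timed_out: bool
    correct: bool

    def __post_init__(self) -> None:
        if self.timed_out != (self.choice == 0):
            raise ValueError("timed_out must hold exactly when choice == 0")


def evidence_series(
    seq: DotSequence,
    mean_px: float = DEFAULT_MEAN_PX,
    sd_px: float = DEFAULT_SD_PX,
    prior_bias: float = 0.0,
) -> EvidenceSeries:
    """Momentary evidence, prefix sums and log posterior odds for one trial."""
    momentary = seq.x.astype(float)
    accumulated = np.cumsum(momentary)
    accumulated_prev = np.concatenate([[0.0], accumulated[:-1]])
    logodds = log_posterior_odds_series(seq, mean_px, sd_px, prior_bias)
    return EvidenceSeries(momentary, accumulated, accumulated_prev, logodds)


def log_posterior_odds_series(
    seq: DotSequence,
    mean_px: float = DEFAULT_MEAN_PX,
    sd_px: float = DEFAULT_SD_PX,
    prior_bias: float = 0.0,
) -> np.ndarray:
    """Log posterior odds of right vs. left after each dot of the trial."""
    if sd_px <= 0:
        raise ValueError(f"sd_px must be > 0, got {sd_px}")
    return (2.0 * mean_px / sd_px**2) * np.cumsum(seq.x) + prior_bias


def log_posterior_odds(
    seq: DotSequence,
    k: int,
    mean_px: float = DEFAULT_MEAN_PX,
    sd_px: float = DEFAULT_SD_PX,
    prior_bias: float = 0.0,
) -> float:
    """Log posterior odds after dots 1..k (k is 1-based)."""
    if not 1 <= k <= seq.n_dots:
        raise ValueError(f"k must be in 1..{seq.n_dots}, got {k}")
    return float(log_posterior_odds_series(seq, mean_px, sd_px, prior_bias)[k - 1])


def simulate_decision(
    seq: DotSequence,
    acc_noise_sd: float = DEFAULT_ACC_NOISE_SD,
    bound: float = DEFAULT_BOUND,
    ndt_ms: float = DEFAULT_NDT_MS,
    rng: np.random.Generator | None = None,
    timeout_ms: float = TIMEOUT_MS,
) -> TrialOutcome:
    """Simulate one bounded-accumulator decision.

    At each 100 ms frame the accumulator adds x[k] plus Gaussian noise; the
    response is the sign of the state when its magnitude first reaches the
    bound, at time (frame * 100 + ndt_ms).  If the bound is never reached
    within the dot sequence, or the response would fall after the timeout,
    the trial times out with choice 0.
    """
    if bound <= 0:
        raise ValueError(f"bound must be > 0, got {bound}")
    if ndt_ms < 0:
        raise ValueError(f"ndt_ms must be >= 0, got {ndt_ms}")
    rng = np.random.default_rng() if rng is None else rng
    state = 0.0
    noise = rng.normal(0.0, acc_noise_sd, size=seq.n_dots) if acc_noise_sd > 0 \
        else np.zeros(seq.n_dots)
    for k in range(seq.n_dots):
        state += seq.x[k] + noise[k]
        if abs(state) >= bound:
            rt = (k + 1) * DOT_DURATION_MS + ndt_ms
            if rt > timeout_ms:
                break
            choice = 1 if state > 0 else -1
            return TrialOutcome(seq.trial_id, choice, rt, False,
                                correct=(choice == seq.target))
    return TrialOutcome(seq.trial_id, 0, float(timeout_ms), True, correct=False)


def simulate_outcomes(
    stimuli: StimulusSet,
    acc_noise_sd: float = DEFAULT_ACC_NOISE_SD,
    bound: float = DEFAULT_BOUND,
    ndt_ms: float = DEFAULT_NDT_MS,
    rng: np.random.Generator | int | None = None,
) -> list[TrialOutcome]:
    """Simulate one participant's choices/RTs for a whole stimulus set."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    elif rng is None:
        rng = np.random.default_rng()
    return [
        simulate_decision(seq, acc_noise_sd, bound, ndt_ms, rng,
                          timeout_ms=stimuli.timeout_ms)
        for seq in stimuli.sequences
    ]


def behavior_summary(outcomes: list[TrialOutcome]) -> dict:
    """Accuracy and median RT over non-timeout trials, plus timeout rate."""
    responded = [o for o in outcomes if not o.timed_out]
    n = len(outcomes)
    if not responded:
        return {"accuracy": np.nan, "median_rt_ms": np.nan, "timeout_rate": 1.0}
    return {
        "accuracy": float(np.mean([o.correct for o in responded])),
        "median_rt_ms": float(np.median([o.rt_ms for o in responded])),
        "timeout_rate": float(1.0 - len(responded) / n),
    }


def check_calibration(
    stimuli: StimulusSet,
    acc_noise_sd: float = DEFAULT_ACC_NOISE_SD,
    bound: float = DEFAULT_BOUND,
    ndt_ms: float = DEFAULT_NDT_MS,
    accuracy_band: tuple[float, float] = (0.70, 0.85),
    rt_band_ms: tuple[float, float] = (800.0, 1400.0),
    rng: np.random.Generator | int | None = None,
) -> dict:
    """Simulate the set and report whether behavior falls in the target bands."""
    outcomes = simulate_outcomes(stimuli, acc_noise_sd, bound, ndt_ms, rng)
    summary = behavior_summary(outcomes)
    summary["accuracy_in_band"] = bool(
        accuracy_band[0] <= summary["accuracy"] <= accuracy_band[1])
    summary["rt_in_band"] = bool(
        rt_band_ms[0] <= summary["median_rt_ms"] <= rt_band_ms[1])
    return summary


def outcomes_to_frame(outcomes: list[TrialOutcome]) -> pd.DataFrame:
    return pd.DataFrame(
        [(o.trial_id, o.choice, o.rt_ms, o.timed_out, o.correct)
         for o in outcomes],
        columns=["trial_id", "choice", "rt_ms", "timed_out", "correct"],
    )


def outcomes_from_frame(df: pd.DataFrame) -> list[TrialOutcome]:
    return [
        TrialOutcome(int(r.trial_id), int(r.choice), float(r.rt_ms),
                     bool(r.timed_out), bool(r.correct))
        for r in df.itertuples()
    ]
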