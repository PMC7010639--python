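"""Per-participant OLS over the time x channel grid for all three designs.

Every fit is an ordinary least-squares regression of z-scored signals on
z-scored regressors, so with (approximately) uncorrelated regressors the
coefficients read as correlations.  Serial dependence between overlapping
expanded rows is not modelled (plain OLS throughout); second-level inference
across participants absorbs the resulting within-participant dependence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import (
    DesignConfig,
    build_expanded_design,
    build_expanded_rows,
    build_response_design,
    build_standard_design,
    zscore_signal,
)
from .observer import TrialOutcome
from .simulate import SignalTensor
from .stimulus import StimulusSet

#: default dot-aligned latency grid: 0..690 ms in 10 ms steps (70 points)
DOT_ALIGNED_TIMES = np.arange(0, 700, 10)
#: default response-aligned grid: -500..190 ms in 10 ms steps (70 points)
RESPONSE_ALIGNED_TIMES = np.arange(-500, 200, 10)
#: response-aligned windows for the aggregated fits (ms, inclusive)
BUILDUP_WINDOW_MS = (-500, -120)
RESPONSE_WINDOW_MS = (-30, 100)


@dataclass
class FirstLevelResult:
    """Fitted coefficients for one participant on a time grid.

    coefficients has shape (n_regressors, n_channels, n_times); cells whose
    regression had too few rows are NaN and are excluded by group tests.
    """

    participant_id: int | str
    coefficients: np.ndarray
    regressors: list[str]
    channel_ids: list[str]
    times_ms: np.ndarray
    n_rows: np.ndarray
    design: str = ""
    meta: dict = field(default_factory=dict)

    def coef(self, regressor: str) -> np.ndarray:
        """(n_channels, n_times) coefficient map of one regressor."""
        return self.coefficients[self.regressors.index(regressor)]

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("beta", data=self.coefficients)
            f.create_dataset("n_rows", data=self.n_rows)
            f.create_dataset("time_ms", data=self.times_ms)
            f.create_dataset("regressors",
                             data=np.array(self.regressors, dtype="S"))
            f.create_dataset("channel_ids",
                             data=np.array(self.channel_ids, dtype="S"))
            f.attrs["participant_id"] = str(self.participant_id)
            f.attrs["design"] = self.design


def fit_ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least-squares coefficients for a full-column-rank design.

    y may hold several right-hand sides (columns); the result then has one
    coefficient column per side.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more rows ({n}) than regressors ({p})")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # pinpoint offending columns via rank-revealing QR diagonal
        r = np.abs(np.diag(np.linalg.qr(X, mode="r")))
        tol = r.max() * max(X.shape) * np.finfo(float).eps
        bad = [str(j) for j in np.nonzero(r <= tol)[0]]
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {p}); "
            f"collinear columns: {', '.join(bad) or 'unresolved'}")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta


def permute_trials(tensor: SignalTensor,
                   rng: np.random.Generator | int | None = None) -> SignalTensor:
    """Permute the trial axis identically across channels and times.

    Breaking the trial correspondence between signal and stimuli provides
    the permutation null for all regression analyses.
    """
    if tensor.n_trials < 2:
        raise ValueError("need at least 2 trials to permute")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    elif rng is None:
        rng = np.random.default_rng()
    perm = rng.permutation(tensor.n_trials)
    return replace(tensor, data=tensor.data[perm])


def run_expanded(
    tensor: SignalTensor,
    stimuli: StimulusSet,
    outcomes: list[TrialOutcome],
    cfg: DesignConfig | None = None,
    times_ms: np.ndarray = DOT_ALIGNED_TIMES,
    zscore: bool = True,
) -> FirstLevelResult:
    """Expanded (overlapping-epoch) regression over the latency grid.

    One regression per time-from-dot-onset, shared across channels: the
    selected rows are concatenated across trials into one long data vector
    per channel and regressed on the per-(trial, dot) evidence regressors.
    """
    cfg = cfg or DesignConfig()
    z = zscore_signal(tensor) if zscore else tensor
    names = None
    coefs, n_rows = [], []
    for t in times_ms:
        rows = build_expanded_rows(outcomes, int(t), cfg)
        if len(rows) == 0:
            coefs.append(None)
            n_rows.append(0)
            continue
        dsg = build_expanded_design(stimuli, rows, cfg, int(t))
        names = dsg.names
        if dsg.n_rows <= len(dsg.names):
            coefs.append(None)
            n_rows.append(dsg.n_rows)
            continue
        ti = rows["trial_index"].to_numpy()
        si = ((rows["sample_time_ms"].to_numpy() - int(z.times_ms[0]))
              // z.sample_ms).astype(int)
        Y = z.data[ti, :, si]                    # (n_rows, n_channels)
        coefs.append(fit_ols(dsg.X, Y))
        n_rows.append(dsg.n_rows)
    if names is None:
        raise ValueError("no time point produced any rows")
    p = len(names)
    out = np.full((p, tensor.n_channels, len(times_ms)), np.nan)
    for j, b in enumerate(coefs):
        if b is not None and b.shape[0] == p:
            out[:, :, j] = b
    return FirstLevelResult(
        tensor.participant_id, out, names, tensor.channel_ids,
        np.asarray(times_ms), np.asarray(n_rows), design="expanded",
        meta={"variant": cfg.variant, "exclusion_ms": cfg.exclusion_ms})


def run_standard(
    tensor: SignalTensor,
    stimuli: StimulusSet,
    outcomes: list[TrialOutcome],
    n_dots: int = 6,
    times_ms: np.ndarray | None = None,
    zscore: bool = True,
) -> FirstLevelResult:
    """Standard per-trial regression at every first-dot-aligned time point."""
    z = zscore_signal(tensor) if zscore else tensor
    if times_ms is None:
        times_ms = z.times_ms[(z.times_ms >= 0) & (z.times_ms <= 1000)]
    df = build_standard_design(stimuli, outcomes, n_dots)
    idx = df["trial_index"].to_numpy()
    names = [c for c in df.columns if c != "trial_index"]
    X = df[names].to_numpy()
    si = np.array([z.sample_index(t) for t in times_ms])
    Y = z.data[idx][:, :, si]                    # (trials, channels, times)
    n = idx.size
    beta = fit_ols(X, Y.reshape(n, -1)).reshape(len(names), z.n_channels,
                                                si.size)
    return FirstLevelResult(
        tensor.participant_id, beta, names, tensor.channel_ids,
        np.asarray(times_ms), np.full(si.size, n), design="standard")


def _response_aligned_data(
    tensor: SignalTensor, outcomes: list[TrialOutcome],
    trial_index: np.ndarray, times_ms: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Extract trials x channels x reltimes signal aligned at the response.

    Returns the aligned array (NaN outside the recorded span) and a
    (trials, reltimes) validity mask.  Response times are rounded to the
    10 ms sample grid.
    """
    step = tensor.sample_ms
    rt = np.array([outcomes[i].rt_ms for i in trial_index])
    rt_idx = np.round(rt / step).astype(int) * step
    aligned = np.full((trial_index.size, tensor.n_channels, times_ms.size),
                      np.nan)
    tmin, tmax = tensor.times_ms[0], tensor.times_ms[-1]
    for r, (i, r0) in enumerate(zip(trial_index, rt_idx)):
        ts = r0 + times_ms
        ok = (ts >= tmin) & (ts <= tmax)
        if ok.any():
            si = ((ts[ok] - tmin) // step).astype(int)
            aligned[r][:, ok] = tensor.data[i][:, si]
    valid = ~np.isnan(aligned[:, 0, :])
    return aligned, valid


def run_response(
    tensor: SignalTensor,
    outcomes: list[TrialOutcome],
    times_ms: np.ndarray = RESPONSE_ALIGNED_TIMES,
) -> FirstLevelResult:
    """Univariate response-aligned regressions over the channel x time grid.

    Data are re-aligned at each trial's response, z-scored across trials
    within each aligned time point, and regressed on choice + trial-time +
    intercept.  Aligned samples falling outside the recorded span drop the
    trial at that time point only.
    """
    df = build_response_design(outcomes)
    idx = df["trial_index"].to_numpy()
    names = [c for c in df.columns if c != "trial_index"]
    X = df[names].to_numpy()
    aligned, valid = _response_aligned_data(tensor, outcomes, idx,
                                            np.asarray(times_ms))
    p = len(names)
    beta = np.full((p, tensor.n_channels, len(times_ms)), np.nan)
    n_rows = np.zeros(len(times_ms), dtype=int)
    all_valid = bool(valid.all())
    if all_valid:
        Y = aligned
        mu = Y.mean(axis=0, keepdims=True)
        sd = Y.std(axis=0, keepdims=True)
        if (sd == 0).any():
            raise ValueError("zero variance across trials in aligned data")
        Yz = (Y - mu) / sd
        beta = fit_ols(X, Yz.reshape(idx.size, -1)).reshape(
            p, tensor.n_channels, len(times_ms))
        n_rows[:] = idx.size
    else:
        for j in range(len(times_ms)):
            ok = valid[:, j]
            n_rows[j] = int(ok.sum())
            if n_rows[j] <= p:
                continue
            Y = aligned[ok, :, j]
            sd = Y.std(axis=0)
            if (sd == 0).any():
                raise ValueError("zero variance across trials in aligned data")
            Yz = (Y - Y.mean(axis=0)) / sd
            beta[:, :, j] = fit_ols(X[ok], Yz)
    return FirstLevelResult(
        tensor.participant_id, beta, names, tensor.channel_ids,
        np.asarray(times_ms), n_rows, design="response")


def run_window_aggregate(
    tensor: SignalTensor,
    outcomes: list[TrialOutcome],
    window_ms: tuple[int, int],
) -> FirstLevelResult:
    """One response-aligned regression per channel over a whole time window.

    The z-scored aligned data from all times in the window are concatenated
    (trials x times rows) and regressed on the per-trial design repeated for
    each time, giving a single coefficient per channel and regressor.
    Defaults elsewhere use the build-up (-500..-120 ms) and response
    (-30..100 ms) windows.
    """
    lo, hi = window_ms
    if hi < lo:
        raise ValueError("empty window")
    step = tensor.sample_ms
    times = np.arange(lo, hi + step, step)
    df = build_response_design(outcomes)
    idx = df["trial_index"].to_numpy()
    names = [c for c in df.columns if c != "trial_index"]
    X = df[names].to_numpy()
    aligned, valid = _response_aligned_data(tensor, outcomes, idx, times)
    X_rows, Y_rows = [], []
    for j in range(times.size):
        ok = valid[:, j]
        if ok.sum() < 2:
            continue
        Y = aligned[ok, :, j]
        sd = Y.std(axis=0)
        if (sd == 0).any():
            raise ValueError("zero variance across trials in aligned data")
        Y_rows.append((Y - Y.mean(axis=0)) / sd)
        X_rows.append(X[ok])
    if not X_rows:
        raise ValueError("window contains no valid samples")
    Xc = np.vstack(X_rows)
    Yc = np.vstack(Y_rows)
    beta = fit_ols(Xc, Yc)[:, :, None]           # (p, channels, 1)
    return FirstLevelResult(
        tensor.participant_id, beta, names, tensor.channel_ids,
        np.array([(lo + hi) // 2]), np.array([Xc.shape[0]]),
        design="window", meta={"window_ms": (lo, hi)})
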