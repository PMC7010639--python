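"""Regression designs with the analysis' row-selection and normalization rules.

Three designs are supported:

* standard   — one row per trial, dot-specific regressors (x/y of the first
               n dots) plus response, trial-counter and intercept nuisances;
* expanded   — one row per (trial, dot) pair at a fixed latency from each
               dot's onset, pooling within-trial evidence fluctuations
               across trials; rows within 200 ms of the response are dropped;
* response   — one row per non-timeout trial with the signed choice, a
               trial-time nuisance and an intercept, for response-aligned
               fits.

Normalization contract: the signal is z-scored per (channel, original time
point) across trials BEFORE any row expansion; regressors are z-scored on
the assembled design matrix AFTER concatenation.  With both sides z-scored,
coefficients of mutually uncorrelated regressors equal Pearson correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .observer import TrialOutcome
from .simulate import SignalTensor
from .stimulus import DOT_DURATION_MS, StimulusSet

#: regressors of the momentary-evidence expanded design, in column order
MOMENTARY_COLUMNS = (
    "x", "y", "abs_x", "abs_y", "update_x", "update_y",
    "accum_prev_x", "accum_prev_y", "intercept",
)
#: the accumulated variant replaces x by the running sum and drops the
#: previous-sum x regressor
ACCUMULATED_COLUMNS = (
    "accum_x", "y", "abs_x", "abs_y", "update_x", "update_y",
    "accum_prev_y", "intercept",
)


@dataclass
class DesignConfig:
    """Options of the expanded design."""

    variant: str = "momentary"        # "momentary" | "accumulated"
    exclusion_ms: int = 200           # pre-response exclusion
    dot_duration_ms: int = DOT_DURATION_MS
    max_dots: int = 25
    drop_constant_columns: bool = False

    def __post_init__(self) -> None:
        if self.variant not in ("momentary", "accumulated"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.exclusion_ms < 0:
            raise ValueError("exclusion_ms must be >= 0")

    @property
    def columns(self) -> tuple[str, ...]:
        return (MOMENTARY_COLUMNS if self.variant == "momentary"
                else ACCUMULATED_COLUMNS)


@dataclass
class ExpandedDesign:
    """Row-expanded regression problem for one time-from-dot-onset."""

    time_from_onset_ms: int
    rows: pd.DataFrame            # trial_index, trial_id, dot_index, sample_time_ms
    X: np.ndarray                 # rows x regressors, z-scored + intercept
    names: list[str]

    @property
    def n_rows(self) -> int:
        return len(self.rows)


def zscore_columns(X: np.ndarray, names: list[str],
                   skip: tuple[str, ...] = ("intercept",),
                   drop_constant: bool = False,
                   uncentered: tuple[str, ...] = ()) -> tuple[np.ndarray, list[str]]:
    """Z-score design columns in place of the normalization contract.

    Columns named in `skip` are left untouched; columns in `uncentered` are
    scaled to unit SD without centering.  A zero-variance column raises
    (naming the column) unless drop_constant is set.
    """
    X = np.array(X, dtype=float)
    keep = []
    for j, name in enumerate(names):
        if name in skip:
            keep.append(j)
            continue
        sd = X[:, j].std()
        if sd == 0:
            if drop_constant:
                continue
            raise ValueError(f"regressor {name!r} has zero variance")
        if name in uncentered:
            X[:, j] = X[:, j] / sd
        else:
            X[:, j] = (X[:, j] - X[:, j].mean()) / sd
        keep.append(j)
    return X[:, keep], [names[j] for j in keep]


def expanded_row_counts(rt_ms: float, t_from_onset_ms: int,
                        cfg: DesignConfig | None = None) -> dict:
    """Counts behind the row-selection rule for a single trial.

    Returns the number of dots shown before the response, the candidate
    sample times at the requested latency, and the rows retained after the
    pre-response exclusion.
    """
    cfg = cfg or DesignConfig()
    d = cfg.dot_duration_ms
    onsets = np.arange(cfg.max_dots) * d
    shown = onsets < rt_ms
    sample = onsets + t_from_onset_ms
    candidate = shown & (sample < rt_ms)
    retained = candidate & (sample < rt_ms - cfg.exclusion_ms)
    return {
        "n_dots_shown": int(shown.sum()),
        "n_candidates": int(candidate.sum()),
        "n_retained": int(retained.sum()),
    }


def build_expanded_rows(
    outcomes: list[TrialOutcome],
    t_from_onset_ms: int,
    cfg: DesignConfig | None = None,
) -> pd.DataFrame:
    """Select the (trial, dot) rows entering the expanded regression.

    For each non-timeout trial, dot k (1-based, onset (k-1)*100 ms) yields a
    row at sample time (k-1)*100 + t_from_onset if the dot's onset precedes
    the response and the sample time falls strictly before rt - exclusion.
    """
    if t_from_onset_ms < 0:
        raise ValueError("t_from_onset_ms must be >= 0")
    cfg = cfg or DesignConfig()
    d = cfg.dot_duration_ms
    records = []
    for i, o in enumerate(outcomes):
        if o.timed_out:
            continue
        for k in range(1, cfg.max_dots + 1):
            onset = (k - 1) * d
            if onset >= o.rt_ms:
                break
            sample = onset + t_from_onset_ms
            if sample < o.rt_ms and sample < o.rt_ms - cfg.exclusion_ms:
                records.append((i, o.trial_id, k, sample))
    return pd.DataFrame(
        records,
        columns=["trial_index", "trial_id", "dot_index", "sample_time_ms"],
    )


def build_expanded_design(
    stimuli: StimulusSet,
    rows: pd.DataFrame,
    cfg: DesignConfig | None = None,
    t_from_onset_ms: int | None = None,
) -> ExpandedDesign:
    """Assemble the z-scored expanded design matrix for the selected rows."""
    if len(rows) == 0:
        raise ValueError("row set is empty")
    cfg = cfg or DesignConfig()
    x = stimuli.coordinate_matrix("x")
    y = stimuli.coordinate_matrix("y")
    ti = rows["trial_index"].to_numpy()
    k0 = rows["dot_index"].to_numpy() - 1        # 0-based dot index

    acc_x = np.cumsum(x, axis=1)
    acc_y = np.cumsum(y, axis=1)
    prev_x = np.concatenate([np.zeros((x.shape[0], 1)), acc_x[:, :-1]], axis=1)
    prev_y = np.concatenate([np.zeros((y.shape[0], 1)), acc_y[:, :-1]], axis=1)
    # previous position of dot 1 is the screen center
    lag_x = np.concatenate([np.zeros((x.shape[0], 1)), x[:, :-1]], axis=1)
    lag_y = np.concatenate([np.zeros((y.shape[0], 1)), y[:, :-1]], axis=1)

    values = {
        "x": x[ti, k0],
        "accum_x": acc_x[ti, k0],
        "y": y[ti, k0],
        "abs_x": np.abs(x[ti, k0]),
        "abs_y": np.abs(y[ti, k0]),
        "update_x": np.abs(x[ti, k0] - lag_x[ti, k0]),
        "update_y": np.abs(y[ti, k0] - lag_y[ti, k0]),
        "accum_prev_x": prev_x[ti, k0],
        "accum_prev_y": prev_y[ti, k0],
        "intercept": np.ones(len(rows)),
    }
    names = list(cfg.columns)
    X = np.column_stack([values[n] for n in names])
    X, names = zscore_columns(X, names,
                              drop_constant=cfg.drop_constant_columns)
    t = t_from_onset_ms
    if t is None and len(rows):
        t = int(rows["sample_time_ms"].iloc[0]
                - (rows["dot_index"].iloc[0] - 1) * cfg.dot_duration_ms)
    return ExpandedDesign(int(t), rows.reset_index(drop=True), X, names)


def build_standard_design(
    stimuli: StimulusSet,
    outcomes: list[TrialOutcome],
    n_dots: int = 6,
) -> pd.DataFrame:
    """Per-trial design: x/y of the first n_dots, response, trial counter.

    One row per non-timeout trial; all columns except the intercept are
    z-scored.  The extra column `trial_index` (not a regressor) maps rows
    back to the trial axis of the signal tensor.
    """
    x = stimuli.coordinate_matrix("x")
    y = stimuli.coordinate_matrix("y")
    rows = [i for i, o in enumerate(outcomes) if not o.timed_out]
    if len(rows) < 3:
        raise ValueError("need at least 3 non-timeout trials")
    idx = np.array(rows)
    cols = {f"x_{k+1}": x[idx, k] for k in range(n_dots)}
    cols.update({f"y_{k+1}": y[idx, k] for k in range(n_dots)})
    cols["response"] = np.array([outcomes[i].choice for i in idx], dtype=float)
    cols["trial_count"] = idx.astype(float)   # position within the session
    cols["intercept"] = np.ones(idx.size)
    names = list(cols)
    X, names = zscore_columns(np.column_stack(list(cols.values())), names)
    df = pd.DataFrame(X, columns=names)
    df.insert(0, "trial_index", idx)
    return df


def build_response_design(outcomes: list[TrialOutcome]) -> pd.DataFrame:
    """Per-trial response-aligned design: choice, trial-time, intercept.

    Choice is z-scored; trial-time is scaled to unit SD but deliberately not
    centered; timeout trials are excluded.
    """
    rows = [i for i, o in enumerate(outcomes) if not o.timed_out]
    if len(rows) < 3:
        raise ValueError("need at least 3 non-timeout trials")
    idx = np.array(rows)
    X = np.column_stack([
        np.array([outcomes[i].choice for i in idx], dtype=float),
        idx.astype(float) + 1.0,       # trial number within the experiment
        np.ones(idx.size),
    ])
    names = ["choice", "trial_time", "intercept"]
    X, names = zscore_columns(X, names, uncentered=("trial_time",))
    df = pd.DataFrame(X, columns=names)
    df.insert(0, "trial_index", idx)
    return df


def zscore_signal(tensor: SignalTensor) -> SignalTensor:
    """Z-score the signal per (channel, time point) across trials.

    This is the data half of the normalization contract and is applied
    before any row expansion.
    """
    if tensor.n_trials < 2:
        raise ValueError("z-scoring needs at least 2 trials")
    mean = tensor.data.mean(axis=0, keepdims=True)
    sd = tensor.data.std(axis=0, keepdims=True)
    bad = np.nonzero(sd[0] == 0)
    if bad[0].size:
        c, t = bad[0][0], bad[1][0]
        raise ValueError(
            f"zero variance across trials at channel "
            f"{tensor.channel_ids[c]!r}, time {tensor.times_ms[t]} ms")
    return replace(tensor, data=(tensor.data - mean) / sd)
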