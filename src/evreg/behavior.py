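"""Per-dot choice-evidence correlations and their across-dot tests.

For each participant and dot index k, the signed choice (-1/+1) is
correlated across trials with the momentary evidence (dot k's x-coordinate)
or the accumulated evidence (running sum up to dot k), and with the
y-coordinate analogues as decision-irrelevant controls.  In the task's
generative regime the accumulated-evidence correlation rises toward ~0.7
over the first ~10 dots while the momentary-evidence correlation stays
moderate and the y correlations hover around 0.  A one-way ANOVA across dot
indices and paired t-tests between dots quantify whether individual dots
differ in their influence on the choice.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .observer import TrialOutcome
from .stimulus import StimulusSet


def choice_evidence_correlation(
    outcomes: list[TrialOutcome],
    stimuli: StimulusSet,
    coordinate: str = "x",
    kind: str = "momentary",
    max_dots: int | None = None,
) -> np.ndarray:
    """Pearson r between choices and per-dot evidence for one participant.

    Returns one correlation per dot index (1..max_dots), computed across
    the participant's non-timeout trials.  Zero-variance inputs yield NaN
    (flagged, never silently 0).
    """
    if kind not in ("momentary", "accumulated"):
        raise ValueError(f"kind must be 'momentary' or 'accumulated', got {kind!r}")
    values = stimuli.coordinate_matrix(coordinate)
    if kind == "accumulated":
        values = np.cumsum(values, axis=1)
    keep = np.array([not o.timed_out for o in outcomes])
    if keep.sum() < 3:
        raise ValueError("need at least 3 non-timeout trials")
    choice = np.array([o.choice for o in outcomes], dtype=float)[keep]
    values = values[keep]
    n_dots = values.shape[1] if max_dots is None else max_dots
    r = np.empty(n_dots)
    c_sd = choice.std()
    for k in range(n_dots):
        v = values[:, k]
        if c_sd == 0 or v.std() == 0:
            r[k] = np.nan
        else:
            r[k] = np.corrcoef(choice, v)[0, 1]
    return r


def correlation_table(
    outcomes_per_participant: list[list[TrialOutcome]],
    stimuli: StimulusSet,
    coordinate: str = "x",
    kind: str = "momentary",
    max_dots: int = 14,
) -> pd.DataFrame:
    """Participants x dots table of choice-evidence correlations."""
    rows = [
        choice_evidence_correlation(out, stimuli, coordinate, kind, max_dots)
        for out in outcomes_per_participant
    ]
    return pd.DataFrame(
        np.stack(rows),
        index=pd.RangeIndex(len(rows), name="participant"),
        columns=pd.Index(range(1, max_dots + 1), name="dot"),
    )


def dot_influence_anova(table: pd.DataFrame,
                        dots: list[int] | None = None) -> dict:
    """One-way ANOVA of the correlations across dot indices.

    Participant x dot cells are treated as independent observations, giving
    dof (n_dots - 1, n_dots * n_participants - n_dots); with 14 dots and 34
    participants this is (13, 462).
    """
    if dots is None:
        dots = list(table.columns)
    sub = table[dots]
    if sub.isna().any().any():
        raise ValueError("correlation table has missing cells")
    groups = [sub[d].to_numpy() for d in dots]
    n_dots, n_part = len(dots), len(sub)
    if np.ptp(sub.to_numpy()) == 0:
        f, p = 0.0, 1.0       # no variation anywhere: no dot effect
    else:
        f, p = stats.f_oneway(*groups)
    return {"F": float(f), "dof1": n_dots - 1,
            "dof2": n_dots * n_part - n_dots, "p": float(p)}


def paired_dot_ttest(table: pd.DataFrame, i: int, j: int) -> dict:
    """Paired two-sided t-test across participants between dots i and j."""
    a, b = table[i], table[j]
    if a.isna().any() or b.isna().any():
        raise ValueError("both dots must be present for all participants")
    if len(a) < 2:
        raise ValueError("need at least 2 participants")
    diff = (a - b).to_numpy()
    if np.ptp(diff) == 0 and diff[0] == 0:
        t, p = 0.0, 1.0       # identical columns
    else:
        t, p = stats.ttest_rel(a, b)
    return {"t": float(t), "dof": len(a) - 1, "p": float(p)}
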