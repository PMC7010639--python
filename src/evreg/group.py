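"""Second-level (across-participant) inference over the time x location grid.

First-level coefficients are treated as the participant-level summary
statistic: each (regressor, location, time) cell gets a one-sample two-sided
t-test across participants, and the resulting p-values are corrected for
false discovery rate with the Benjamini-Hochberg step-up applied jointly
over the full flattened grid (all times x all locations).  For the default
dot-aligned source grid of 70 time points x 362 areas this is 25,340 tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .firstlevel import FirstLevelResult


@dataclass
class GroupResult:
    """Across-participant statistics per (regressor, location, time)."""

    mean_beta: np.ndarray     # (n_reg, n_loc, n_time)
    t: np.ndarray
    p: np.ndarray
    regressors: list[str]
    location_ids: list[str]
    times_ms: np.ndarray
    n_participants: int

    def significance(self, alpha: float = 0.05,
                     regressor: str | None = None) -> np.ndarray:
        """BH-FDR mask at level alpha, corrected over the full grid.

        Correction is per regressor (each regressor's map is one family of
        times x locations hypotheses).
        """
        if regressor is not None:
            r = self.regressors.index(regressor)
            return fdr_correct(self.p[r], alpha)
        return np.stack([fdr_correct(self.p[r], alpha)
                         for r in range(len(self.regressors))])

    def to_frame(self, alpha: float = 0.05) -> pd.DataFrame:
        """Tidy (regressor, location, time) table for TSV export."""
        sig = self.significance(alpha)
        recs = []
        for r, reg in enumerate(self.regressors):
            for c, loc in enumerate(self.location_ids):
                for j, t_ms in enumerate(self.times_ms):
                    recs.append((reg, loc, int(t_ms), self.mean_beta[r, c, j],
                                 self.t[r, c, j], self.p[r, c, j],
                                 bool(sig[r, c, j])))
        return pd.DataFrame(
            recs, columns=["regressor", "location", "time_ms", "mean_beta",
                           "t", "p", "significant"])


def second_level(results: list[FirstLevelResult]) -> GroupResult:
    """One-sample two-sided t-tests across participants per grid cell.

    Cells that are missing (NaN) for any participant stay NaN and are
    excluded from FDR correction.  Degenerate cells with zero variance map
    to t = +/-inf (p = 0) for a nonzero mean and t = 0 (p = 1) otherwise.
    """
    if len(results) < 2:
        raise ValueError("second level needs at least 2 participants")
    first = results[0]
    for r in results[1:]:
        if (r.coefficients.shape != first.coefficients.shape
                or not np.array_equal(r.times_ms, first.times_ms)
                or r.regressors != first.regressors):
            raise ValueError("first-level grids are not aligned")
    stack = np.stack([r.coefficients for r in results])   # (n_part, ...)
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    zero_sd = (sd == 0) & np.isfinite(mean)
    t[zero_sd & (mean != 0)] = np.sign(mean[zero_sd & (mean != 0)]) * np.inf
    t[zero_sd & (mean == 0)] = 0.0
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    p[np.isnan(t)] = np.nan
    return GroupResult(mean, t, p, list(first.regressors),
                       list(first.channel_ids), first.times_ms, n)


def fdr_correct(p: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up over the flattened grid.

    All hypotheses (every time point x every location) enter one joint
    correction; NaN cells are excluded and never significant.
    """
    p = np.asarray(p, dtype=float)
    mask = np.zeros(p.shape, dtype=bool)
    finite = np.isfinite(p)
    if finite.any():
        rej, *_ = multipletests(p[finite], alpha=alpha, method="fdr_bh")
        mask[finite] = rej
    return mask


def grand_average_magnitude(
    results: list[FirstLevelResult],
    regressor: str,
    channels: list[str] | None = None,
) -> dict:
    """Mean-over-channels magnitude of the grand-average coefficient.

    Per time point: |mean over participants of beta| averaged across the
    chosen channels (rectify after averaging), plus the signed grand-average
    topography for per-time maps.
    """
    stack = np.stack([r.coef(regressor) for r in results])  # (part, chan, time)
    grand = stack.mean(axis=0)
    ids = results[0].channel_ids
    if channels is not None:
        sel = [ids.index(c) for c in channels]
        trace = np.abs(grand[sel]).mean(axis=0)
    else:
        trace = np.abs(grand).mean(axis=0)
    return {"times_ms": results[0].times_ms, "magnitude": trace,
            "topography": grand}


def significant_windows(
    mask: np.ndarray,
    t: np.ndarray,
    times_ms: np.ndarray,
    location_ids: list[str],
    top_n: int = 5,
) -> list[dict]:
    """Maximal contiguous time intervals containing significant locations.

    For each interval, locations are ranked by their time-averaged |t| over
    the interval (the averaging runs over all time points in the window,
    significant or not, for the locations that reach significance at least
    once inside it).
    """
    mask = np.asarray(mask, dtype=bool)
    any_sig = mask.any(axis=0)
    windows = []
    j = 0
    while j < any_sig.size:
        if not any_sig[j]:
            j += 1
            continue
        j0 = j
        while j < any_sig.size and any_sig[j]:
            j += 1
        span = slice(j0, j)
        locs = np.nonzero(mask[:, span].any(axis=1))[0]
        score = np.abs(t[locs, span]).mean(axis=1)
        order = locs[np.argsort(score)[::-1]]
        windows.append({
            "t_start_ms": int(times_ms[j0]),
            "t_end_ms": int(times_ms[j - 1]),
            "locations": [location_ids[i] for i in order],
            "mean_abs_t": dict(zip((location_ids[i] for i in order),
                                   np.sort(score)[::-1].tolist())),
            "top": [location_ids[i] for i in order[:top_n]],
        })
    return windows
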