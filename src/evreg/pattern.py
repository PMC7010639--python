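"""Spatial correlation-pattern differences between two time windows.

Correlation magnitudes generally grow from the pre-response build-up to the
response itself; to compare the spatial *shape* of the patterns rather than
their level, each participant's magnitude pattern within a window is
normalized by shifting its minimum to 0 and scaling its mean to 1.
First-level differences between windows are then tested across participants
per location, with BH-FDR across locations.  At the source level the
normalization parameters are computed only over locations with a
significant effect in that window, and differences are evaluated for
locations significant in at least one window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .firstlevel import FirstLevelResult
from .group import fdr_correct


@dataclass
class PatternComparison:
    """Per-location window-difference statistics."""

    location_ids: list[str]
    mean_a: np.ndarray        # grand-average normalized magnitude, window A
    mean_b: np.ndarray
    mean_diff: np.ndarray     # grand average of first-level B - A
    t: np.ndarray
    p: np.ndarray
    significant: np.ndarray
    alpha: float
    tested: np.ndarray        # bool: location entered the difference test

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "location": self.location_ids,
            "norm_mag_a": self.mean_a,
            "norm_mag_b": self.mean_b,
            "mean_diff": self.mean_diff,
            "t": self.t,
            "p": self.p,
            "significant": self.significant,
            "tested": self.tested,
        })


def normalize_pattern(magnitudes: np.ndarray,
                      subset: np.ndarray | None = None) -> np.ndarray:
    """Shift-and-scale a spatial magnitude pattern.

    The subset minimum is shifted to 0 and the subset mean of the shifted
    values to 1; the resulting affine map is applied to all locations.
    Invariant under positive rescaling of the input.
    """
    m = np.asarray(magnitudes, dtype=float)
    if m.ndim != 1:
        raise ValueError("expected a 1-D magnitude pattern")
    idx = np.arange(m.size) if subset is None else np.asarray(subset)
    if idx.dtype == bool:
        idx = np.nonzero(idx)[0]
    if idx.size < 2:
        raise ValueError("normalization subset must have at least 2 locations")
    shifted = m - m[idx].min()
    scale = shifted[idx].mean()
    if scale == 0:
        raise ValueError("magnitudes are constant over the subset")
    return shifted / scale


def window_magnitudes(results: list[FirstLevelResult],
                      regressor: str = "choice") -> np.ndarray:
    """(participants, locations) |beta| from window-aggregated fits."""
    return np.stack([np.abs(r.coef(regressor)[:, 0]) for r in results])


def compare_windows(
    mags_a: np.ndarray,
    mags_b: np.ndarray,
    location_ids: list[str],
    sig_a: np.ndarray | None = None,
    sig_b: np.ndarray | None = None,
    alpha: float = 0.01,
) -> PatternComparison:
    """Test per-location pattern differences between windows A and B.

    mags_a/mags_b are (participants, locations) first-level correlation
    magnitudes (|beta| from the window-aggregated fits).  Sensor-level use
    passes no significance masks: normalization runs over all locations and
    all locations are tested.  Source-level use passes per-window masks:
    normalization parameters come only from each window's significant
    locations and only the union enters the test.
    """
    A = np.asarray(mags_a, dtype=float)
    B = np.asarray(mags_b, dtype=float)
    if A.shape != B.shape:
        raise ValueError("window magnitude arrays must have equal shape")
    n_part, n_loc = A.shape
    if len(location_ids) != n_loc:
        raise ValueError("location_ids length mismatch")
    if (sig_a is None) != (sig_b is None):
        raise ValueError("pass both significance masks or neither")
    if sig_a is None:
        subset_a = subset_b = np.arange(n_loc)
        tested = np.ones(n_loc, dtype=bool)
    else:
        sig_a = np.asarray(sig_a, dtype=bool)
        sig_b = np.asarray(sig_b, dtype=bool)
        tested = sig_a | sig_b
        if not tested.any():
            raise ValueError("no location significant in either window")
        subset_a, subset_b = np.nonzero(sig_a)[0], np.nonzero(sig_b)[0]

    norm_a = np.stack([normalize_pattern(A[i], subset_a)
                       for i in range(n_part)])
    norm_b = np.stack([normalize_pattern(B[i], subset_b)
                       for i in range(n_part)])
    diff = norm_b - norm_a

    t = np.zeros(n_loc)
    p = np.ones(n_loc)
    for c in np.nonzero(tested)[0]:
        d = diff[:, c]
        sd = d.std(ddof=1)
        if sd == 0:
            t[c] = 0.0 if d.mean() == 0 else np.sign(d.mean()) * np.inf
            p[c] = 1.0 if d.mean() == 0 else 0.0
        else:
            t[c], p[c] = stats.ttest_1samp(d, 0.0)
    sig = np.zeros(n_loc, dtype=bool)
    p_masked = np.where(tested, p, np.nan)
    sig = fdr_correct(p_masked, alpha)
    return PatternComparison(
        list(location_ids), norm_a.mean(axis=0), norm_b.mean(axis=0),
        diff.mean(axis=0), t, p, sig, alpha, tested)
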