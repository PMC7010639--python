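"""Basic topography and time-course plots."""

from __future__ import annotations

import numpy as np
import pandas as pd


def plot_topography(values, layout: pd.DataFrame, ax=None, cmap="RdBu_r",
                    vlim: float | None = None):
    """Scatter-style sensor topography on a 2D layout (id, x2d, y2d)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(3.2, 3.2))
    values = np.asarray(values, dtype=float)
    if vlim is None:
        vlim = np.nanmax(np.abs(values)) or 1.0
    sc = ax.scatter(layout["x2d"], layout["y2d"], c=values, cmap=cmap,
                    vmin=-vlim, vmax=vlim, s=60, edgecolors="k",
                    linewidths=0.3)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.figure.colorbar(sc, ax=ax, shrink=0.7)
    return ax


def plot_magnitude_timecourse(times_ms, traces: dict, ax=None,
                              ylabel="mean |grand-average beta|"):
    """Overlay named magnitude time courses (e.g. observed vs. permuted)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    for label, trace in traces.items():
        style = "--" if "perm" in label.lower() else "-"
        ax.plot(times_ms, trace, style, label=label)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel(ylabel)
    ax.legend(frameon=False, fontsize=8)
    return ax
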