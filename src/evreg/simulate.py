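"""Synthetic multi-participant signal tensors with known embedded effects.

The generator produces MEG-like sensor (or area-level) time series at 100 Hz
in which chosen regressors — momentary evidence, y-coordinate, accumulated
evidence, or the trial's choice — have linear, lag-specific correlates with a
known channel topography, on top of white noise and a condition-independent
evoked template.  Because ground truth is known, every downstream stage
(design construction, first-level OLS, group statistics, pattern comparison)
can be validated for recovery, specificity and calibration.

Not emulated: realistic MEG noise spectra, sensor types beyond a single
grid, head movement, artifacts, or source mixing; "source-level" inputs are
simply tensors whose channel axis is labeled with parcellation areas.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd

from .observer import TrialOutcome, evidence_series, simulate_outcomes
from .stimulus import DOT_DURATION_MS, TIMEOUT_MS, StimulusSet, build_stimulus_set

DEFAULT_SAMPLE_MS = 10
DEFAULT_TMIN_MS = -300
DEFAULT_TMAX_MS = 2500
DEFAULT_N_CHANNELS = 102  # magnetometer grid
N_AREAS = 362             # 180 parcellation areas + 1 unassigned, per hemisphere

#: regressors defined per (trial, dot)
DOT_REGRESSORS = (
    "x", "y", "abs_x", "abs_y", "update_x", "update_y",
    "accum_x", "accum_y", "accum_prev_x", "accum_prev_y",
)
#: regressors defined per trial
TRIAL_REGRESSORS = ("choice",)


@dataclass
class SignalTensor:
    """One participant's signals: trials x channels x samples at 10 ms."""

    participant_id: int | str
    data: np.ndarray
    times_ms: np.ndarray
    channel_ids: list[str]
    sample_ms: int = DEFAULT_SAMPLE_MS
    baseline_span: tuple[int, int] = (DEFAULT_TMIN_MS, 0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.times_ms = np.asarray(self.times_ms)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if self.data.shape[2] != self.times_ms.size:
            raise ValueError("times_ms length must match the sample axis")
        if np.isnan(self.data).any():
            raise ValueError("signal tensor contains missing values")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def t0_index(self) -> int:
        return self.sample_index(0)

    def sample_index(self, t_ms: float) -> int:
        """Index of the sample at time t_ms (must lie on the grid)."""
        idx = np.nonzero(self.times_ms == int(round(t_ms)))[0]
        if idx.size == 0:
            raise ValueError(f"time {t_ms} ms is not on the sampled grid")
        return int(idx[0])

    def baseline_correct(self) -> "SignalTensor":
        """Subtract each trial/channel's mean over the baseline window."""
        lo, hi = self.baseline_span
        win = (self.times_ms >= lo) & (self.times_ms < hi)
        if not win.any():
            raise ValueError("baseline window not covered by the time axis")
        base = self.data[:, :, win].mean(axis=2, keepdims=True)
        return replace(self, data=self.data - base)

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.create_dataset("time_ms", data=self.times_ms)
            f.create_dataset("channel_ids",
                             data=np.array(self.channel_ids, dtype="S"))
            f.attrs["participant_id"] = str(self.participant_id)
            f.attrs["sample_ms"] = self.sample_ms
            f.attrs["baseline_span"] = self.baseline_span

    @classmethod
    def from_hdf5(cls, path) -> "SignalTensor":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                participant_id=f.attrs["participant_id"],
                data=f["data"][()],
                times_ms=f["time_ms"][()],
                channel_ids=[c.decode() for c in f["channel_ids"][()]],
                sample_ms=int(f.attrs["sample_ms"]),
                baseline_span=tuple(f.attrs["baseline_span"]),
            )


@dataclass
class EffectSpec:
    """A ground-truth linear correlate to embed in the simulated signal.

    For dot-aligned regressors the effect follows the dot's display window
    shifted by lag_ms (duration_ms None), or a boxcar of duration_ms from
    onset + lag_ms; for the trial-level choice regressor it is a boxcar of
    duration_ms starting lag_ms from the response.
    """

    regressor: str
    lag_ms: int
    weights: np.ndarray       # per-channel topography, unitless
    amplitude: float          # signal units per z-scored regressor unit
    align: str = "dot"        # "dot" or "response"
    duration_ms: int | None = None   # None: dot display duration (100 ms)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.lag_ms % DEFAULT_SAMPLE_MS != 0:
            raise ValueError(f"lag_ms must be a multiple of "
                             f"{DEFAULT_SAMPLE_MS} ms, got {self.lag_ms}")
        if self.align == "dot" and self.regressor not in DOT_REGRESSORS:
            raise ValueError(f"unknown dot-aligned regressor {self.regressor!r}")
        if self.align == "response" and self.regressor not in TRIAL_REGRESSORS:
            raise ValueError(
                f"unknown response-aligned regressor {self.regressor!r}")
        if self.align not in ("dot", "response"):
            raise ValueError(f"align must be 'dot' or 'response', got {self.align!r}")


def amplitude_for_correlation(r: float, noise_sd: float = 1.0) -> float:
    """Amplitude giving theoretical signal/regressor correlation r.

    With signal = a * z + noise, corr(signal, z) = a / sqrt(a^2 + noise^2),
    so a = noise * r / sqrt(1 - r^2).
    """
    if not 0 <= r < 1:
        raise ValueError(f"r must be in [0, 1), got {r}")
    return noise_sd * r / np.sqrt(1.0 - r**2)


def regressor_matrix(name: str, stimuli: StimulusSet) -> np.ndarray:
    """(n_trials, n_dots) values of a dot-level regressor."""
    x = stimuli.coordinate_matrix("x")
    y = stimuli.coordinate_matrix("y")
    if name == "x":
        return x
    if name == "y":
        return y
    if name == "abs_x":
        return np.abs(x)
    if name == "abs_y":
        return np.abs(y)
    if name == "update_x":
        # previous position of dot 1 taken as screen center
        return np.abs(np.diff(np.concatenate(
            [np.zeros((x.shape[0], 1)), x], axis=1), axis=1))
    if name == "update_y":
        return np.abs(np.diff(np.concatenate(
            [np.zeros((y.shape[0], 1)), y], axis=1), axis=1))
    if name == "accum_x":
        return np.cumsum(x, axis=1)
    if name == "accum_y":
        return np.cumsum(y, axis=1)
    if name == "accum_prev_x":
        acc = np.cumsum(x, axis=1)
        return np.concatenate([np.zeros((x.shape[0], 1)), acc[:, :-1]], axis=1)
    if name == "accum_prev_y":
        acc = np.cumsum(y, axis=1)
        return np.concatenate([np.zeros((y.shape[0], 1)), acc[:, :-1]], axis=1)
    raise ValueError(f"unknown dot-level regressor {name!r}")


def _pool_zscore(values: np.ndarray) -> np.ndarray:
    sd = values.std()
    if sd == 0:
        raise ValueError("regressor has zero variance over the pool")
    return (values - values.mean()) / sd


def _evoked_template(times_ms: np.ndarray, amplitude: float) -> np.ndarray:
    """Damped oscillation starting at first dot onset, zero before."""
    t = np.clip(times_ms, 0, None) / 1000.0
    e = amplitude * np.exp(-t / 0.3) * np.sin(2 * np.pi * 3.0 * t)
    e[times_ms < 0] = 0.0
    return e


def simulate_session(
    stimuli: StimulusSet,
    outcomes: list[TrialOutcome],
    effects: list[EffectSpec],
    noise_sd: float = 1.0,
    rng: np.random.Generator | int | None = None,
    n_channels: int = DEFAULT_N_CHANNELS,
    participant_id: int | str = 0,
    evoked_amplitude: float = 1.0,
    tmin_ms: int = DEFAULT_TMIN_MS,
    tmax_ms: int = DEFAULT_TMAX_MS,
    dtype=np.float64,
) -> SignalTensor:
    """Simulate one participant's signal tensor with embedded effects.

    data(trial, c, t) = sum_effects weight(c) * amplitude(participant)
                        * z(regressor value of the dot active at t - lag)
                        + evoked template + Normal(0, noise_sd),
    where dots contribute only while displayed and before the response, and
    choice effects only around the response of non-timeout trials.
    """
    if len(outcomes) != stimuli.n_trials:
        raise ValueError("need exactly one outcome per trial")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    elif rng is None:
        rng = np.random.default_rng()

    times = np.arange(tmin_ms, tmax_ms + DEFAULT_SAMPLE_MS, DEFAULT_SAMPLE_MS)
    n_trials, n_samples = stimuli.n_trials, times.size
    data = rng.normal(0.0, noise_sd,
                      size=(n_trials, n_channels, n_samples)).astype(dtype)
    data += _evoked_template(times, evoked_amplitude)[None, None, :]

    rt = np.array([TIMEOUT_MS if o.timed_out else o.rt_ms for o in outcomes])
    d = stimuli.dot_duration_ms
    n_dots = stimuli.sequences[0].n_dots
    for eff in effects:
        if eff.weights.size != n_channels:
            raise ValueError("effect weight map must cover all channels")
        if eff.align == "dot":
            z = _pool_zscore(regressor_matrix(eff.regressor, stimuli))
            for k in range(n_dots):
                onset = k * d
                shown = onset < rt           # dot reached before the response
                if not shown.any():
                    break
                # effect window shifted by the lag, truncated at the
                # response for trials that responded mid-dot
                dur = d if eff.duration_ms is None else eff.duration_ms
                t_start = onset + eff.lag_ms
                stop = np.minimum(onset + dur, rt) + eff.lag_ms
                for i in np.nonzero(shown)[0]:
                    sel = (times >= t_start) & (times < stop[i])
                    if sel.any():
                        data[i, :, sel] += eff.weights * eff.amplitude * z[i, k]
        else:  # response-aligned choice effect
            responded = np.array([not o.timed_out for o in outcomes])
            if not responded.any():
                continue
            choice = np.array([o.choice for o in outcomes], dtype=float)
            zc = np.zeros(n_trials)
            zc[responded] = _pool_zscore(choice[responded])
            dur = DOT_DURATION_MS if eff.duration_ms is None else eff.duration_ms
            for i in np.nonzero(responded)[0]:
                t_start = rt[i] + eff.lag_ms
                sel = (times >= t_start) & (times < t_start + dur)
                if sel.any():
                    data[i, :, sel] += eff.weights * eff.amplitude * zc[i]

    channel_ids = [f"MAG{c:03d}" for c in range(n_channels)]
    return SignalTensor(participant_id, data, times, channel_ids)


@dataclass
class Cohort:
    """A multi-participant synthetic dataset sharing one stimulus set."""

    stimuli: StimulusSet
    outcomes: list[list[TrialOutcome]]
    tensors: list[SignalTensor]

    @property
    def n_participants(self) -> int:
        return len(self.tensors)


def generate_cohort(
    n_participants: int,
    between_sd: float,
    template: list[EffectSpec],
    seed: int,
    stimuli: StimulusSet | None = None,
    noise_sd: float = 1.0,
    n_channels: int = DEFAULT_N_CHANNELS,
    evoked_amplitude: float = 1.0,
    **session_kwargs,
) -> Cohort:
    """Simulate a cohort with participant-varying effect amplitudes.

    Each participant's effect amplitudes are drawn Normal(template
    amplitude, between_sd); behavior and signal noise use child seeds spawned
    deterministically from the cohort seed.
    """
    if n_participants < 2:
        raise ValueError("a cohort needs at least 2 participants")
    ss = np.random.SeedSequence(seed)
    if stimuli is None:
        stimuli = build_stimulus_set(rng=np.random.default_rng(ss.spawn(1)[0]))
    children = ss.spawn(n_participants)
    outcomes_all, tensors = [], []
    for p, child in enumerate(children):
        rng = np.random.default_rng(child)
        outcomes = simulate_outcomes(stimuli, rng=rng)
        effects = [
            replace(e, amplitude=float(rng.normal(e.amplitude, between_sd)))
            for e in template
        ]
        tensor = simulate_session(
            stimuli, outcomes, effects, noise_sd=noise_sd, rng=rng,
            n_channels=n_channels, participant_id=p,
            evoked_amplitude=evoked_amplitude, **session_kwargs)
        outcomes_all.append(outcomes)
        tensors.append(tensor)
    return Cohort(stimuli, outcomes_all, tensors)


def load_channel_layout() -> pd.DataFrame:
    """Synthetic 2D sensor layout fixture (id, x2d, y2d) for topographies."""
    path = resources.files("evreg.data") / "channel_layout_synthetic.tsv"
    return pd.read_csv(path, sep="\t", comment="#")


def load_parcellation() -> pd.DataFrame:
    """Parcellation label fixture: 180 areas + 1 unassigned per hemisphere."""
    path = resources.files("evreg.data") / "parcellation_synthetic.tsv"
    return pd.read_csv(path, sep="\t", comment="#")


def make_channel_layout(n_channels: int = DEFAULT_N_CHANNELS) -> pd.DataFrame:
    """Concentric-ring sensor positions on the unit disc (synthetic)."""
    rows = []
    ring_sizes = []
    remaining = n_channels
    ring = 1
    while remaining > 0:
        size = min(remaining, 6 * ring)
        ring_sizes.append(size)
        remaining -= size
        ring += 1
    c = 0
    for r, size in enumerate(ring_sizes, start=1):
        radius = r / len(ring_sizes)
        for j in range(size):
            ang = 2 * np.pi * j / size
            rows.append((f"MAG{c:03d}", radius * np.cos(ang),
                         radius * np.sin(ang)))
            c += 1
    return pd.DataFrame(rows, columns=["id", "x2d", "y2d"])


def make_parcellation(n_areas_per_hemi: int = 180) -> pd.DataFrame:
    """Generic area labels: A001..A180 plus one unassigned, per hemisphere."""
    rows = []
    for hemi in ("L", "R"):
        for a in range(1, n_areas_per_hemi + 1):
            rows.append((f"{hemi}_A{a:03d}", hemi))
        rows.append((f"{hemi}_unassigned", hemi))
    return pd.DataFrame(rows, columns=["area", "hemisphere"])
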