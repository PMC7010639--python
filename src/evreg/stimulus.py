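"""Stimulus construction for the single-dot evidence task.

Each trial presents a sequence of up to 25 dot positions, one every 100 ms,
drawn from a 2D Gaussian centered on one of two lateral targets at
(±25, 0) px with SD 70 px on both axes.  The experimental set is built from
a small number of base sequences: each base is expanded into six variants
that differ only in the x-coordinate of the fifth dot (±160, ±96, ±32 px),
easy short-RT catch sequences are added, and the whole set is duplicated by
mirroring every x-coordinate so the set is balanced across left/right
responses.  Presentation order is a seeded constrained shuffle that
interleaves catch trials with the variant trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: x-values (px) taken by dot 5 across the six variants of a base sequence
FIFTH_DOT_VALUES = (-160.0, -96.0, -32.0, 32.0, 96.0, 160.0)

DEFAULT_N_DOTS = 25
DEFAULT_MEAN_PX = 25.0
DEFAULT_SD_PX = 70.0
DOT_DURATION_MS = 100
TIMEOUT_MS = 2500


@dataclass
class DotSequence:
    """One trial's stimulus: per-dot pixel offsets from screen center.

    x is rightward-positive, y upward-positive; dot indices are 1-based in
    documentation and 0-based in the arrays.
    """

    trial_id: int
    target: int                      # -1 left, +1 right
    x: np.ndarray                    # (n_dots,) signed horizontal offsets, px
    y: np.ndarray                    # (n_dots,) signed vertical offsets, px
    is_catch: bool = False
    variant_value: float | None = None  # fifth-dot x value, None for catch/base
    mirrored: bool = False
    base_id: int = -1                # index of the originating base sequence

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")

    @property
    def n_dots(self) -> int:
        return self.x.size


@dataclass
class StimulusSet:
    """An ordered collection of dot sequences forming one session."""

    sequences: list[DotSequence]
    order_seed: int | None = None
    dot_duration_ms: int = DOT_DURATION_MS
    timeout_ms: int = TIMEOUT_MS

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def n_trials(self) -> int:
        return len(self.sequences)

    def coordinate_matrix(self, coordinate: str = "x") -> np.ndarray:
        """(n_trials, n_dots) matrix of one coordinate across trials."""
        if coordinate not in ("x", "y"):
            raise ValueError(f"coordinate must be 'x' or 'y', got {coordinate!r}")
        return np.stack([getattr(s, coordinate) for s in self.sequences])

    def to_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-(trial, dot) table for TSV export."""
        records = []
        for seq in self.sequences:
            for k in range(seq.n_dots):
                records.append(
                    (seq.trial_id, k + 1, seq.x[k], seq.y[k], seq.target,
                     seq.is_catch, seq.mirrored)
                )
        return pd.DataFrame(
            records,
            columns=["trial_id", "dot_index", "x_px", "y_px", "target",
                     "is_catch", "mirrored"],
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("x", data=self.coordinate_matrix("x"))
            f.create_dataset("y", data=self.coordinate_matrix("y"))
            f.create_dataset("trial_id", data=[s.trial_id for s in self.sequences])
            f.create_dataset("target", data=[s.target for s in self.sequences])
            f.create_dataset("is_catch", data=[s.is_catch for s in self.sequences])
            f.create_dataset("mirrored", data=[s.mirrored for s in self.sequences])
            f.attrs["dot_duration_ms"] = self.dot_duration_ms
            f.attrs["timeout_ms"] = self.timeout_ms
            if self.order_seed is not None:
                f.attrs["order_seed"] = self.order_seed

    @classmethod
    def from_hdf5(cls, path) -> "StimulusSet":
        import h5py

        with h5py.File(path, "r") as f:
            x = f["x"][()]
            y = f["y"][()]
            trial_id = f["trial_id"][()]
            target = f["target"][()]
            is_catch = f["is_catch"][()]
            mirrored = f["mirrored"][()]
            seqs = [
                DotSequence(int(trial_id[i]), int(target[i]), x[i], y[i],
                            is_catch=bool(is_catch[i]), mirrored=bool(mirrored[i]))
                for i in range(x.shape[0])
            ]
            return cls(
                seqs,
                order_seed=int(f.attrs["order_seed"]) if "order_seed" in f.attrs else None,
                dot_duration_ms=int(f.attrs["dot_duration_ms"]),
                timeout_ms=int(f.attrs["timeout_ms"]),
            )


def sample_dot_sequence(
    target: int,
    n_dots: int = DEFAULT_N_DOTS,
    mean_px: float = DEFAULT_MEAN_PX,
    sd_px: float = DEFAULT_SD_PX,
    rng: np.random.Generator | None = None,
    trial_id: int = 0,
    is_catch: bool = False,
) -> DotSequence:
    """Draw one dot sequence from the task's generative 2D Gaussian.

    x[k] ~ Normal(target * mean_px, sd_px) and y[k] ~ Normal(0, sd_px),
    independently across dots and axes.
    """
    if target not in (-1, 1):
        raise ValueError(f"target must be -1 or +1, got {target}")
    if n_dots < 1:
        raise ValueError(f"n_dots must be >= 1, got {n_dots}")
    if sd_px < 0:
        raise ValueError(f"sd_px must be >= 0, got {sd_px}")
    rng = np.random.default_rng() if rng is None else rng
    x = rng.normal(target * mean_px, sd_px, size=n_dots)
    y = rng.normal(0.0, sd_px, size=n_dots)
    return DotSequence(trial_id, target, x, y, is_catch=is_catch)


def apply_fifth_dot_variants(base: DotSequence) -> list[DotSequence]:
    """Expand a base sequence into its six fifth-dot variants.

    Variant i sets the x-coordinate of dot 5 to FIFTH_DOT_VALUES[i]; every
    other coordinate is identical to the base.
    """
    if base.n_dots < 5:
        raise ValueError(
            f"base sequence must have at least 5 dots, got {base.n_dots}"
        )
    variants = []
    for value in FIFTH_DOT_VALUES:
        x = base.x.copy()
        x[4] = value
        variants.append(
            replace(base, x=x, y=base.y.copy(), variant_value=value)
        )
    return variants


def mirror_sequence(seq: DotSequence) -> DotSequence:
    """Negate every x-coordinate, leave y unchanged, toggle the mirror flag."""
    return replace(
        seq,
        x=-seq.x,
        y=seq.y.copy(),
        target=-seq.target,
        variant_value=None if seq.variant_value is None else -seq.variant_value,
        mirrored=not seq.mirrored,
    )


def _constrained_order(is_special: np.ndarray, rng: np.random.Generator,
                       max_run: int = 4) -> np.ndarray:
    """Permutation of indices with no run of > max_run special trials.

    "Special" marks the long-RT-derived variant trials; forbidding long runs
    of them keeps catch trials interleaved throughout the session.  The
    catch trials partition the order into gaps of capacity max_run; each
    special trial is placed into a uniformly chosen gap with room left.
    Degenerate sets for which the constraint is infeasible fall back to a
    plain shuffle.
    """
    n = is_special.size
    special = rng.permutation(np.nonzero(is_special)[0])
    catch = rng.permutation(np.nonzero(~is_special)[0])
    if special.size > max_run * (catch.size + 1):
        return rng.permutation(n)
    capacity = np.full(catch.size + 1, max_run)
    gaps: list[list[int]] = [[] for _ in range(catch.size + 1)]
    for idx in special:
        open_gaps = np.nonzero(capacity > 0)[0]
        g = int(open_gaps[rng.integers(open_gaps.size)])
        gaps[g].append(int(idx))
        capacity[g] -= 1
    order = []
    for g, items in enumerate(gaps):
        order.extend(items)
        if g < catch.size:
            order.append(int(catch[g]))
    return np.array(order)


def build_stimulus_set(
    n_long: int = 28,
    n_catch: int = 72,
    rng: np.random.Generator | int | None = None,
    n_dots: int = DEFAULT_N_DOTS,
    mean_px: float = DEFAULT_MEAN_PX,
    sd_px: float = DEFAULT_SD_PX,
) -> StimulusSet:
    """Build the full session stimulus set.

    n_long base sequences are expanded into 6 fifth-dot variants each,
    n_catch catch sequences are added, the resulting set is duplicated by
    mirroring, and the presentation order is a seeded constrained shuffle.
    Defaults (28, 72) give 2*(28*6 + 72) = 480 trials.
    """
    if n_long < 1:
        raise ValueError(f"n_long must be >= 1, got {n_long}")
    if n_catch < 0:
        raise ValueError(f"n_catch must be >= 0, got {n_catch}")
    seed = None
    if isinstance(rng, (int, np.integer)):
        seed = int(rng)
        rng = np.random.default_rng(seed)
    elif rng is None:
        rng = np.random.default_rng()

    pre_mirror: list[DotSequence] = []
    for b in range(n_long):
        target = 1 if rng.random() < 0.5 else -1
        base = sample_dot_sequence(target, n_dots, mean_px, sd_px, rng)
        base.base_id = b
        pre_mirror.extend(apply_fifth_dot_variants(base))
    for c in range(n_catch):
        target = 1 if rng.random() < 0.5 else -1
        seq = sample_dot_sequence(target, n_dots, mean_px, sd_px, rng,
                                  is_catch=True)
        seq.base_id = n_long + c
        pre_mirror.append(seq)

    full = pre_mirror + [mirror_sequence(s) for s in pre_mirror]
    is_special = np.array([not s.is_catch for s in full])
    order = (_constrained_order(is_special, rng) if n_catch > 0
             else rng.permutation(len(full)))
    ordered = [full[i] for i in order]
    for i, seq in enumerate(ordered):
        seq.trial_id = i
    return StimulusSet(ordered, order_seed=seed)
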