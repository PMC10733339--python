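"""Supervised dataset construction, seeded splitting and normalization.

The network learns the map x -> (u, f, m) from samples taken at every grid
point of a reference trajectory.  Samples are assigned at random (seeded)
to training / validation / test subsets in the 75 / 13 / 12 ratio, with
non-integer counts resolved by largest-remainder apportionment.  Inputs
and targets are affinely mapped to [-1, 1] per channel for training only;
all reported metrics are in original units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import Trajectory

__all__ = [
    "Dataset",
    "SplitAssignment",
    "Normalizer",
    "build_dataset",
    "split_dataset",
    "fit_normalizer",
    "DEFAULT_RATIOS",
]

DEFAULT_RATIOS = (0.75, 0.13, 0.12)
SPLIT_LABELS = ("train", "val", "test")


@dataclass
class Dataset:
    """Input/target samples for supervised training.

    ``inputs`` has shape (n,), ``targets`` shape (n, 3) with columns
    (u, f, m).
    """

    inputs: np.ndarray
    targets: np.ndarray
    source: str = "adams"

    def __post_init__(self) -> None:
        self.inputs = np.asarray(self.inputs, dtype=float)
        self.targets = np.asarray(self.targets, dtype=float)
        if self.inputs.ndim != 1 or self.inputs.size == 0:
            raise ValueError("inputs must be a non-empty vector")
        if self.targets.shape != (self.inputs.size, 3):
            raise ValueError("targets must have shape (n, 3) matching inputs")

    def __len__(self) -> int:
        return self.inputs.size

    def to_frame(self, split: "SplitAssignment | None" = None):
        """DataFrame with columns x, u, f, m and, given a split, the labels."""
        import pandas as pd

        df = pd.DataFrame(
            {
                "x": self.inputs,
                "u": self.targets[:, 0],
                "f": self.targets[:, 1],
                "m": self.targets[:, 2],
            }
        )
        if split is not None:
            df["split"] = split.labels
        return df

    def to_csv(self, path, split: "SplitAssignment | None" = None) -> None:
        self.to_frame(split).to_csv(path, index=False, float_format="%.17g")


@dataclass
class SplitAssignment:
    """Per-sample split labels and the seed that produced them."""

    labels: np.ndarray  # array of "train"/"val"/"test"
    seed: int
    ratios: tuple = DEFAULT_RATIOS

    def indices(self, label: str) -> np.ndarray:
        if label not in SPLIT_LABELS:
            raise ValueError(f"unknown split label {label!r}")
        return np.flatnonzero(self.labels == label)

    @property
    def counts(self) -> dict:
        return {lab: int(np.sum(self.labels == lab)) for lab in SPLIT_LABELS}


def build_dataset(traj: Trajectory) -> Dataset:
    """One sample per grid point; targets copied verbatim from the trajectory."""
    if len(traj) == 0:
        raise ValueError("trajectory is empty")
    return Dataset(
        inputs=traj.xs.copy(), targets=traj.states.copy(), source=traj.provenance
    )


def _apportion(n: int, ratios) -> np.ndarray:
    """Largest-remainder apportionment of n samples to the ratios."""
    quotas = n * np.asarray(ratios, dtype=float)
    counts = np.floor(quotas).astype(int)
    short = n - counts.sum()
    # hand leftover samples to the largest fractional remainders, ties by
    # position (train first) for determinism
    order = np.argsort(-(quotas - counts), kind="stable")
    counts[order[:short]] += 1
    return counts


def split_dataset(ds: Dataset, ratios=DEFAULT_RATIOS, seed: int = 0) -> SplitAssignment:
    """Seeded uniform random train/val/test assignment without replacement.

    Counts follow largest-remainder apportionment of the ratios; e.g. the
    default 101-point dataset with ratios (0.75, 0.13, 0.12) splits into
    76 / 13 / 12 samples.
    """
    ratios = tuple(float(r) for r in ratios)
    if len(ratios) != 3 or any(r <= 0 for r in ratios):
        raise ValueError("ratios must be three positive fractions")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {sum(ratios)}")
    n = len(ds)
    counts = _apportion(n, ratios)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    labels = np.empty(n, dtype=object)
    start = 0
    for lab, c in zip(SPLIT_LABELS, counts):
        labels[perm[start : start + c]] = lab
        start += c
    return SplitAssignment(labels=labels, seed=seed, ratios=ratios)


@dataclass
class Normalizer:
    """Per-channel affine map to [-1, 1] and its exact inverse.

    Fitted on the full dataset (inputs and the three target channels);
    ``invert(apply(v)) == v`` to within 1e-14.
    """

    lo: np.ndarray
    hi: np.ndarray

    def apply(self, v: np.ndarray) -> np.ndarray:
        return 2.0 * (np.asarray(v, dtype=float) - self.lo) / (self.hi - self.lo) - 1.0

    def invert(self, v: np.ndarray) -> np.ndarray:
        return (np.asarray(v, dtype=float) + 1.0) * (self.hi - self.lo) / 2.0 + self.lo


def fit_normalizer(values: np.ndarray, names=None) -> Normalizer:
    """Fit a [-1, 1] min-max map per channel of a (n,) or (n, c) array."""
    v = np.asarray(values, dtype=float)
    if v.ndim == 1:
        v = v[:, None]
    lo, hi = v.min(axis=0), v.max(axis=0)
    flat = np.isclose(hi, lo)
    if np.any(flat):
        names = names or [f"channel {i}" for i in range(v.shape[1])]
        bad = [names[i] for i in np.flatnonzero(flat)]
        raise ValueError(f"constant channel(s) cannot be normalized: {bad}")
    if values.ndim == 1:
        return Normalizer(lo=lo[0], hi=hi[0])
    return Normalizer(lo=lo, hi=hi)
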