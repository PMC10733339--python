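"""Evaluation surfaces for the trained surrogate.

Reproduces the standard neural-fitting diagnostics: per-split MSE,
per-compartment absolute-error (AE) curves over the full grid, a 20-bin
histogram of pooled signed errors (target - output convention), and
ordinary-least-squares regression of outputs on targets with the Pearson
R and determination coefficient R^2, per compartment and pooled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from .model import Trajectory

__all__ = [
    "absolute_error",
    "error_histogram",
    "regression_metrics",
    "EvaluationReport",
]

CLASS_NAMES = ("u", "f", "m")


def absolute_error(pred: Trajectory, ref: Trajectory) -> dict[str, np.ndarray]:
    """Pointwise |pred - ref| per compartment; trajectories must share a grid."""
    if len(pred) != len(ref) or not np.allclose(pred.xs, ref.xs, rtol=0, atol=1e-12):
        raise ValueError("trajectories are on different grids")
    ae = np.abs(pred.states - ref.states)
    return {name: ae[:, i] for i, name in enumerate(CLASS_NAMES)}


def error_histogram(errors: np.ndarray, n_bins: int = 20) -> dict:
    """Equal-width histogram of pooled signed errors.

    Returns bin edges, counts (summing to the sample count) and the centre
    of the bin closest to zero error — the "zero error" marker of the
    standard fitting-tool histogram panel.
    """
    errors = np.asarray(errors, dtype=float).ravel()
    if errors.size == 0:
        raise ValueError("no errors to histogram")
    lo, hi = errors.min(), errors.max()
    if lo == hi:  # all errors identical: one occupied bin around the value
        lo, hi = lo - 0.5, hi + 0.5
    counts, edges = np.histogram(errors, bins=n_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    zero_bin = int(np.argmin(np.abs(centers)))
    return {
        "bin_edges": edges,
        "counts": counts,
        "bin_centers": centers,
        "zero_error_bin_center": float(centers[zero_bin]),
    }


def _regress(outputs: np.ndarray, targets: np.ndarray) -> dict:
    if targets.size < 2:
        raise ValueError("need at least 2 samples for regression")
    if np.var(targets) == 0:
        return {"slope": np.nan, "intercept": np.nan, "r": np.nan, "r2": np.nan}
    res = stats.linregress(targets, outputs)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r": float(res.rvalue),
        "r2": float(res.rvalue**2),
    }


def regression_metrics(outputs: np.ndarray, targets: np.ndarray) -> dict:
    """OLS fit of output vs target per compartment and pooled.

    A compartment with zero target variance yields NaN metrics rather than
    an exception (undefined correlation).
    """
    outputs = np.atleast_2d(np.asarray(outputs, dtype=float))
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    if outputs.shape != targets.shape:
        raise ValueError("outputs and targets must have matching shapes")
    out = {}
    for i, name in enumerate(CLASS_NAMES[: outputs.shape[1]]):
        out[name] = _regress(outputs[:, i], targets[:, i])
    out["pooled"] = _regress(outputs.ravel(), targets.ravel())
    return out


@dataclass
class EvaluationReport:
    """The full metric bundle for one trained case."""

    case_id: int
    seed: int
    n_restarts: int
    mse: dict  # train/val/test MSE at the returned weights
    best_val_mse: float
    best_val_epoch: int
    final_grad_norm: float
    n_epochs: int
    stop_reason: str
    ae: dict  # per-class AE arrays over the full grid (vs Adams reference)
    ae_max: dict
    ae_mean: dict
    histogram: dict
    regression: dict

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("ae",):
            d[key] = {k: np.asarray(v).tolist() for k, v in d[key].items()}
        d["histogram"] = {
            k: (np.asarray(v).tolist() if isinstance(v, np.ndarray) else v)
            for k, v in d["histogram"].items()
        }
        return d
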