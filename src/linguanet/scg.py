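"""Moller scaled conjugate gradient training with early stopping.

Full-batch, line-search-free conjugate-gradient optimization of the
network weights.  Curvature along the search direction p is estimated by a
one-sided finite difference of the gradient with displacement sigma/|p|
and regularized by a Levenberg-style scale parameter lambda, which grows
when the local quadratic model predicts the loss poorly (comparison ratio
Delta < 0.25) and shrinks when it predicts well (Delta > 0.75).  The
direction restarts to steepest descent every n_params accepted steps.

The optimizer core (``scg_minimize``) is objective-agnostic; ``train``
wraps it with the network loss on the normalized [-1, 1] scale and the
standard stopping rules, checked each epoch: maximum epochs, loss at
goal, gradient norm below min_gradient, or max_val_fail consecutive
epochs without a new best validation MSE.  The weights returned are
always those of the best-validation epoch, not the final one.

MSE traces in the TrainingRecord are reported on the original target
scale; ``train_loss`` and the gradient norm (and the min_gradient
threshold) refer to the normalized training objective actually minimized.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np

from .data import Dataset, SplitAssignment, fit_normalizer
from .network import MLPWeights, NetConfig, forward, init_weights, loss_and_gradient

__all__ = ["SCGConfig", "TrainingRecord", "scg_minimize", "train", "multi_restart"]

_LAMBDA_CAP = 1e15  # guard against stagnation at huge regularization


@dataclass(frozen=True)
class SCGConfig:
    """Optimizer and stopping-rule settings.

    sigma is the second-order estimation step scale and lambda0 the
    initial trust/scale parameter (Moller's published defaults; sigma 7e-5
    is the documented alternative).  min_gradient defaults to 1e-7, the
    tolerance the training is run at; max_val_fail consecutive validation
    failures trigger early stopping.
    """

    sigma: float = 5e-5
    lambda0: float = 5e-7
    max_epochs: int = 1000
    min_gradient: float = 1e-7
    max_val_fail: int = 6
    goal_mse: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.lambda0 <= 0:
            raise ValueError("sigma and lambda0 must be positive")
        if self.max_epochs < 1 or self.min_gradient < 0 or self.max_val_fail < 1:
            raise ValueError("invalid stopping configuration")


@dataclass
class TrainingRecord:
    """Per-epoch traces and the outcome of one training run."""

    train_mse: list = field(default_factory=list)
    val_mse: list = field(default_factory=list)
    test_mse: list = field(default_factory=list)
    train_loss: list = field(default_factory=list)  # normalized objective
    grad_norm: list = field(default_factory=list)
    best_val_epoch: int = 0
    best_val_mse: float = np.inf
    stop_reason: str = ""
    seed: int = 0

    @property
    def n_epochs(self) -> int:
        return len(self.train_mse)

    def to_dict(self) -> dict:
        return asdict(self)


def scg_minimize(
    fun: Callable[[np.ndarray], tuple[float, np.ndarray]],
    x0: np.ndarray,
    scg: SCGConfig,
    callback: Callable[[int, np.ndarray, float, float], str | None] | None = None,
) -> tuple[np.ndarray, float, str]:
    """Moller scaled conjugate gradient on a generic objective.

    ``fun(x)`` returns (value, gradient).  ``callback(epoch, x, value,
    grad_norm)`` runs once per epoch after the step; a non-None return
    value stops the iteration with that string as the stop reason.  Steps
    are only accepted when they do not increase the objective, so the
    value trace over epochs is non-increasing.

    Returns (final x, final value, stop reason).
    """
    x = np.asarray(x0, dtype=float).copy()
    n = x.size
    E, g = fun(x)
    if not np.isfinite(E):
        raise ValueError("objective is non-finite at the initial point")
    r = -g
    p = r.copy()
    lam, lam_bar = scg.lambda0, 0.0
    success = True
    delta = 0.0
    n_accepted = 0
    reason = "max_epochs"

    for epoch in range(1, scg.max_epochs + 1):
        p_norm2 = float(p @ p)
        p_norm = float(np.sqrt(p_norm2))
        if success and p_norm > 0:
            # second-order information along p, one-sided difference
            sigma_k = scg.sigma / p_norm
            _, g_probe = fun(x + sigma_k * p)
            s = (g_probe + r) / sigma_k  # (grad(x+s*p) - grad(x)) / s
            delta = float(p @ s)

        delta_k = delta + (lam - lam_bar) * p_norm2
        if delta_k <= 0 and p_norm2 > 0:
            # make the scaled Hessian estimate positive definite
            lam_bar = 2.0 * (lam - delta_k / p_norm2)
            delta_k = -delta_k + lam * p_norm2
            lam = lam_bar

        mu = float(p @ r)
        alpha = mu / delta_k if delta_k != 0 else 0.0
        x_new = x + alpha * p
        E_new, g_new = fun(x_new)
        if not np.isfinite(E_new):
            reason = "non_finite_loss"
            break
        Delta = 2.0 * delta_k * (E - E_new) / (mu * mu) if mu != 0 else -1.0

        if Delta >= 0:  # successful step
            x, E = x_new, E_new
            r_new = -g_new
            n_accepted += 1
            lam_bar = 0.0
            success = True
            if n_accepted % n == 0:  # periodic restart to steepest descent
                p = r_new.copy()
            else:
                beta = float(r_new @ r_new - r_new @ r) / mu
                p = r_new + beta * p
            r = r_new
            if Delta >= 0.75:
                lam = lam * 0.5
        else:
            lam_bar = lam
            success = False
        if Delta < 0.25:
            lam = min(lam * 4.0, _LAMBDA_CAP)

        grad_norm = float(np.linalg.norm(r))
        stop = callback(epoch, x, E, grad_norm) if callback is not None else None
        if E <= scg.goal_mse:
            reason = "goal"
            break
        if grad_norm <= scg.min_gradient:
            reason = "min_gradient"
            break
        if stop is not None:
            reason = stop
            break

    return x, E, reason


def train(
    config: NetConfig,
    scg: SCGConfig,
    dataset: Dataset,
    split: SplitAssignment,
    seed: int,
) -> tuple[MLPWeights, TrainingRecord]:
    """Run Moller SCG on the network loss from a seeded initialization.

    Returns the weights of the best-validation epoch together with the
    full training record.  Deterministic for fixed (dataset, split, seed).
    """
    x_norm = fit_normalizer(dataset.inputs, names=["x"])
    t_norm = fit_normalizer(dataset.targets, names=["u", "f", "m"])
    xn = x_norm.apply(dataset.inputs)[:, None]
    tn = t_norm.apply(dataset.targets)

    subsets = {}
    for label in ("train", "val", "test"):
        idx = split.indices(label)
        subsets[label] = (xn[idx], tn[idx])
    if subsets["train"][0].size == 0:
        raise ValueError("training split is empty")
    if subsets["val"][0].size == 0:
        raise ValueError("validation split is empty")
    xtr, ttr = subsets["train"]

    # per-channel squared half-ranges, to de-normalize MSE traces
    t_scale2 = ((t_norm.hi - t_norm.lo) / 2.0) ** 2

    weights0 = init_weights(config, seed)
    record = TrainingRecord(seed=seed)
    state = {"best_flat": weights0.flatten(), "val_fail": 0}

    def fun(flat: np.ndarray) -> tuple[float, np.ndarray]:
        return loss_and_gradient(MLPWeights.from_flat(flat, config), xtr, ttr)

    def orig_mse(w: MLPWeights, label: str) -> float:
        xs, ts = subsets[label]
        if xs.size == 0:
            return float("nan")
        return float(np.mean((forward(w, xs) - ts) ** 2 * t_scale2))

    def callback(epoch: int, flat: np.ndarray, E: float, grad_norm: float):
        w = MLPWeights.from_flat(flat, config)
        record.train_loss.append(E)
        record.grad_norm.append(grad_norm)
        record.train_mse.append(orig_mse(w, "train"))
        record.val_mse.append(orig_mse(w, "val"))
        record.test_mse.append(orig_mse(w, "test"))
        v = record.val_mse[-1]
        if v < record.best_val_mse:
            record.best_val_mse = v
            record.best_val_epoch = epoch
            state["best_flat"] = flat.copy()
            state["val_fail"] = 0
        else:
            state["val_fail"] += 1
            if state["val_fail"] >= scg.max_val_fail:
                return "val_fail"
        return None

    _, _, reason = scg_minimize(fun, weights0.flatten(), scg, callback)
    record.stop_reason = reason
    best = MLPWeights.from_flat(state["best_flat"], config)
    return best, record


def multi_restart(
    config: NetConfig,
    scg: SCGConfig,
    dataset: Dataset,
    split: SplitAssignment,
    n_restarts: int,
    base_seed: int,
) -> tuple[MLPWeights, TrainingRecord]:
    """Best of n_restarts seeded runs, selected by best-validation MSE.

    Runs ``train`` with seeds base_seed ... base_seed + n_restarts - 1 and
    returns the run whose best-validation MSE is lowest (ties -> lowest
    seed).  Deterministic given base_seed.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be at least 1")
    best: tuple[MLPWeights, TrainingRecord] | None = None
    for k in range(n_restarts):
        w, rec = train(config, scg, dataset, split, seed=base_seed + k)
        if best is None or rec.best_val_mse < best[1].best_val_mse:
            best = (w, rec)
    return best
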