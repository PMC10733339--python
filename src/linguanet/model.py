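"""Three-compartment language-learning ODE model.

The model tracks the proportions of language knowledge in three states:
``u`` (unknown), ``f`` (familiar) and ``m`` (mastered).  Knowledge moves
unknown -> familiar -> mastered at a learning rate ``alpha`` and decays
back (familiar -> unknown, mastered -> familiar) at rates proportional to
a forgetting constant ``beta``:

    du/dx = beta*f/(1+2*alpha) - alpha*u
    df/dx = -alpha*f - beta*f/(1+2*alpha) + alpha*u + beta*m/(2+4*alpha)
    dm/dx = alpha*f - beta*m/(2+4*alpha)

The system is linear with constant coefficients, so the rate-matrix form
``dy/dx = A y`` admits an exact solution ``y(x) = expm(A x) y(0)``, which
this module provides as the ground-truth oracle for every numerical method
in the package.  Each column of ``A`` sums to zero, so ``u + f + m`` is
conserved along every trajectory; off-diagonal entries are nonnegative
(Metzler structure), so trajectories started on the unit simplex stay in
``[0, 1]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import expm

__all__ = [
    "ModelParams",
    "CompartmentState",
    "Trajectory",
    "make_case",
    "rate_matrix",
    "rhs",
    "analytic_solution",
    "steady_state",
    "CASE_PARAMS",
]

#: The three parameter presets studied in the reference experiments.
CASE_PARAMS = {1: (0.5, 0.1), 2: (0.5, 0.5), 3: (0.5, 0.9)}

#: Default initial proportions: everything starts unknown.
DEFAULT_INIT = (1.0, 0.0, 0.0)


@dataclass(frozen=True)
class ModelParams:
    """Rate constants of the learning model.

    Parameters
    ----------
    alpha : float
        Learning-rate constant in (0, 1); how rapidly new material is
        acquired.
    beta : float
        Forgetting-rate constant in (0, 1); how rapidly proficiency decays.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        for name, v in (("alpha", self.alpha), ("beta", self.beta)):
            if not np.isfinite(v) or not (0.0 < v < 1.0):
                raise ValueError(
                    f"{name} must lie in the open interval (0, 1), got {v!r}"
                )


@dataclass(frozen=True)
class CompartmentState:
    """Proportions (u, f, m) of unknown / familiar / mastered knowledge at x."""

    u: float
    f: float
    m: float
    x: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.u, self.f, self.m)
        if not all(np.isfinite(v) for v in vals) or np.isnan(self.x):
            raise ValueError(f"non-finite compartment state: {vals} at x={self.x}")

    def as_array(self) -> np.ndarray:
        return np.array([self.u, self.f, self.m], dtype=float)

    @property
    def total(self) -> float:
        return self.u + self.f + self.m

    def on_simplex(self, tol: float = 1e-12) -> bool:
        y = self.as_array()
        return bool(abs(self.total - 1.0) <= tol and np.all(y >= -tol) and np.all(y <= 1 + tol))


@dataclass
class Trajectory:
    """A solution sampled on an increasing grid.

    Attributes
    ----------
    xs : ndarray, shape (n,)
        Strictly increasing grid of the independent variable.
    states : ndarray, shape (n, 3)
        (u, f, m) at each grid point.
    provenance : str
        One of ``"analytic"``, ``"adams"``, ``"rk4"`` or ``"surrogate"``.
    """

    xs: np.ndarray
    states: np.ndarray
    provenance: str = "analytic"

    def __post_init__(self) -> None:
        self.xs = np.asarray(self.xs, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.xs.ndim != 1 or self.xs.size == 0:
            raise ValueError("xs must be a non-empty 1-D grid")
        if self.states.shape != (self.xs.size, 3):
            raise ValueError(
                f"states shape {self.states.shape} does not match grid of "
                f"{self.xs.size} points"
            )
        if self.xs.size > 1 and not np.all(np.diff(self.xs) > 0):
            raise ValueError("xs must be strictly increasing")

    def __len__(self) -> int:
        return self.xs.size

    @property
    def u(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def f(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def m(self) -> np.ndarray:
        return self.states[:, 2]

    def conservation_defect(self) -> np.ndarray:
        """|u + f + m - 1| at each grid point."""
        return np.abs(self.states.sum(axis=1) - 1.0)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"x": self.xs, "u": self.u, "f": self.f, "m": self.m})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


def make_case(case_id: int) -> ModelParams:
    """Return the (alpha, beta) preset for one of the three study cases.

    Case 1: (0.5, 0.1); Case 2: (0.5, 0.5); Case 3: (0.5, 0.9).
    """
    try:
        alpha, beta = CASE_PARAMS[case_id]
    except (KeyError, TypeError):
        raise ValueError(f"unknown case id {case_id!r}; expected 1, 2 or 3") from None
    return ModelParams(alpha=alpha, beta=beta)


def rate_matrix(params: ModelParams) -> np.ndarray:
    """Rate matrix A with row order (u, f, m); columns sum exactly to zero."""
    a, b = params.alpha, params.beta
    r_fu = b / (1.0 + 2.0 * a)  # familiar -> unknown forgetting rate
    r_mf = b / (2.0 + 4.0 * a)  # mastered -> familiar forgetting rate
    return np.array(
        [
            [-a, r_fu, 0.0],
            [a, -a - r_fu, r_mf],
            [0.0, a, -r_mf],
        ]
    )


def rhs(params: ModelParams, state: CompartmentState | Sequence[float]) -> np.ndarray:
    """Time derivative (du/dx, df/dx, dm/dx); components sum to zero."""
    if isinstance(state, CompartmentState):
        y = state.as_array()
    else:
        y = np.asarray(state, dtype=float)
        if y.shape != (3,) or not np.all(np.isfinite(y)):
            raise ValueError(f"state must be a finite length-3 vector, got {state!r}")
    return rate_matrix(params) @ y


def analytic_solution(
    params: ModelParams,
    init: CompartmentState | Sequence[float] = DEFAULT_INIT,
    xs: Sequence[float] = (0.0,),
) -> Trajectory:
    """Exact solution y(x) = expm(A*(x - x0)) y0 on the given grid.

    Accurate to better than 1e-12 per component on [0, 1] grids; used as the
    oracle against which the Adams solver and the neural surrogate are judged.
    """
    xs = np.asarray(xs, dtype=float)
    if xs.size == 0:
        raise ValueError("xs must contain at least one point")
    if isinstance(init, CompartmentState):
        x0, y0 = init.x, init.as_array()
    else:
        x0, y0 = xs[0], np.asarray(init, dtype=float)
    A = rate_matrix(params)
    states = np.empty((xs.size, 3))
    for i, x in enumerate(xs):
        states[i] = expm(A * (x - x0)) @ y0
    return Trajectory(xs=xs, states=states, provenance="analytic")


def steady_state(params: ModelParams) -> CompartmentState:
    """Long-run equilibrium: the null-space direction of A normalized to sum 1.

    Detailed balance of the chain u <-> f <-> m gives, with
    ``r_fu = beta/(1+2 alpha)`` and ``r_mf = beta/(2+4 alpha)``:
    ``u* = (r_fu/alpha) f*`` and ``m* = (alpha/r_mf) f*``.
    """
    a, b = params.alpha, params.beta
    r_fu = b / (1.0 + 2.0 * a)
    r_mf = b / (2.0 + 4.0 * a)
    f = 1.0 / (r_fu / a + 1.0 + a / r_mf)
    return CompartmentState(u=r_fu / a * f, f=f, m=a / r_mf * f, x=np.inf)
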