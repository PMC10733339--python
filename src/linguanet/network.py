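"""One-hidden-layer feedforward network with exact backpropagation.

Topology: 1 input -> 12 log-sigmoid hidden units -> 3 linear outputs
(63 free parameters at the defaults).  Weights are initialized with the
Nguyen-Widrow scheme so the hidden sigmoids start spread across the
normalized input range.  The loss is the mean squared error averaged over
samples and output channels, and ``loss_and_gradient`` returns its exact
derivative with respect to the flattened weight vector — verified in the
test suite against central finite differences.
"""

from __future__ import annotations

from dataclasses import dataclass
import json

import numpy as np

__all__ = [
    "NetConfig",
    "MLPWeights",
    "logsig",
    "init_weights",
    "forward",
    "loss_and_gradient",
]


@dataclass(frozen=True)
class NetConfig:
    n_input: int = 1
    n_hidden: int = 12
    n_output: int = 3

    def __post_init__(self) -> None:
        if self.n_hidden < 1 or self.n_input < 1 or self.n_output < 1:
            raise ValueError("layer sizes must be positive")

    @property
    def n_params(self) -> int:
        return self.n_hidden * (self.n_input + 1) + self.n_output * (self.n_hidden + 1)


@dataclass
class MLPWeights:
    """Network parameters with a flat-vector view for the optimizer."""

    w1: np.ndarray  # (n_hidden, n_input)
    b1: np.ndarray  # (n_hidden,)
    w2: np.ndarray  # (n_output, n_hidden)
    b2: np.ndarray  # (n_output,)

    @property
    def config(self) -> NetConfig:
        return NetConfig(self.w1.shape[1], self.w1.shape[0], self.w2.shape[0])

    def flatten(self) -> np.ndarray:
        return np.concatenate(
            [self.w1.ravel(), self.b1.ravel(), self.w2.ravel(), self.b2.ravel()]
        )

    @classmethod
    def from_flat(cls, flat: np.ndarray, config: NetConfig) -> "MLPWeights":
        h, i, o = config.n_hidden, config.n_input, config.n_output
        flat = np.asarray(flat, dtype=float)
        if flat.size != config.n_params:
            raise ValueError(f"expected {config.n_params} parameters, got {flat.size}")
        pos = 0

        def take(shape):
            nonlocal pos
            size = int(np.prod(shape))
            out = flat[pos : pos + size].reshape(shape).copy()
            pos += size
            return out

        return cls(take((h, i)), take((h,)), take((o, h)), take((o,)))

    def copy(self) -> "MLPWeights":
        return MLPWeights(self.w1.copy(), self.b1.copy(), self.w2.copy(), self.b2.copy())

    def to_json(self, path) -> None:
        obj = {k: getattr(self, k).tolist() for k in ("w1", "b1", "w2", "b2")}
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path) -> "MLPWeights":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(**{k: np.asarray(obj[k], dtype=float) for k in ("w1", "b1", "w2", "b2")})


def logsig(z: np.ndarray) -> np.ndarray:
    """Numerically stable log-sigmoid 1/(1+exp(-z)), bounded in (0, 1).

    Branches on the sign of z so exp never overflows, even at |z| ~ 1000.
    """
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def init_weights(config: NetConfig, seed: int) -> MLPWeights:
    """Nguyen-Widrow initialization, deterministic per seed.

    Hidden weights are drawn uniformly then rescaled so every hidden unit's
    incoming weight norm equals 0.7 * n_hidden**(1/n_input) over the
    normalized [-1, 1] input range; hidden biases spread the sigmoid centres
    evenly across that range.  Output-layer weights are small uniform draws.
    """
    rng = np.random.default_rng(seed)
    h, i, o = config.n_hidden, config.n_input, config.n_output
    scale = 0.7 * h ** (1.0 / i)
    w1 = rng.uniform(-1.0, 1.0, size=(h, i))
    norms = np.linalg.norm(w1, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    w1 = scale * w1 / norms
    if h > 1:
        b1 = scale * np.linspace(-1.0, 1.0, h) * np.sign(w1[:, 0])
    else:
        b1 = np.zeros(1)
    w2 = rng.uniform(-0.5, 0.5, size=(o, h))
    b2 = rng.uniform(-0.5, 0.5, size=o)
    return MLPWeights(w1=w1, b1=b1, w2=w2, b2=b2)


def _as_2d(x: np.ndarray, n_cols: int, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None] if n_cols == 1 else x[None, :]
    if x.ndim != 2 or x.shape[1] != n_cols:
        raise ValueError(f"{name} must have {n_cols} column(s), got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite values")
    return x


def forward(weights: MLPWeights, inputs: np.ndarray) -> np.ndarray:
    """Network outputs W2 @ logsig(W1 x + b1) + b2, vectorized over samples."""
    x = _as_2d(inputs, weights.w1.shape[1], "inputs")
    a = logsig(x @ weights.w1.T + weights.b1)
    return a @ weights.w2.T + weights.b2


def loss_and_gradient(
    weights: MLPWeights, inputs: np.ndarray, targets: np.ndarray
) -> tuple[float, np.ndarray]:
    """MSE over samples x channels and its exact gradient (flat vector)."""
    x = _as_2d(inputs, weights.w1.shape[1], "inputs")
    t = _as_2d(targets, weights.w2.shape[0], "targets")
    if t.shape[0] != x.shape[0]:
        raise ValueError("inputs and targets disagree on sample count")
    n, c = t.shape
    a = logsig(x @ weights.w1.T + weights.b1)  # (n, h)
    y = a @ weights.w2.T + weights.b2  # (n, c)
    e = y - t
    mse = float(np.mean(e * e))

    # d mse / d y = 2 e / (n c)
    gy = (2.0 / (n * c)) * e
    gw2 = gy.T @ a
    gb2 = gy.sum(axis=0)
    ga = gy @ weights.w2  # (n, h)
    gz = ga * a * (1.0 - a)  # logsig'(z) = a(1-a)
    gw1 = gz.T @ x
    gb1 = gz.sum(axis=0)
    grad = np.concatenate([gw1.ravel(), gb1, gw2.ravel(), gb2])
    return mse, grad
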