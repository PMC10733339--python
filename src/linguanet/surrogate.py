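"""Model/Results interface tying the pipeline together.

``NeuralSurrogate`` is the user-facing model object: it holds the
supervised dataset (built from an Adams reference trajectory), the split
assignment and the network/optimizer configuration.  ``fit`` runs seeded
multi-restart scaled-conjugate-gradient training and returns a
``SurrogateResults`` carrying the best weights, the training record, a
``predict`` method, the full evaluation report against the reference
solutions, and a ``summary()`` table.

``reproduce_case`` is the one-call end-to-end experiment for a study case:
Adams dataset on [0, 1] with step 0.01 -> 75/13/12 split -> multi-restart
training -> evaluation, with optional CSV/JSON artifact output.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .adams import Grid, solve_adams
from .data import (
    DEFAULT_RATIOS,
    Dataset,
    SplitAssignment,
    build_dataset,
    fit_normalizer,
    split_dataset,
)
from .evaluation import (
    EvaluationReport,
    absolute_error,
    error_histogram,
    regression_metrics,
)
from .model import DEFAULT_INIT, Trajectory, analytic_solution, make_case
from .network import MLPWeights, NetConfig, forward
from .scg import SCGConfig, TrainingRecord, multi_restart

__all__ = ["NeuralSurrogate", "SurrogateResults", "reproduce_case"]


class NeuralSurrogate:
    """Feedforward surrogate of the language-learning ODE solution.

    Parameters
    ----------
    dataset : Dataset
        (x, (u, f, m)) samples, normally from the Adams reference solver.
    split : SplitAssignment, optional
        Train/validation/test labels; built with the default 75/13/12
        ratios and ``split_seed`` when omitted.
    net_config, scg_config : optional
        Network topology (default 1 -> 12 log-sigmoid -> 3 linear) and
        optimizer/stopping settings.
    """

    def __init__(
        self,
        dataset: Dataset,
        split: SplitAssignment | None = None,
        net_config: NetConfig | None = None,
        scg_config: SCGConfig | None = None,
        split_seed: int = 0,
        case_id: int | None = None,
        reference: Trajectory | None = None,
    ) -> None:
        self.dataset = dataset
        self.split = split if split is not None else split_dataset(
            dataset, DEFAULT_RATIOS, seed=split_seed
        )
        self.net_config = net_config or NetConfig()
        self.scg_config = scg_config or SCGConfig()
        self.case_id = case_id
        self.reference = reference
        # normalizers are part of the model: predict() must use the same
        # affine maps the trainer used
        self.x_norm = fit_normalizer(dataset.inputs, names=["x"])
        self.t_norm = fit_normalizer(dataset.targets, names=["u", "f", "m"])

    @classmethod
    def from_case(
        cls,
        case_id: int,
        grid: Grid | None = None,
        split_seed: int = 0,
        split_ratios=DEFAULT_RATIOS,
        net_config: NetConfig | None = None,
        scg_config: SCGConfig | None = None,
    ) -> "NeuralSurrogate":
        """Build the surrogate model for one of the three study cases."""
        grid = grid or Grid()
        params = make_case(case_id)
        ref = solve_adams(params, DEFAULT_INIT, grid)
        ds = build_dataset(ref)
        return cls(
            ds,
            split=split_dataset(ds, split_ratios, seed=split_seed),
            net_config=net_config,
            scg_config=scg_config,
            case_id=case_id,
            reference=ref,
        )

    def fit(self, seed: int = 0, n_restarts: int = 1) -> "SurrogateResults":
        """Train with ``n_restarts`` seeded restarts; best run by validation MSE."""
        weights, record = multi_restart(
            self.net_config,
            self.scg_config,
            self.dataset,
            self.split,
            n_restarts=n_restarts,
            base_seed=seed,
        )
        return SurrogateResults(self, weights, record, seed=seed, n_restarts=n_restarts)


class SurrogateResults:
    """Fit results: best weights, training traces, predictions and metrics."""

    def __init__(
        self,
        model: NeuralSurrogate,
        weights: MLPWeights,
        record: TrainingRecord,
        seed: int,
        n_restarts: int,
    ) -> None:
        self.model = model
        self.weights = weights
        self.record = record
        self.seed = seed
        self.n_restarts = n_restarts

    # ------------------------------------------------------------------ #
    def predict(self, xs: np.ndarray | None = None) -> Trajectory:
        """Surrogate trajectory on ``xs`` (default: the training grid)."""
        if xs is None:
            xs = self.model.dataset.inputs
        xs = np.asarray(xs, dtype=float)
        xn = self.model.x_norm.apply(xs)[:, None]
        yn = forward(self.weights, xn)
        states = self.model.t_norm.invert(yn)
        return Trajectory(xs=xs, states=states, provenance="surrogate")

    def split_mse(self) -> dict:
        """Train/val/test MSE of the returned (best-validation) weights."""
        ds, split = self.model.dataset, self.model.split
        pred = self.predict().states
        out = {}
        for label in ("train", "val", "test"):
            idx = split.indices(label)
            out[label] = float(np.mean((pred[idx] - ds.targets[idx]) ** 2))
        return out

    def evaluate(self, reference: Trajectory | None = None) -> EvaluationReport:
        """Full metric bundle against the reference trajectory.

        AE curves are computed on the full grid against the Adams reference
        (the dataset source); per-split MSEs stay split-specific.  Signed
        errors pooled for the histogram follow the target - output
        convention.
        """
        ref = reference if reference is not None else self.model.reference
        if ref is None:
            ref = Trajectory(
                xs=self.model.dataset.inputs,
                states=self.model.dataset.targets,
                provenance=self.model.dataset.source,
            )
        pred = self.predict(ref.xs)
        ae = absolute_error(pred, ref)
        signed = (ref.states - pred.states).ravel()
        rec = self.record
        return EvaluationReport(
            case_id=self.model.case_id if self.model.case_id is not None else -1,
            seed=self.seed,
            n_restarts=self.n_restarts,
            mse=self.split_mse(),
            best_val_mse=rec.best_val_mse,
            best_val_epoch=rec.best_val_epoch,
            final_grad_norm=rec.grad_norm[-1] if rec.grad_norm else float("nan"),
            n_epochs=rec.n_epochs,
            stop_reason=rec.stop_reason,
            ae=ae,
            ae_max={k: float(v.max()) for k, v in ae.items()},
            ae_mean={k: float(v.mean()) for k, v in ae.items()},
            histogram=error_histogram(signed),
            regression=regression_metrics(pred.states, ref.states),
        )

    def history_frame(self) -> pd.DataFrame:
        rec = self.record
        return pd.DataFrame(
            {
                "epoch": np.arange(1, rec.n_epochs + 1),
                "train_mse": rec.train_mse,
                "val_mse": rec.val_mse,
                "test_mse": rec.test_mse,
                "grad_norm": rec.grad_norm,
            }
        )

    def summary(self) -> str:
        """Human-readable fit summary in the statsmodels spirit."""
        rep = self.evaluate()
        case = f"case {rep.case_id}" if rep.case_id > 0 else "custom dataset"
        lines = [
            "        Neural surrogate fit (scaled conjugate gradient)",
            "=" * 64,
            f"Problem:            language-learning ODE, {case}",
            f"Network:            1 -> {self.model.net_config.n_hidden} log-sigmoid -> 3 linear"
            f"  ({self.model.net_config.n_params} parameters)",
            f"Restarts / seed:    {self.n_restarts} / {self.seed}",
            f"Stop reason:        {rep.stop_reason} after {rep.n_epochs} epochs",
            f"Best val epoch:     {rep.best_val_epoch}",
            "-" * 64,
            f"MSE (train):        {rep.mse['train']:.6e}",
            f"MSE (validation):   {rep.mse['val']:.6e}",
            f"MSE (test):         {rep.mse['test']:.6e}",
            f"Best val MSE:       {rep.best_val_mse:.6e}",
            f"Final grad norm:    {rep.final_grad_norm:.6e}",
            "-" * 64,
            "Max |error| vs reference (per compartment):",
            f"  unknown u:        {rep.ae_max['u']:.3e}",
            f"  familiar f:       {rep.ae_max['f']:.3e}",
            f"  mastered m:       {rep.ae_max['m']:.3e}",
            f"R^2 (pooled):       {rep.regression['pooled']['r2']:.6f}",
            "=" * 64,
        ]
        return "\n".join(lines)

    def plot_diagnostics(self, out_dir) -> list:
        """Write fit / AE / histogram / regression panels as PNG files."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rep = self.evaluate()
        ref = self.model.reference or Trajectory(
            xs=self.model.dataset.inputs, states=self.model.dataset.targets
        )
        pred = self.predict(ref.xs)
        paths = []

        fig, ax = plt.subplots()
        for i, (name, style) in enumerate(zip(("u", "f", "m"), ("-", "--", ":"))):
            ax.plot(ref.xs, ref.states[:, i], style, label=f"{name} reference")
            ax.plot(pred.xs, pred.states[:, i], "o", ms=2, label=f"{name} surrogate")
        ax.set(xlabel="x", ylabel="proportion", title="Fit vs reference")
        ax.legend(fontsize=7)
        paths.append(out_dir / "fit.png")
        fig.savefig(paths[-1], dpi=120)
        plt.close(fig)

        fig, ax = plt.subplots()
        for name, arr in rep.ae.items():
            ax.semilogy(ref.xs, np.maximum(np.asarray(arr), 1e-18), label=name)
        ax.set(xlabel="x", ylabel="absolute error", title="AE per compartment")
        ax.legend()
        paths.append(out_dir / "ae.png")
        fig.savefig(paths[-1], dpi=120)
        plt.close(fig)

        fig, ax = plt.subplots()
        h = rep.histogram
        ax.bar(h["bin_centers"], h["counts"], width=np.diff(h["bin_edges"]))
        ax.set(xlabel="signed error (target - output)", ylabel="count",
               title="Error histogram")
        paths.append(out_dir / "histogram.png")
        fig.savefig(paths[-1], dpi=120)
        plt.close(fig)

        fig, axes = plt.subplots(1, 3, figsize=(10, 3.2))
        for i, (name, ax) in enumerate(zip(("u", "f", "m"), axes)):
            t, y = ref.states[:, i], pred.states[:, i]
            ax.plot(t, y, ".", ms=3)
            ax.plot([t.min(), t.max()], [t.min(), t.max()], "k--", lw=0.8)
            ax.set(title=f"{name}: R^2={rep.regression[name]['r2']:.4f}",
                   xlabel="target", ylabel="output")
        fig.tight_layout()
        paths.append(out_dir / "regression.png")
        fig.savefig(paths[-1], dpi=120)
        plt.close(fig)
        return paths


def reproduce_case(
    case_id: int,
    seed: int = 0,
    n_restarts: int = 20,
    out_dir=None,
    scg_config: SCGConfig | None = None,
    split_ratios=DEFAULT_RATIOS,
    split_seed: int | None = None,
    plots: bool = False,
) -> EvaluationReport:
    """End-to-end experiment for one study case.

    Adams reference on [0, 1] with step 0.01, 75/13/12 seeded split,
    ``n_restarts`` training restarts, evaluation against the Adams
    reference.  Fully deterministic per (seed, n_restarts); when
    ``out_dir`` is given, writes report.json, trajectory_pred.csv,
    trajectory_ref.csv, ae.csv and history.csv (and PNG panels with
    ``plots=True``).
    """
    model = NeuralSurrogate.from_case(
        case_id,
        split_seed=seed if split_seed is None else split_seed,
        split_ratios=split_ratios,
        scg_config=scg_config,
    )
    res = model.fit(seed=seed, n_restarts=n_restarts)
    report = res.evaluate()

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        try:
            with open(out_dir / "report.json", "w") as fh:
                json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
            res.predict(model.reference.xs).to_csv(out_dir / "trajectory_pred.csv")
            model.reference.to_csv(out_dir / "trajectory_ref.csv")
            ae_frame = pd.DataFrame({"x": model.reference.xs, **report.ae})
            ae_frame.to_csv(out_dir / "ae.csv", index=False, float_format="%.17g")
            res.history_frame().to_csv(
                out_dir / "history.csv", index=False, float_format="%.17g"
            )
            if plots:
                res.plot_diagnostics(out_dir)
        except Exception:
            for name in (
                "report.json",
                "trajectory_pred.csv",
                "trajectory_ref.csv",
                "ae.csv",
                "history.csv",
            ):
                (out_dir / name).unlink(missing_ok=True)
            raise
    return report
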