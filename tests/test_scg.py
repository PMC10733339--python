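"""Scaled conjugate gradient optimizer and training orchestration."""

import numpy as np
import pytest

from linguanet import NetConfig, SCGConfig, multi_restart, train
from linguanet.scg import scg_minimize


def test_scg_config_validation():
    with pytest.raises(ValueError):
        SCGConfig(sigma=0.0)
    with pytest.raises(ValueError):
        SCGConfig(max_epochs=0)
    with pytest.raises(ValueError):
        SCGConfig(min_gradient=-1.0)


def test_quadratic_converges_to_least_squares_optimum():
    """On an exactly quadratic loss (linear map), SCG finds the closed-form
    least-squares solution to 1e-10 within 200 epochs."""
    rng = np.random.default_rng(0)
    A = rng.normal(size=(30, 10))
    w_true = rng.normal(size=10)
    b = A @ w_true

    def fun(w):
        r = A @ w - b
        return float(np.mean(r * r)), (2.0 / b.size) * (A.T @ r)

    w_opt, *_ = np.linalg.lstsq(A, b, rcond=None)
    x, E, reason = scg_minimize(
        fun, np.zeros(10), SCGConfig(max_epochs=200, min_gradient=0.0)
    )
    assert np.max(np.abs(x - w_opt)) <= 1e-10


def test_objective_trace_non_increasing(dataset_case1, split_case1, quick_scg):
    """Only improving steps are accepted, so the optimized loss never rises."""
    _, rec = train(NetConfig(), quick_scg, dataset_case1, split_case1, seed=0)
    assert np.all(np.diff(rec.train_loss) <= 0)


def test_training_reproducible_bitwise(dataset_case1, split_case1, quick_scg):
    w1, r1 = train(NetConfig(), quick_scg, dataset_case1, split_case1, seed=4)
    w2, r2 = train(NetConfig(), quick_scg, dataset_case1, split_case1, seed=4)
    assert np.array_equal(w1.flatten(), w2.flatten())
    assert r1.to_dict() == r2.to_dict()


def test_best_val_epoch_is_argmin(dataset_case1, split_case1, quick_scg):
    _, rec = train(NetConfig(), quick_scg, dataset_case1, split_case1, seed=1)
    v = np.array(rec.val_mse)
    assert rec.best_val_epoch == int(np.argmin(v)) + 1
    assert rec.best_val_mse == v.min()


def test_stop_reason_semantics(dataset_case1, split_case1):
    """val_fail stops after exactly max_val_fail non-improving epochs;
    a min_gradient stop leaves the gradient at or below the threshold."""
    _, rec = train(NetConfig(), SCGConfig(), dataset_case1, split_case1, seed=1)
    if rec.stop_reason == "val_fail":
        v = np.array(rec.val_mse)
        best_before = v[: rec.best_val_epoch].min()
        tail = v[rec.best_val_epoch :]
        assert tail.size == SCGConfig().max_val_fail
        assert np.all(tail >= best_before)
    elif rec.stop_reason == "min_gradient":
        assert rec.grad_norm[-1] <= SCGConfig().min_gradient
    assert rec.n_epochs <= SCGConfig().max_epochs


def test_returned_weights_are_best_validation(dataset_case1, split_case1):
    """The trainer hands back the best-validation weights, not the final ones."""
    from linguanet.data import fit_normalizer
    from linguanet.network import forward

    w, rec = train(NetConfig(), SCGConfig(), dataset_case1, split_case1, seed=2)
    x_norm = fit_normalizer(dataset_case1.inputs, names=["x"])
    t_norm = fit_normalizer(dataset_case1.targets, names=["u", "f", "m"])
    idx = split_case1.indices("val")
    xn = x_norm.apply(dataset_case1.inputs)[idx, None]
    tn = t_norm.apply(dataset_case1.targets)[idx]
    scale2 = ((t_norm.hi - t_norm.lo) / 2.0) ** 2
    val = float(np.mean((forward(w, xn) - tn) ** 2 * scale2))
    assert val == pytest.approx(rec.best_val_mse, rel=1e-12)


def test_training_actually_learns(dataset_case1, split_case1):
    """Sanity guard: a full run fits the smooth target far below the data
    variance (~5e-2), i.e. the optimizer is not broken."""
    _, rec = train(NetConfig(), SCGConfig(), dataset_case1, split_case1, seed=0)
    assert rec.best_val_mse <= 1e-5


def test_empty_train_split_rejected(dataset_case1, split_case1):
    bad = type(split_case1)(
        labels=np.full(len(dataset_case1), "test", dtype=object),
        seed=0,
    )
    with pytest.raises(ValueError):
        train(NetConfig(), SCGConfig(), dataset_case1, bad, seed=0)


def test_multi_restart_contract(dataset_case1, split_case1, quick_scg):
    """n=1 equals a single run; the winner beats every individual restart;
    selection is deterministic in the base seed."""
    cfg = NetConfig()
    w1, r1 = train(cfg, quick_scg, dataset_case1, split_case1, seed=10)
    wm, rm = multi_restart(cfg, quick_scg, dataset_case1, split_case1, 1, base_seed=10)
    assert np.array_equal(w1.flatten(), wm.flatten())
    assert r1.best_val_mse == rm.best_val_mse

    _, best = multi_restart(cfg, quick_scg, dataset_case1, split_case1, 5, base_seed=10)
    singles = [
        train(cfg, quick_scg, dataset_case1, split_case1, seed=10 + k)[1].best_val_mse
        for k in range(5)
    ]
    assert best.best_val_mse == min(singles)

    _, again = multi_restart(cfg, quick_scg, dataset_case1, split_case1, 5, base_seed=10)
    assert again.seed == best.seed and again.best_val_mse == best.best_val_mse

    with pytest.raises(ValueError):
        multi_restart(cfg, quick_scg, dataset_case1, split_case1, 0, base_seed=0)
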