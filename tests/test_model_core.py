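"""Compartmental model: presets, rate matrix, exact solution, steady state."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from linguanet import (
    CompartmentState,
    ModelParams,
    Trajectory,
    analytic_solution,
    make_case,
    rate_matrix,
    rhs,
    steady_state,
)

params_st = st.builds(
    ModelParams,
    alpha=st.floats(1e-6, 1 - 1e-6, allow_nan=False),
    beta=st.floats(1e-6, 1 - 1e-6, allow_nan=False),
)

# matrix-exponential oracle values, frozen from a 40-digit mpmath
# eigen/series computation: expm(A*1) @ (1, 0, 0) per case
EXPM_AT_1 = {
    1: (0.61401155196791268, 0.29774203927992776, 0.088246408752159560),
    2: (0.64202240826898044, 0.27707729558440862, 0.080900296146610946),
    3: (0.66724502424511474, 0.25848899093004373, 0.074265984824841528),
}
STEADY = {
    1: (0.0047393364928909953, 0.047393364928909953, 0.94786729857819905),
    2: (0.090909090909090909, 0.18181818181818182, 0.72727272727272727),
    3: (0.21832884097035040, 0.24258760107816712, 0.53908355795148248),
}


@pytest.mark.parametrize(
    "case_id,expected", [(1, (0.5, 0.1)), (2, (0.5, 0.5)), (3, (0.5, 0.9))]
)
def test_case_presets(case_id, expected):
    p = make_case(case_id)
    assert (p.alpha, p.beta) == expected


@pytest.mark.parametrize("bad", [0, 4, -1, "1", None, 2.5])
def test_unknown_case_rejected(bad):
    with pytest.raises(ValueError):
        make_case(bad)


@pytest.mark.parametrize(
    "alpha,beta", [(0.0, 0.5), (1.0, 0.5), (0.5, 0.0), (0.5, 1.0), (-0.1, 0.5), (0.5, np.nan)]
)
def test_params_open_interval(alpha, beta):
    with pytest.raises(ValueError):
        ModelParams(alpha, beta)


@pytest.mark.parametrize(
    "case_id,rows",
    [
        (1, [[-0.5, 0.05, 0.0], [0.5, -0.55, 0.025], [0.0, 0.5, -0.025]]),
        (2, [[-0.5, 0.25, 0.0], [0.5, -0.75, 0.125], [0.0, 0.5, -0.125]]),
    ],
)
def test_rate_matrix_printed_coefficients(case_id, rows):
    assert np.allclose(rate_matrix(make_case(case_id)), rows, rtol=0, atol=1e-15)


@settings(max_examples=200, deadline=None)
@given(params_st)
def test_rate_matrix_structure(params):
    """Columns conserve mass; off-diagonals nonnegative (Metzler)."""
    A = rate_matrix(params)
    sums = A.sum(axis=0)
    # u and m columns cancel exactly; the f column has three terms and may
    # carry one rounding error
    assert sums[0] == 0.0 and sums[2] == 0.0
    assert abs(sums[1]) <= np.finfo(float).eps
    off = A[~np.eye(3, dtype=bool)]
    assert np.all(off >= 0) and np.all(np.diag(A) <= 0)


def test_rate_matrix_spectrum():
    """One zero eigenvalue; the other two have negative real parts."""
    for case_id in (1, 2, 3):
        ev = np.sort_complex(np.linalg.eigvals(rate_matrix(make_case(case_id))))
        assert min(abs(e) for e in ev) < 1e-14
        assert sum(1 for e in ev if e.real < -1e-10) == 2


@pytest.mark.parametrize(
    "case_id,state,expected",
    [
        (1, (1.0, 0.0, 0.0), (-0.5, 0.5, 0.0)),
        (2, (0.0, 1.0, 0.0), (0.25, -0.75, 0.5)),
    ],
)
def test_rhs_substitution(case_id, state, expected):
    d = rhs(make_case(case_id), CompartmentState(*state))
    assert np.allclose(d, expected, rtol=0, atol=1e-15)


@settings(max_examples=100, deadline=None)
@given(
    params_st,
    st.lists(st.floats(-2, 2, allow_nan=False), min_size=3, max_size=3),
)
def test_rhs_conserves_total(params, y):
    assert abs(np.sum(rhs(params, np.array(y)))) <= 1e-15


def test_rhs_rejects_nonfinite():
    with pytest.raises(ValueError):
        rhs(make_case(1), np.array([np.nan, 0.0, 0.0]))


def test_analytic_identity_at_origin(case1):
    traj = analytic_solution(case1, (1.0, 0.0, 0.0), [0.0])
    assert np.array_equal(traj.states[0], [1.0, 0.0, 0.0])


def test_analytic_empty_grid_rejected(case1):
    with pytest.raises(ValueError):
        analytic_solution(case1, (1.0, 0.0, 0.0), [])


@pytest.mark.parametrize("case_id", [1, 2, 3])
def test_analytic_matches_frozen_oracle(case_id):
    """expm-based solution at x=1 agrees with the high-precision oracle."""
    traj = analytic_solution(make_case(case_id), (1.0, 0.0, 0.0), [0.0, 1.0])
    assert np.allclose(traj.states[-1], EXPM_AT_1[case_id], rtol=0, atol=1e-12)


def test_analytic_conservation_and_bounds(analytic_case1):
    assert analytic_case1.conservation_defect().max() <= 1e-12
    assert np.all(analytic_case1.states >= -1e-12)
    assert np.all(analytic_case1.states <= 1 + 1e-12)


@pytest.mark.parametrize("case_id", [1, 2, 3])
def test_steady_state(case_id):
    params = make_case(case_id)
    ss = steady_state(params)
    assert np.allclose(ss.as_array(), STEADY[case_id], rtol=0, atol=1e-12)
    assert np.all(ss.as_array() > 0)
    assert abs(ss.total - 1.0) <= 1e-12
    assert np.max(np.abs(rate_matrix(params) @ ss.as_array())) <= 1e-12


@pytest.mark.parametrize("case_id", [1, 2, 3])
def test_long_run_limit(case_id):
    """The trajectory converges to the steady state in the long run."""
    params = make_case(case_id)
    end = analytic_solution(params, (1.0, 0.0, 0.0), [0.0, 500.0]).states[-1]
    assert np.max(np.abs(end - steady_state(params).as_array())) <= 1e-9


def test_trajectory_validation():
    with pytest.raises(ValueError):
        Trajectory(xs=[0.0, 0.0], states=np.zeros((2, 3)))
    with pytest.raises(ValueError):
        Trajectory(xs=[0.0, 1.0], states=np.zeros((3, 3)))
    with pytest.raises(ValueError):
        Trajectory(xs=[], states=np.zeros((0, 3)))


def test_trajectory_csv_roundtrip(tmp_path, analytic_case1):
    import pandas as pd

    path = tmp_path / "traj.csv"
    analytic_case1.to_csv(path)
    df = pd.read_csv(path)
    assert list(df.columns) == ["x", "u", "f", "m"]
    assert np.allclose(df[["u", "f", "m"]].to_numpy(), analytic_case1.states,
                       rtol=0, atol=1e-15)
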