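import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from linguanet import (
    Grid,
    NeuralSurrogate,
    SCGConfig,
    analytic_solution,
    build_dataset,
    make_case,
    solve_adams,
    split_dataset,
)

DEFAULT_XS = np.round(np.arange(101) * 0.01, 10)


@pytest.fixture(scope="session")
def case1():
    return make_case(1)


@pytest.fixture(scope="session")
def adams_case1(case1):
    return solve_adams(case1, (1.0, 0.0, 0.0), Grid())


@pytest.fixture(scope="session")
def analytic_case1(case1, adams_case1):
    return analytic_solution(case1, (1.0, 0.0, 0.0), adams_case1.xs)


@pytest.fixture(scope="session")
def dataset_case1(adams_case1):
    return build_dataset(adams_case1)


@pytest.fixture(scope="session")
def split_case1(dataset_case1):
    return split_dataset(dataset_case1, seed=7)


@pytest.fixture(scope="session")
def fitted_case1():
    """One moderately trained case-1 surrogate, shared across tests."""
    model = NeuralSurrogate.from_case(1, split_seed=7)
    return model.fit(seed=7, n_restarts=3)


@pytest.fixture
def quick_scg():
    """Short-budget optimizer settings for structural (non-accuracy) tests."""
    return SCGConfig(max_epochs=60)
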