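import numpy as np
import pytest

from hnc_cea.eq5d import ValueSet
from hnc_cea.synthetic import gen_calibrated_fixture


@pytest.fixture(scope="session")
def calibrated():
    """Two-arm single-state fixture calibrated to the published base case."""
    return gen_calibrated_fixture()


@pytest.fixture()
def toy_value_set():
    """Sparse toy TTO value set used by the worked scoring examples."""
    return ValueSet(
        full_health_value=1.0,
        constant_decrement_any_problem=0.08,
        dimension_decrements={("mobility", 2): 0.05, ("anxiety_depression", 3): 0.12},
        n3_decrement=0.10,
    )


def random_stochastic_matrix(rng: np.random.Generator, n_states: int) -> np.ndarray:
    """Random row-stochastic matrix with an absorbing last (Death) row."""
    P = rng.dirichlet(np.ones(n_states), size=n_states)
    P[-1] = 0.0
    P[-1, -1] = 1.0
    return P
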