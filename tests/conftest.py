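"""Shared fixtures: small random inverse problems and synthetic scenarios."""

import numpy as np
import pytest

import cghbm as c


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def random_problem(rng, m=12, n_pos=8, sigma=0.05):
    """A small random linear inverse problem with a planted source."""
    L = rng.normal(size=(m, 3 * n_pos))
    x_true = np.zeros(3 * n_pos)
    j = rng.integers(n_pos)
    x_true[3 * j:3 * j + 3] = rng.normal(size=3)
    y = L @ x_true + sigma * rng.normal(size=m)
    return L, y, sigma


@pytest.fixture(scope="session")
def small_scenario():
    """Moderate-size EEG scenario reused by slower integration tests."""
    return c.scenario_p20n20_like(n_dense=1500, seed=7)
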