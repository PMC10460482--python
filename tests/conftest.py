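import numpy as np
import pytest

from condq import SimScenario, simulate_dataset, make_test_table, two_sample_t_pvalues


@pytest.fixture
def rng():
    return np.random.default_rng(20230817)


def make_table(pvalues, covariates):
    """Canonical test table from raw vectors."""
    return make_test_table(np.asarray(pvalues, float), np.asarray(covariates, float))


def simulated_table(seed, m=2000, scenario="B", mu_delta=0.24, n=10):
    """One simulated dataset as (table, truth)."""
    sc = SimScenario(m=m, n=n, mu_delta=mu_delta, pi0_fn=scenario, seed=seed)
    expr, truth = simulate_dataset(sc)
    p = two_sample_t_pvalues(expr)
    return make_test_table(p, truth.x), truth


@pytest.fixture(scope="session")
def signal_table():
    """A strong-signal dataset shared across tests needing rejections."""
    return simulated_table(seed=101, m=2000, scenario="B", mu_delta=0.6)
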