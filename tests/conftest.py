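import numpy as np
import pytest

import icweibull as icw


@pytest.fixture(scope="session")
def cosmesis():
    return icw.cosmesis_fixture()


@pytest.fixture(scope="session")
def cosmesis_mle(cosmesis):
    return icw.fit_mle(cosmesis)


@pytest.fixture(scope="session")
def cosmesis_terms(cosmesis, cosmesis_mle):
    return icw.loglik_derivatives(cosmesis, cosmesis_mle.params)


def random_interval_dataset(n, rng, scale=2.0, shape=1.2):
    """Small helper shared across test modules: clinic-visit data with a
    fresh seed drawn from ``rng``."""
    seed = int(rng.integers(0, 2**31 - 1))
    sim = icw.simulate_dataset(icw.SimConfig(
        n=n, true_params=icw.WeibullParams(scale, shape), seed=seed))
    return sim.dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
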