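"""Shared fixtures: the small two-type reference model and random-model pools."""

import numpy as np
import pytest

import rvsdyn as rv


@pytest.fixture(scope="session")
def two_type():
    """The reference two-type model: f = (2, 1), symmetric mu = 0.1, N = 3."""
    return rv.two_type_model(2.0, 1.0, 0.1, 3)


@pytest.fixture(scope="session")
def two_type_space(two_type):
    return rv.enumerate_compositions(two_type.K, two_type.N)


def random_model_pool(n, seed, K_max=4, N_max=8, **kwargs):
    """Yield n seeded random models with K in [2, K_max], N in [2, N_max]."""
    rng = np.random.default_rng(seed)
    for _ in range(n):
        K = int(rng.integers(2, K_max + 1))
        N = int(rng.integers(2, N_max + 1))
        yield rv.random_model(K, N, seed=rng, **kwargs)


def random_composition(spec, rng):
    """A uniformly random composition for a model (multinomial spread)."""
    return rng.multinomial(spec.N, np.full(spec.K, 1.0 / spec.K))
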