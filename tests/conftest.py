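import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import neupredict as nm

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sine_pop():
    """One realized Sine population (N=1000), shared across tests."""
    return nm.gen_sine(1000, seed=11)


@pytest.fixture(scope="session")
def bump_pop():
    return nm.gen_bump(1000, seed=11)


@pytest.fixture()
def affine_pop():
    """Population whose y is exactly affine in x on both streams (no error)."""
    rng = np.random.default_rng(3)
    x_l, x_u = rng.uniform(0, 1, 40), rng.uniform(0, 1, 40)
    return nm.NeutroPopulation(
        nm.NeutroArray(x_l, x_u),
        nm.NeutroArray(2.0 + 3.0 * x_l, 2.0 + 3.0 * x_u),
        40,
        name="affine",
    )


@pytest.fixture()
def small_sample():
    return lambda N, n, seed=0: nm.srswor(N, n, np.random.default_rng(seed))
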