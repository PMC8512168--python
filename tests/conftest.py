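import numpy as np
import pytest

from bearsim.observers import CohortConfig, ListenerProfile, make_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Twelve listeners with the default generative settings."""
    return make_cohort(CohortConfig(n_listeners=12, seed=123))


@pytest.fixture(scope="session")
def onh_profile():
    """A near-normal-hearing listener with almost no response noise."""
    cfg = CohortConfig(n_listeners=2, onh_fraction=1.0, seed=5, noise_free=True)
    return make_cohort(cfg)[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
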