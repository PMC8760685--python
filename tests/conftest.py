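import numpy as np
import pytest
from hypothesis import settings

from methrep import InferenceConfig

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def advi_cfg():
    """Default ADVI settings used by most fits in the suite."""
    return InferenceConfig(backend="advi", s_draws=1000, seed=0)


@pytest.fixture(scope="session")
def mcmc_cfg():
    return InferenceConfig(
        backend="mcmc", s_draws=1000, mcmc_iterations=1500, seed=0
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
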