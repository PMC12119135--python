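import numpy as np
import pytest

from microdyn import MCMCSettings, generate_fixture


@pytest.fixture(scope="session")
def var3_noisy():
    """Stable 3-species VAR fixture with the canonical noise scale (sd 1.5)."""
    params, series = generate_fixture(
        "var", n_vars=3, n_steps=200, seed=0, noise_sd=1.5, stability="stable"
    )
    return params, series


@pytest.fixture(scope="session")
def fast_mcmc():
    """Reduced sampler settings for tests that only need rough posteriors."""
    return MCMCSettings(chains=4, tune=600, draws=600, thin=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
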