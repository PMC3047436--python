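import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import sphingokin as sk

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def network():
    return sk.load_default_network()


@pytest.fixture(scope="session")
def ref_params(network):
    return sk.load_reference_params(network)


@pytest.fixture(scope="session")
def clean_dataset(network):
    """Noise-free single-replicate dual-condition dataset from the reference set."""
    truth = sk.SyntheticTruth.default(network, noise_frac_sem=0.0, n_bio=1, n_tech=1)
    return sk.generate_dataset(network, truth)


@pytest.fixture(scope="session")
def noisy_dataset(network):
    """Default study conditions: 25% fractional SEM, 3 x 3 replicates."""
    truth = sk.SyntheticTruth.default(network, seed=7)
    return sk.generate_dataset(network, truth)


@pytest.fixture(scope="session")
def recovery_fit(network, clean_dataset):
    """The headline run: two-step estimation on the noise-free synthetic data."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return sk.two_step_fit(network, clean_dataset)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
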