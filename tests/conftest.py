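import warnings

import numpy as np
import pytest

from dungbef.synthetic_data import SyntheticConfig, generate_study

# MixedLM boundary fits emit convergence chatter that is handled inside
# fit_component; keep test output readable.
warnings.filterwarnings("ignore", module="statsmodels")


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down study: 8 landscapes in 3 regions."""
    return SyntheticConfig(seed=42, n_landscapes=8, n_regions=3,
                           pool_size=20, richness_mean_low=10.0)


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_study(small_config)


@pytest.fixture(scope="session")
def small_bundle(small_study):
    return small_study[0]


@pytest.fixture(scope="session")
def full_study():
    """A full-size study under the default design (38 landscapes)."""
    return generate_study(SyntheticConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
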