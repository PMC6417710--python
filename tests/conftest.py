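import pytest

import covermix as cm
from covermix.simulate import SiteSpec, SyntheticConfig


@pytest.fixture(scope="session")
def catalog():
    return cm.build_catalog()


@pytest.fixture(scope="session")
def default_trial():
    """One default synthetic trial (all noise sources on), seed 42."""
    return cm.generate(cm.default_config(42))


@pytest.fixture(scope="session")
def noise_free_config():
    return cm.default_config(7, species_cv=0.0, block_sd=0.0, weed_cv=0.0, dropout_base=0.0)


@pytest.fixture(scope="session")
def noise_free_trial(noise_free_config):
    return cm.generate(noise_free_config)


@pytest.fixture()
def single_weed_site_config():
    """One 2014-style weed-sampled site (40 treatments x 3 blocks)."""

    def make(seed: int, beta1: float = -0.0068, **overrides) -> SyntheticConfig:
        site = SiteSpec(11, 3, 2014, 1, 1.2, weed_sampled=True, beta1=beta1)
        return cm.default_config(seed, sites=(site,), **overrides)

    return make
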