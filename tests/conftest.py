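import numpy as np
import pytest

from rnacleave.ph_rate_model import (
    RateParams,
    TABLE1_BACKGROUND,
    TABLE1_CATALYST,
)


@pytest.fixture(scope="session")
def background_params() -> RateParams:
    """Fitted background constants (no-catalyst column)."""
    return TABLE1_BACKGROUND


@pytest.fixture(scope="session")
def catalyst_params() -> RateParams:
    """Fitted constants with 1 mM organomercury catalyst."""
    return TABLE1_CATALYST


@pytest.fixture(scope="session")
def combined_params() -> RateParams:
    """Background constants plus the catalytic term.

    The catalyzed experiments are compared against the catalyst-free
    background, so fold-acceleration bookkeeping uses the no-catalyst
    background constants together with the catalytic constants.
    """
    return RateParams(kH=2.4e-3, kH2O=1.3e-7, kOH=0.10, kcat=1.6e-3, Ka=3e-6)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20210224)
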