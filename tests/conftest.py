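import numpy as np
import pytest

from dynevolve.cli_pipeline import make_fixtures


@pytest.fixture(scope="session")
def fixtures():
    """Small canned datasets with known planted truths (seed 0)."""
    return make_fixtures(seed=0)


@pytest.fixture(scope="session")
def all_neutral(fixtures):
    return fixtures["all_neutral"]


@pytest.fixture(scope="session")
def single_sweep(fixtures):
    return fixtures["single_sweep"]


@pytest.fixture(scope="session")
def zigzag(fixtures):
    return fixtures["zigzag"]


@pytest.fixture(scope="session")
def two_founder_mix(fixtures):
    return fixtures["two_founder_mix"]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
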