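import numpy as np
import pytest

from abnma.hypodata import ScenarioSpec, generate
from abnma.mcmc import ChainConfig
from abnma.network import load_corticosteroids


@pytest.fixture(scope="session")
def cortico():
    return load_corticosteroids()


@pytest.fixture(scope="session")
def data_2a():
    return generate(ScenarioSpec(2, "a"))


@pytest.fixture(scope="session")
def data_3b():
    return generate(ScenarioSpec(3, "b"))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def short_chains(seed: int, kept: int = 4000, thin: int = 2) -> ChainConfig:
    """Reduced chain regime for tests: enough effective draws for the
    qualitative and MC-error-scaled checks, at seconds per fit."""
    return ChainConfig(
        burn_in=2000, post_burn_updates=kept * thin, thin=thin, seed=seed
    )
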