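import numpy as np
import pytest

from chainabridge import ChainSpec, FixtureConfig, generate_random_chains


@pytest.fixture(scope="session")
def random_chains():
    """General-position chains spanning sizes and rate scales."""
    return generate_random_chains(FixtureConfig(count=60, seed=20250921))


@pytest.fixture(scope="session")
def separated_chains():
    """Chains rescaled to validity ratio rho = 1e-3 (fast chain, slow exit)."""
    return generate_random_chains(
        FixtureConfig(count=40, seed=777, rho_target=1e-3)
    )


@pytest.fixture
def unit_rate_chain():
    """The classic three-species chain S1 <=> S2 -> S3 with unit rates."""
    return ChainSpec(n=2, forward=(1.0,), backward=(1.0,), exit_rate=1.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
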