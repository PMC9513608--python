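import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from breadsalt import bread_market as bm
from breadsalt import cra_mortality as cra
from breadsalt import synthetic_data as synth


@pytest.fixture(scope="session")
def policy_fixture():
    return synth.paper_fixture()


@pytest.fixture(scope="session")
def market_decomp(policy_fixture):
    return bm.decompose_market(
        policy_fixture.market_inputs, policy_fixture.total_t_yr
    )


@pytest.fixture(scope="session")
def implied_density(policy_fixture):
    return policy_fixture.salt_baseline.mean_salt_density_g_per_100g


@pytest.fixture
def one_stratum():
    """A single all-ages stratum with 1000 deaths from one cause."""
    return [
        cra.MortalityStratum(
            age_low=0,
            age_high=None,
            sex="female",
            population=1_000_000,
            deaths_by_cause={"cerebrovascular_disease": 1000.0},
        )
    ]


@pytest.fixture(scope="session")
def synthetic_strata():
    return synth.generate_strata(synth.SyntheticConfig(seed=42))
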