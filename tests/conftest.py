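import pytest

import traumacost as tc


@pytest.fixture(scope="session")
def config():
    return tc.default_config()


@pytest.fixture(scope="session")
def fixture_cohort():
    """The packaged deterministic reference cohort (n = 458)."""
    return tc.reference_cohort()


@pytest.fixture(scope="session")
def small_cohort():
    """A small generated cohort for fast structural checks."""
    return tc.generate_cohort(tc.GeneratorSpec(n=200, seed=7))


@pytest.fixture(scope="session")
def large_fit():
    """One expensive dose-response fit at n = 50,000, shared across tests.

    Generated with the reference per-trauma effect (OR 1.232) so parameter
    recovery can be checked against the generating value.
    """
    cohort = tc.generate_cohort(tc.GeneratorSpec(n=50_000, seed=20180401))
    return tc.fit_cumulative_logit(cohort)


@pytest.fixture(scope="session")
def base_distribution(config):
    return config.base_distribution()
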