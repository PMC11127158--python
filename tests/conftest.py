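import pytest

import mskcbr as m


@pytest.fixture(scope="session")
def worked_example():
    """Five-attribute worked example: (model, query, 4-case base)."""
    return m.worked_example_fixture()


@pytest.fixture(scope="session")
def default_model():
    return m.default_model()


@pytest.fixture(scope="session")
def cohort105():
    return m.generate_cohort(m.default_cohort_model(n=105, seed=1))


@pytest.fixture(scope="session")
def cohort50():
    return m.generate_cohort(m.default_cohort_model(n=50, seed=7))
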