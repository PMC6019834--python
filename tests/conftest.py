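import pytest

from mcidkit.instruments import CAT, CCQ, synthetic_sgrq
from mcidkit.synthetic import GeneratorConfig, generate, make_fixture


@pytest.fixture(scope="session")
def cat_spec():
    return CAT


@pytest.fixture(scope="session")
def ccq_spec():
    return CCQ


@pytest.fixture(scope="session")
def sgrq_spec():
    return synthetic_sgrq()


@pytest.fixture(scope="session")
def tiny_cohort():
    cohort, _ = make_fixture("tiny12")
    return cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One full-schedule synthetic cohort at the default conditions."""
    cohort, truth = generate(GeneratorConfig(seed=1))
    return cohort, truth


@pytest.fixture(scope="session")
def big_cohort():
    """Large cohort for moment checks (shares the calibration cache)."""
    cohort, truth = generate(GeneratorConfig(n_patients=5000, seed=3))
    return cohort, truth
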