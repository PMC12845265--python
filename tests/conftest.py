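import pytest

from digoxin_pbpk import (
    apply_heart_failure,
    build_model,
    digoxin_parameters,
    reference_adult_profile,
    scale_to_age,
)


@pytest.fixture(scope="session")
def adult_profile():
    return reference_adult_profile()


@pytest.fixture(scope="session")
def hf_profile(adult_profile):
    return apply_heart_failure(adult_profile)


@pytest.fixture(scope="session")
def neonate_profile(hf_profile):
    return scale_to_age(hf_profile, age=3, body_weight=3.5)


@pytest.fixture(scope="session")
def adult_drug():
    return digoxin_parameters("healthy_adult")


@pytest.fixture(scope="session")
def pediatric_drug():
    return digoxin_parameters("pediatric_hf")


@pytest.fixture(scope="session")
def adult_model(adult_drug, adult_profile):
    return build_model(adult_drug, adult_profile)


@pytest.fixture(scope="session")
def neonate_model(pediatric_drug, neonate_profile):
    return build_model(pediatric_drug, neonate_profile)
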