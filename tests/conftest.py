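"""Shared fixtures: synthetic study inputs fitted once per session."""

import pytest

from tobcohort import CohortConfig, derive_modified_table, fit_suite
from tobcohort.synthetic import (
    SyntheticSpec,
    gen_mortality,
    gen_transitions,
    reference_delta,
)


@pytest.fixture(scope="session")
def spec():
    return SyntheticSpec(seed=20240901)


@pytest.fixture(scope="session")
def base_table(spec):
    return gen_transitions(spec)


@pytest.fixture(scope="session")
def suite(spec):
    return fit_suite(gen_mortality(spec))


@pytest.fixture(scope="session")
def delta(spec):
    return reference_delta(spec)


@pytest.fixture(scope="session")
def modified_table(base_table, delta):
    return derive_modified_table(base_table, delta)


@pytest.fixture(scope="session")
def cohort_config():
    return CohortConfig()  # 1,000,000 never-users followed from 13 to 103
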