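import pytest

from fatexchange import (
    CohortSpec,
    apply_exchanges,
    cohort_intakes,
    default_rule_set,
    generate_cohort,
    generate_composition,
)


@pytest.fixture(scope="session")
def composition():
    return generate_composition(seed=1)


@pytest.fixture(scope="session")
def small_cohort(composition):
    """A 60-child cohort for unit-level checks."""
    return generate_cohort(CohortSpec(n_children=60, seed=2), composition)


@pytest.fixture(scope="session")
def full_cohort(composition):
    """The default study conditions: 600 children, 4-day diaries."""
    return generate_cohort(CohortSpec(n_children=600, seed=1), composition)


@pytest.fixture(scope="session")
def baseline_intakes(full_cohort, composition):
    return cohort_intakes(full_cohort.diaries, composition)


@pytest.fixture(scope="session")
def exchanged(full_cohort, composition):
    rules = default_rule_set(composition)
    modelled_diaries, report = apply_exchanges(full_cohort.diaries, rules, composition)
    return rules, modelled_diaries, report


@pytest.fixture(scope="session")
def modelled_intakes(exchanged, composition):
    _, modelled_diaries, _ = exchanged
    return cohort_intakes(modelled_diaries, composition)
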