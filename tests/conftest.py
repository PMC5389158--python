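from datetime import date

import pytest

from sirest import (
    Individual,
    combine_tables,
    generate_synthetic_cohort,
    worked_example_rates,
    worked_example_study_end,
)


@pytest.fixture(scope="session")
def rates():
    """Period-stratified mortality/migration/incidence of the worked example."""
    return worked_example_rates()


@pytest.fixture(scope="session")
def gamma(rates):
    return combine_tables(rates["mortality"], rates["migration"])


@pytest.fixture(scope="session")
def study_end():
    return worked_example_study_end()


@pytest.fixture(scope="session")
def reference_individual():
    """Born 1950-01-01, enters 1990-01-01 aged exactly 40, never diagnosed."""
    return Individual("ref", "any", date(1950, 1, 1), date(1990, 1, 1))


@pytest.fixture(scope="session")
def worked_cohort():
    cohort, _ = generate_synthetic_cohort(1000, profile="worked_example")
    return cohort


@pytest.fixture(scope="session")
def staggered_toy():
    """Three individuals entering in three different years, spread in age."""
    return [
        Individual("a", "any", date(1949, 3, 10), date(1990, 5, 1)),
        Individual("b", "any", date(1947, 7, 2), date(1991, 2, 15)),
        Individual("c", "any", date(1951, 11, 20), date(1992, 8, 3)),
    ]
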