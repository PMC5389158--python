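"""Synthetic cohort and rate-table generators.

The ``worked_example`` profile reproduces the single-stratum teaching
cohort: everyone is born 1950-01-01, enters follow-up 1990-01-01 aged
exactly 40, and is followed through 2004-12-31 under period-varying
yearly rates — mortality 2, 3, 5 per 1000, out-migration 13, 10, 7 per
1000 and disease incidence 0.5, 0.8, 1.2 per 1000 over 1990–94,
1995–99 and 2000–04. The ``staggered`` profile draws entry and birth
years uniformly to exercise arbitrary Lexis trajectories.

Generators are deterministic given a seed; no real cohort data is used
or emulated beyond these study-design parameters.
"""

from __future__ import annotations

from datetime import date, timedelta
from pathlib import Path

import numpy as np

from . import io as sio
from .person_time import Individual
from .rates import RateTable

__all__ = [
    "worked_example_rates",
    "worked_example_study_end",
    "generate_synthetic_cohort",
    "write_fixture",
]

#: (year_low, year_high) → (mortality, migration, incidence), per 1000
WORKED_EXAMPLE_RATES_PER_1000 = {
    (1990, 1995): (2.0, 13.0, 0.5),
    (1995, 2000): (3.0, 10.0, 0.8),
    (2000, 2005): (5.0, 7.0, 1.2),
}


def worked_example_study_end() -> date:
    return date(2004, 12, 31)


def worked_example_rates() -> dict[str, RateTable]:
    """Period-stratified rate tables of the worked example, open age domain.

    Rates vary by calendar period only (all ages, both sexes); for the
    fixed-entry cohort this reproduces the age-period diagonal 40–44 /
    45–49 / 50–54 exactly.
    """
    tables = {}
    for pos, name in [(0, "mortality"), (1, "migration"), (2, "incidence")]:
        records = [
            {"age_low": 0, "age_high": None, "year_low": yl, "year_high": yh,
             "sex": "any", "rate": vals[pos]}
            for (yl, yh), vals in WORKED_EXAMPLE_RATES_PER_1000.items()
        ]
        tables[name] = RateTable.from_records(records, scale="per1000", name=name)
    return tables


def generate_synthetic_cohort(
    n: int,
    seed: int = 0,
    profile: str = "worked_example",
    entry_years: tuple[int, int] = (1990, 2000),
    birth_years: tuple[int, int] = (1935, 1960),
) -> tuple[list[Individual], dict[str, RateTable]]:
    """Generate a cohort plus matching rate tables, reproducibly.

    ``worked_example`` emits ``n`` copies of the reference individual
    (no diagnoses; the simulator supplies events). ``staggered`` draws
    birth and entry dates uniformly from the given year ranges, with
    random sex, validated against the usual ordering constraints.
    """
    if n <= 0:
        raise ValueError(f"cohort size must be positive, got {n}")
    rates = worked_example_rates()
    if profile == "worked_example":
        cohort = [
            Individual(f"wx{i:05d}", "any", date(1950, 1, 1), date(1990, 1, 1))
            for i in range(n)
        ]
    elif profile == "staggered":
        rng = np.random.default_rng(seed)
        cohort = []
        for i in range(n):
            birth = date(int(rng.integers(birth_years[0], birth_years[1] + 1)), 1, 1) \
                + timedelta(days=int(rng.integers(0, 365)))
            entry = date(int(rng.integers(entry_years[0], entry_years[1] + 1)), 1, 1) \
                + timedelta(days=int(rng.integers(0, 365)))
            if entry < birth:
                entry = birth
            sex = "male" if rng.random() < 0.5 else "female"
            cohort.append(Individual(f"st{i:05d}", sex, birth, entry))
    else:
        raise ValueError(f"unknown cohort profile {profile!r}")
    return cohort, rates


def write_fixture(
    out_dir, n: int, seed: int = 0, profile: str = "worked_example"
) -> dict[str, Path]:
    """Write cohort + rate files for a generated fixture; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort, rates = generate_synthetic_cohort(n, seed=seed, profile=profile)
    paths = {"cohort": out / "cohort.csv"}
    sio.write_cohort(paths["cohort"], cohort)
    for name, table in rates.items():
        paths[name] = out / f"{name}.csv"
        sio.write_rates(paths[name], table, scale="per1000")
    return paths
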