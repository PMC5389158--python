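"""Lexis expansion and expected person-years under unknown end of follow-up.

Follow-up of an individual is split at every calendar-year boundary and
every age-group boundary into cell-wise durations (the Lexis expansion).
For cohort members whose end of follow-up is unobserved, expected
person-years are computed from the yearly combined loss rate γ in two
ways:

* per individual, as the survival-weighted expected time in each
  traversed cell (the product recursion), and
* in aggregate, by iteratively discounting the "raw" person-year table
  (everyone followed to study end) year by year, moving a fraction
  ``1/w`` of each year's expected loss into the next-oldest ``w``-year
  age group to account for aging.

The two pathways differ in how the year of loss is credited: the
per-individual recursion credits an expected half year to individuals
lost within a year, whereas the aggregate iteration applies the full
factor ``(1 − γ)`` in each cell. Both are exposed; see
``docs/methods.md`` for the discrepancy and its size.

Dates are whole days; durations use an ACT/365.25 day-count. An event
date (diagnosis, study end) contributes through the end of its day.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from datetime import date, timedelta
from typing import Iterable, Optional, Sequence

import numpy as np

from .rates import RateTable, SEXES

__all__ = [
    "DAYS_PER_YEAR",
    "EVENT_TIME_FRACTION",
    "Individual",
    "PYTable",
    "lexis_expand",
    "raw_person_years",
    "yearly_expected_py",
    "expected_py_individual",
    "adjust_person_years",
]

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25

#: expected within-year timing of a loss event (uniform within the year)
EVENT_TIME_FRACTION = 0.5


@dataclass(frozen=True)
class Individual:
    """One cohort member: follow-up facts known at cohort definition."""

    id: str
    sex: str
    birth_date: date
    entry_date: date
    diagnosis_date: Optional[date] = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.entry_date < self.birth_date:
            raise ValueError(
                f"individual {self.id}: entry {self.entry_date} before birth {self.birth_date}"
            )
        if self.diagnosis_date is not None and self.diagnosis_date < self.entry_date:
            raise ValueError(
                f"individual {self.id}: diagnosis {self.diagnosis_date} before entry {self.entry_date}"
            )

    def age_at(self, when: date) -> float:
        """Exact age in years (ACT/365.25) at the start of ``when``."""
        return (when - self.birth_date).days / DAYS_PER_YEAR

    def is_case(self, study_end: date) -> bool:
        return self.diagnosis_date is not None and self.diagnosis_date <= study_end


class PYTable:
    """Person-years on an (age group, calendar year, sex) grid.

    ``role`` tags provenance: ``raw`` (followed to study end), ``cases``
    (exact case time), ``adjusted`` (loss-discounted) or ``combined``.
    """

    def __init__(self, role: str, age_width: float = 5.0):
        if role not in ("raw", "adjusted", "cases", "combined"):
            raise ValueError(f"unknown PYTable role {role!r}")
        self.role = role
        self.age_width = float(age_width)
        self.data: dict[tuple[float, int, str], float] = {}

    def add(self, age_low: float, year: int, sex: str, py: float) -> None:
        if py < 0:
            raise ValueError(f"negative person-years {py} in cell ({age_low}, {year}, {sex})")
        key = (float(age_low), int(year), sex)
        self.data[key] = self.data.get(key, 0.0) + py

    def get(self, age_low: float, year: int, sex: str) -> float:
        return self.data.get((float(age_low), int(year), sex), 0.0)

    def total(self) -> float:
        return float(sum(self.data.values()))

    def cells(self):
        """Iterate ``(age_low, year, sex), py`` sorted by age then year."""
        return sorted(self.data.items())

    def years(self) -> list[int]:
        return sorted({k[1] for k in self.data})

    def combine(self, other: "PYTable") -> "PYTable":
        """Cell-wise sum of two tables (role becomes ``combined``)."""
        if self.age_width != other.age_width:
            raise ValueError("cannot combine PYTables with different age widths")
        out = PYTable("combined", self.age_width)
        for (a, y, s), v in self.data.items():
            out.add(a, y, s, v)
        for (a, y, s), v in other.data.items():
            out.add(a, y, s, v)
        return out

    __add__ = combine


def lexis_expand(
    individual: Individual, end_date: date, age_width: float = 5.0
) -> list[tuple[float, int, float]]:
    """Split ``[entry_date, end_date)`` at age-group and year boundaries.

    Returns ``(age_group_low, calendar_year, duration_years)`` triples in
    chronological order; durations sum exactly (to day-count precision)
    to ``(end_date − entry_date)``. ``end_date`` is exclusive: pass
    ``event_date + 1 day`` to credit the event day itself.
    """
    entry = individual.entry_date
    if end_date < entry:
        raise ValueError(f"end_date {end_date} precedes entry_date {entry}")
    if end_date == entry:
        return []

    splits = {entry, end_date}
    for year in range(entry.year + 1, end_date.year + 1):
        splits.add(date(year, 1, 1))
    # first day on which age >= boundary b is birth + ceil(b * 365.25) days
    b = age_width * max(1, math.floor(individual.age_at(entry) / age_width))
    while True:
        bdate = individual.birth_date + timedelta(days=math.ceil(b * DAYS_PER_YEAR))
        if bdate >= end_date:
            break
        if bdate > entry:
            splits.add(bdate)
        b += age_width

    points = sorted(d for d in splits if entry <= d <= end_date)
    out = []
    for d0, d1 in zip(points, points[1:]):
        age = individual.age_at(d0)
        group = math.floor(age / age_width) * age_width
        out.append((group, d0.year, (d1 - d0).days / DAYS_PER_YEAR))
    return out


def raw_person_years(
    cohort: Iterable[Individual], study_end: date, age_width: float = 5.0
) -> tuple[PYTable, PYTable]:
    """Raw person-years (non-cases followed to study end) and exact case time.

    Non-cases accrue from entry through the end of ``study_end``; cases
    accrue from entry through the end of their diagnosis day and are
    returned in the separate ``cases`` table. The raw total is the upper
    bound for the cohort's true person-years. Individuals diagnosed after
    ``study_end`` count as non-cases for this study window (logged).
    """
    raw = PYTable("raw", age_width)
    cases = PYTable("cases", age_width)
    for ind in cohort:
        if ind.entry_date > study_end:
            raise ValueError(
                f"individual {ind.id}: entry {ind.entry_date} after study end {study_end}"
            )
        if ind.diagnosis_date is not None and ind.diagnosis_date > study_end:
            logger.info(
                "individual %s diagnosed %s, after study end %s: treated as non-case",
                ind.id, ind.diagnosis_date, study_end,
            )
        if ind.is_case(study_end):
            end = ind.diagnosis_date + timedelta(days=1)
            table = cases
        else:
            end = study_end + timedelta(days=1)
            table = raw
        for group, year, dur in lexis_expand(ind, end, age_width):
            table.add(group, year, ind.sex, dur)
    return raw, cases


def yearly_expected_py(
    gammas: Sequence[float], event_time_fraction: float = EVENT_TIME_FRACTION
) -> np.ndarray:
    """Expected person-years per follow-up year under yearly loss rates.

    For whole-year cells entered on January 1, year ``k``'s expected
    contribution is ``(1 − 0.5·γ_k) · ∏_{κ<k} (1 − γ_κ)``: the
    probability of surviving all earlier years times the expected time in
    year ``k`` (a loss within the year credits half a year on average).
    """
    g = np.asarray(gammas, dtype=float)
    if np.any((g < 0) | (g > 1)):
        raise ValueError("loss rates must lie in [0, 1]")
    surv = np.concatenate([[1.0], np.cumprod(1.0 - g)[:-1]])
    return (1.0 - event_time_fraction * g) * surv


def expected_py_individual(
    individual: Individual,
    gamma: RateTable,
    study_end: date,
    age_width: float = 5.0,
    event_time_fraction: float = EVENT_TIME_FRACTION,
) -> PYTable:
    """Expected person-year contributions of one non-case, cell by cell.

    Each traversed Lexis cell contributes ``S · py* · (1 − f·γ·py*)``
    where ``py*`` is the maximal (raw) time in the cell, ``γ`` the cell's
    combined loss rate, ``f`` the expected within-year event timing and
    ``S = ∏ (1 − γ'·py*')`` over all earlier cells — the probability the
    cell is reached. For whole-year cells entered on January 1 this
    reduces to :func:`yearly_expected_py`.
    """
    if individual.is_case(study_end):
        raise ValueError(
            f"individual {individual.id} is an incident case; its person-years are exact"
        )
    out = PYTable("adjusted", age_width)
    surv = 1.0
    for group, year, dur in lexis_expand(
        individual, study_end + timedelta(days=1), age_width
    ):
        g = gamma.lookup(group, year, individual.sex)
        out.add(group, year, individual.sex, surv * dur * (1.0 - event_time_fraction * g * dur))
        surv *= 1.0 - g * dur
    return out


def adjust_person_years(
    raw: PYTable,
    gamma: RateTable,
    age_width: float = 5.0,
    year_of_loss_credit: float = 0.0,
    aging: bool = True,
) -> PYTable:
    """Discount a raw person-year table for unobserved losses, year by year.

    With the default ``year_of_loss_credit = 0`` the first contributing
    year gets ``p̂y = py*·(1 − γ)`` — the literal iterative rule. Each
    later year subtracts the expected person-year loss of the previous
    year — ``(w−1)/w`` of it from the same age group and ``1/w`` from
    the next youngest group, reflecting that one ``w``-th of a
    ``w``-year age group ages into the next group per year — before
    applying the loss factor.

    ``year_of_loss_credit = 0.5`` instead credits individuals lost
    within a year their expected half year (``p̂y = base·(1 − 0.5γ)``),
    which makes the aggregate accounting agree exactly with the
    per-individual recursion on cohorts that stay within one age group;
    the carried loss is the full person-loss either way. The literal
    rule understates each year's contribution by a factor ≈ (1 − 0.5γ)
    relative to the credited one; both are exposed deliberately.

    ``aging=False`` keeps each year's expected loss in its own age group
    (appropriate when the cohort cannot cross a group boundary during
    follow-up, e.g. a single broad age group).

    Negative intermediate cells (carried losses exceeding raw time in
    sparse cells) are floored at zero with a logged warning; this drops
    the excess loss and arises when a whole birth cohort leaves an age
    group faster than the expected 1/w-per-year aging flow (synchronized
    birth dates — a degenerate input for the aggregate method; use the
    per-individual pathway there).
    """
    if raw.role != "raw":
        raise ValueError(f"adjust_person_years expects a raw table, got role {raw.role!r}")
    w = age_width
    out = PYTable("adjusted", w)
    sexes = sorted({k[2] for k in raw.data})
    for sex in sexes:
        cells = {(a, y): v for (a, y, s), v in raw.data.items() if s == sex}
        if not cells:
            continue
        years = sorted({y for _, y in cells})
        ages = sorted({a for a, _ in cells})
        # include one older group so aged-out losses have somewhere to go
        grid = list(ages)
        if grid:
            grid.append(grid[-1] + w)
        loss_prev: dict[float, float] = {}
        for j in range(years[0], years[-1] + 1):
            loss_cur: dict[float, float] = {}
            for a in grid:
                py_star = cells.get((a, j), 0.0)
                if aging:
                    carried = (
                        loss_prev.get(a, 0.0) * (w - 1.0) / w
                        + loss_prev.get(a - w, 0.0) / w
                    )
                else:
                    carried = loss_prev.get(a, 0.0)
                if py_star == 0.0 and carried == 0.0:
                    continue
                base = py_star - carried
                if base < 0.0:
                    logger.warning(
                        "adjusted person-years negative in cell (age %s, year %s, %s): "
                        "expected loss %.4g exceeds raw %.4g; floored at 0",
                        a, j, sex, carried, py_star,
                    )
                    base = 0.0
                if base > 0.0:
                    g = gamma.lookup(a, j, sex)
                    adj = base * (1.0 - (1.0 - year_of_loss_credit) * g)
                    # person-loss: lost individuals contribute nothing next year,
                    # whatever partial-year credit they received this year
                    loss_cur[a] = py_star - base * (1.0 - g)
                else:
                    adj = 0.0
                    loss_cur[a] = py_star
                if adj > 0.0:
                    out.add(a, j, sex, adj)
            loss_prev = loss_cur
    return out
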