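"""Stratified yearly rates on an age × calendar-year (× sex) grid.

Rates are yearly probabilities (events per person-year, dimensionless,
stored per-1). Strata are half-open rectangles ``[age_low, age_high) ×
[year_low, year_high)``; the top age group may be open-ended
(``age_high = inf``). Mortality (other causes, μ), out-migration (ν) and
disease incidence (λ) all live in :class:`RateTable`; the combined loss
rate γ = μ + ν − μν lives in :class:`GammaTable`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

__all__ = [
    "Stratum",
    "RateTable",
    "GammaTable",
    "RateDomainError",
    "RateLookupError",
    "GridError",
    "combine_loss_rates",
    "combine_tables",
    "scale_rates",
    "SEXES",
]

SEXES = ("any", "male", "female")

#: factor applied at parse time to bring declared scales to per-1
SCALE_FACTORS = {"per1": 1.0, "per1000": 1e-3, "percent": 1e-2}


class RateDomainError(ValueError):
    """A rate (or scaled rate) falls outside the probability range [0, 1]."""


class RateLookupError(LookupError):
    """No stratum covers the queried (age, year, sex) cell."""


class GridError(ValueError):
    """Strata overlap, or two tables cannot be refined to a common grid."""


def _check_rate(value: float, name: str = "rate") -> float:
    if not (0.0 <= value <= 1.0):
        raise RateDomainError(f"{name} = {value!r} is outside [0, 1]")
    return float(value)


@dataclass(frozen=True)
class Stratum:
    """One half-open age × year rectangle with a single yearly rate."""

    age_low: float
    age_high: float  # math.inf for the open-ended top group
    year_low: float
    year_high: float
    sex: str
    rate: float

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if not self.age_low < self.age_high:
            raise GridError(f"empty age interval [{self.age_low}, {self.age_high})")
        if not self.year_low < self.year_high:
            raise GridError(f"empty year interval [{self.year_low}, {self.year_high})")
        _check_rate(self.rate)

    def contains(self, age: float, year: float, sex: str) -> bool:
        sex_ok = self.sex == "any" or sex == "any" or self.sex == sex
        return (
            sex_ok
            and self.age_low <= age < self.age_high
            and self.year_low <= year < self.year_high
        )

    def overlaps(self, other: "Stratum") -> bool:
        sex_clash = (
            self.sex == other.sex or self.sex == "any" or other.sex == "any"
        )
        return (
            sex_clash
            and self.age_low < other.age_high
            and other.age_low < self.age_high
            and self.year_low < other.year_high
            and other.year_low < self.year_high
        )


@dataclass(frozen=True)
class RateTable:
    """A set of non-overlapping strata; exactly one matches an in-domain query."""

    strata: tuple[Stratum, ...]
    name: str = "rate"

    def __post_init__(self) -> None:
        strata = tuple(self.strata)
        object.__setattr__(self, "strata", strata)
        if not strata:
            raise GridError("a rate table needs at least one stratum")
        for i, a in enumerate(strata):
            for b in strata[i + 1 :]:
                if a.overlaps(b):
                    raise GridError(f"overlapping strata: {a} / {b}")

    @classmethod
    def from_records(
        cls,
        records: Iterable[Mapping],
        scale: str = "per1",
        name: str = "rate",
    ) -> "RateTable":
        """Build a table from dict-like rows, normalizing the declared scale.

        Each record needs ``age_low, age_high, year_low, year_high, sex,
        rate``; ``age_high`` of None/inf marks the open top group.
        """
        if scale not in SCALE_FACTORS:
            raise ValueError(f"unknown rate scale {scale!r}")
        factor = SCALE_FACTORS[scale]
        strata = []
        for rec in records:
            high = rec.get("age_high")
            high = math.inf if high is None or (isinstance(high, float) and math.isnan(high)) else float(high)
            raw = float(rec["rate"]) * factor
            _check_rate(raw, f"{name} rate in stratum {dict(rec)}")
            strata.append(
                Stratum(
                    age_low=float(rec["age_low"]),
                    age_high=high,
                    year_low=float(rec["year_low"]),
                    year_high=float(rec["year_high"]),
                    sex=str(rec.get("sex", "any")),
                    rate=raw,
                )
            )
        return cls(tuple(strata), name=name)

    def lookup(self, age: float, year: float, sex: str = "any") -> float:
        """Rate for exact age (years) and calendar year; half-open matching."""
        for s in self.strata:
            if s.contains(age, year, sex):
                return s.rate
        raise RateLookupError(
            f"no {self.name} stratum covers age={age}, year={year}, sex={sex}"
        )

    def scale(self, multipliers) -> "RateTable":
        """See :func:`scale_rates`."""
        return scale_rates(self, multipliers)

    def age_breaks(self) -> list[float]:
        pts = {s.age_low for s in self.strata} | {s.age_high for s in self.strata}
        return sorted(p for p in pts if math.isfinite(p))

    def year_breaks(self) -> list[float]:
        pts = {s.year_low for s in self.strata} | {s.year_high for s in self.strata}
        return sorted(pts)

    def sexes(self) -> set[str]:
        return {s.sex for s in self.strata}


class GammaTable(RateTable):
    """Combined loss-rate (γ) variant of :class:`RateTable`."""


def combine_loss_rates(mortality: float, migration: float) -> float:
    """Combined yearly loss rate γ = μ + ν − μν (inclusion–exclusion).

    Both inputs are yearly probabilities of independent competing losses;
    the result is the probability of leaving observation through either.
    """
    mu = _check_rate(mortality, "mortality rate")
    nu = _check_rate(migration, "migration rate")
    return mu + nu - mu * nu


def _refined_cells(a: RateTable, b: RateTable):
    """Common-refinement cells (age_low, age_high, year_low, year_high, sex)."""
    ages = sorted(set(a.age_breaks()) | set(b.age_breaks()))
    tops_a = {s.age_high for s in a.strata}
    tops_b = {s.age_high for s in b.strata}
    open_top = math.inf in tops_a or math.inf in tops_b
    years = sorted(set(a.year_breaks()) | set(b.year_breaks()))
    if len(years) < 2:
        raise GridError("tables share no refinable year grid")
    sexes = (a.sexes() | b.sexes()) - {"any"} or {"any"}
    age_edges = list(zip(ages, ages[1:]))
    if open_top:
        age_edges.append((ages[-1] if ages else 0.0, math.inf))
    if not age_edges:
        age_edges = [(0.0, math.inf)]
    for al, ah in age_edges:
        for yl, yh in zip(years, years[1:]):
            for sex in sorted(sexes):
                yield al, ah, yl, yh, sex


def combine_tables(mortality: RateTable, migration: RateTable) -> GammaTable:
    """Stratum-wise γ = μ + ν − μν on the common grid refinement.

    Cells where either component is undefined are dropped; downstream
    lookups fail loudly there rather than extrapolating. Raises
    :class:`GridError` if no cell carries both components.
    """
    strata = []
    for al, ah, yl, yh, sex in _refined_cells(mortality, migration):
        probe_age = al if math.isfinite(al) else 0.0
        try:
            mu = mortality.lookup(probe_age, yl, sex)
            nu = migration.lookup(probe_age, yl, sex)
        except RateLookupError:
            continue
        strata.append(Stratum(al, ah, yl, yh, sex, combine_loss_rates(mu, nu)))
    if not strata:
        raise GridError(
            "mortality and migration tables have no common covered cell"
        )
    return GammaTable(tuple(strata), name="gamma")


def scale_rates(table: RateTable, multipliers) -> RateTable:
    """Return a new table with rates multiplied by a factor.

    ``multipliers`` is either a single non-negative number or a mapping
    from a table's :class:`Stratum` (rate ignored in matching) via
    ``(age_low, year_low, sex)`` keys to factors; unmatched strata keep
    factor 1. Scaled rates must remain valid probabilities.
    """
    if isinstance(multipliers, Mapping):
        def factor_for(s: Stratum) -> float:
            return float(multipliers.get((s.age_low, s.year_low, s.sex), 1.0))
    else:
        const = float(multipliers)
        def factor_for(s: Stratum) -> float:
            return const

    new = []
    for s in table.strata:
        f = factor_for(s)
        if f < 0:
            raise RateDomainError(f"negative rate multiplier {f}")
        scaled = s.rate * f
        _check_rate(scaled, f"scaled {table.name} rate in stratum {s}")
        new.append(replace(s, rate=scaled))
    return type(table)(tuple(new), name=table.name)
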