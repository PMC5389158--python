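"""Readers and writers for cohort, rate and person-year CSV files.

All files are plain CSV. Dates are ISO-8601 only. Rate files must
declare their scale, either through a leading ``# rate_scale: per1 |
per1000 | percent`` comment line or through the ``scale`` argument —
there is no guessing, because mixed per-1000 and percent sources are the
dominant practical failure mode.
"""

from __future__ import annotations

import io as _io
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .person_time import Individual, PYTable
from .rates import RateTable, SCALE_FACTORS

__all__ = [
    "read_cohort",
    "write_cohort",
    "read_rates",
    "write_rates",
    "read_py_table",
    "write_py_table",
]

COHORT_COLUMNS = ["id", "sex", "birth_date", "entry_date", "diagnosis_date"]
RATE_COLUMNS = ["age_low", "age_high", "year_low", "year_high", "sex", "rate"]
PY_COLUMNS = ["age_low", "age_high", "year", "sex", "person_years", "role"]


class CohortValidationError(ValueError):
    """One or more cohort rows failed validation; message lists them all."""


def _parse_date(text, row: int, column: str, errors: list[str]) -> Optional[date]:
    if text is None or (isinstance(text, float) and pd.isna(text)) or text == "":
        return None
    try:
        return datetime.strptime(str(text).strip(), "%Y-%m-%d").date()
    except ValueError:
        errors.append(f"row {row}: {column} {text!r} is not an ISO-8601 date")
        return None


def read_cohort(path) -> list[Individual]:
    """Read one individual per row; aggregate all row-level errors."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns and c != "diagnosis_date"]
    if missing:
        raise CohortValidationError(f"{path}: missing required columns {missing}")
    if "diagnosis_date" not in df.columns:
        df["diagnosis_date"] = ""
    errors: list[str] = []
    out: list[Individual] = []
    for idx, rec in enumerate(df.to_dict("records"), start=2):  # header = line 1
        birth = _parse_date(rec["birth_date"], idx, "birth_date", errors)
        entry = _parse_date(rec["entry_date"], idx, "entry_date", errors)
        diag = _parse_date(rec["diagnosis_date"], idx, "diagnosis_date", errors)
        if birth is None or entry is None:
            if rec["birth_date"] == "" or rec["entry_date"] == "":
                errors.append(f"row {idx}: birth_date and entry_date are required")
            continue
        try:
            out.append(Individual(str(rec["id"]), str(rec["sex"]), birth, entry, diag))
        except ValueError as exc:
            errors.append(f"row {idx}: {exc}")
    if errors:
        raise CohortValidationError(f"{path}: " + "; ".join(errors))
    return out


def write_cohort(path, cohort: Iterable[Individual]) -> None:
    df = pd.DataFrame(
        [
            {
                "id": ind.id,
                "sex": ind.sex,
                "birth_date": ind.birth_date.isoformat(),
                "entry_date": ind.entry_date.isoformat(),
                "diagnosis_date": "" if ind.diagnosis_date is None else ind.diagnosis_date.isoformat(),
            }
            for ind in cohort
        ],
        columns=COHORT_COLUMNS,
    )
    df.to_csv(path, index=False)


def _read_scale_header(path) -> Optional[str]:
    with open(path) as fh:
        first = fh.readline().strip()
    if first.startswith("#") and "rate_scale:" in first:
        return first.split("rate_scale:", 1)[1].strip()
    return None


def read_rates(path, scale: Optional[str] = None, name: str = "rate") -> RateTable:
    """Read a long-format rate CSV, normalizing to per-1.

    The scale comes from the ``# rate_scale:`` header comment unless
    given explicitly (the argument wins). A file with neither is refused.
    """
    declared = _read_scale_header(path)
    scale = scale or declared
    if scale is None:
        raise ValueError(
            f"{path}: no rate scale declared; add a '# rate_scale: per1|per1000|percent' "
            "header line or pass scale="
        )
    if scale not in SCALE_FACTORS:
        raise ValueError(f"{path}: unknown rate scale {scale!r}")
    df = pd.read_csv(path, comment="#")
    missing = [c for c in RATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing rate columns {missing}")
    records = df.to_dict("records")
    for rec in records:
        rec["sex"] = "any" if pd.isna(rec.get("sex")) or rec.get("sex") == "" else rec["sex"]
    return RateTable.from_records(records, scale=scale, name=name)


def write_rates(path, table: RateTable, scale: str = "per1") -> None:
    factor = SCALE_FACTORS[scale]
    rows = [
        {
            "age_low": s.age_low,
            "age_high": "" if s.age_high == float("inf") else s.age_high,
            "year_low": s.year_low,
            "year_high": s.year_high,
            "sex": s.sex,
            "rate": s.rate / factor,
        }
        for s in table.strata
    ]
    buf = _io.StringIO()
    buf.write(f"# rate_scale: {scale}\n")
    pd.DataFrame(rows, columns=RATE_COLUMNS).to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue())


def write_py_table(path, table: PYTable) -> None:
    rows = [
        {
            "age_low": a,
            "age_high": a + table.age_width,
            "year": y,
            "sex": s,
            "person_years": v,
            "role": table.role,
        }
        for (a, y, s), v in table.cells()
    ]
    pd.DataFrame(rows, columns=PY_COLUMNS).to_csv(path, index=False)


def read_py_table(path) -> PYTable:
    df = pd.read_csv(path)
    missing = [c for c in PY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing person-year columns {missing}")
    roles = df["role"].unique()
    if len(roles) != 1:
        raise ValueError(f"{path}: mixed roles {list(roles)} in one table")
    widths = (df["age_high"] - df["age_low"]).unique()
    width = float(widths[0]) if len(widths) == 1 else 5.0
    table = PYTable(str(roles[0]), width)
    for rec in df.to_dict("records"):
        table.add(float(rec["age_low"]), int(rec["year"]), str(rec["sex"]),
                  float(rec["person_years"]))
    return table
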