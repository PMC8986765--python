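"""CSV round-trip for household, child and census tables with schema checks.

Tables are written as plain UTF-8 CSV with a header row.  Reading validates
the schema (required columns, value ranges, referential integrity) and
reports the offending column and row on failure.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .simulate import CHILD_COLUMNS, HOUSEHOLD_COLUMNS

__all__ = [
    "SchemaError",
    "write_cohort",
    "read_cohort",
    "read_census",
    "validate_cohort",
]

HOUSEHOLD_FILE = "households.csv"
CHILD_FILE = "children.csv"

_BOOL_HH = [
    "migrant_head",
    "private_toilet",
    "consumed_wildmeat_12mo",
] + [c for c in HOUSEHOLD_COLUMNS if c.startswith("ppi_")]
_BOOL_CH = ["ever_ate_wildmeat", "normally_eats_wildmeat", "malaria_12mo", "worms_3mo"]


class SchemaError(ValueError):
    """A table violates the cohort schema.

    Carries the offending column name and, where applicable, the 0-based row
    index of the first violation.
    """

    def __init__(self, message: str, column: str | None = None, row=None):
        super().__init__(message)
        self.column = column
        self.row = row


def _require_columns(df: pd.DataFrame, columns, table: str) -> None:
    for col in columns:
        if col not in df.columns:
            raise SchemaError(f"{table} table is missing column '{col}'", column=col)


def _first_bad(mask: np.ndarray):
    idx = np.flatnonzero(mask)
    return int(idx[0]) if len(idx) else None


def _check(cond_bad: np.ndarray, message: str, column: str) -> None:
    row = _first_bad(np.asarray(cond_bad))
    if row is not None:
        raise SchemaError(f"{message} (column '{column}', row {row})",
                          column=column, row=row)


def validate_cohort(households: pd.DataFrame, children: pd.DataFrame) -> None:
    """Raise :class:`SchemaError` if the tables violate any invariant."""
    _require_columns(households, HOUSEHOLD_COLUMNS, "household")
    _require_columns(children, CHILD_COLUMNS, "child")

    hh, ch = households, children
    _check(~hh["location"].isin(["rural", "urban"]).to_numpy(),
           "location must be 'rural' or 'urban'", "location")
    _check(~hh["season"].isin(["wet", "dry"]).to_numpy(),
           "season must be 'wet' or 'dry'", "season")
    _check((hh["monthly_income_per_capita"].to_numpy() < 0),
           "income must be nonnegative", "monthly_income_per_capita")
    _check((hh["wildmeat_meals_30d"].to_numpy() < 0),
           "meal counts must be nonnegative", "wildmeat_meals_30d")
    _check(
        (hh["wildmeat_meals_30d"].to_numpy() > 0)
        & ~hh["consumed_wildmeat_12mo"].to_numpy(),
        "positive 30-day meal count implies 12-month consumption",
        "wildmeat_meals_30d",
    )
    for asf in ("fish", "chicken", "beef"):
        col = f"days_per_week_{asf}"
        v = hh[col].to_numpy()
        _check((v < 0) | (v > 7), "days per week must lie in [0, 7]", col)
    rural = (hh["location"] == "rural").to_numpy()
    empty_comm = hh["community_id"].astype(str).str.len().eq(0).to_numpy()
    _check(rural & empty_comm, "rural households need a community_id", "community_id")
    _check(hh["household_id"].duplicated().to_numpy(),
           "duplicate household_id", "household_id")
    _check((hh["fluvial_distance_km"].to_numpy() < 0),
           "fluvial distance must be nonnegative", "fluvial_distance_km")

    _check(ch["child_id"].duplicated().to_numpy(), "duplicate child_id", "child_id")
    age = ch["age_years"].to_numpy()
    _check((age < 0.5) | (age >= 5.0), "age must lie in [0.5, 5)", "age_years")
    _check(~ch["sex"].isin(["F", "M"]).to_numpy(), "sex must be 'F' or 'M'", "sex")
    _check((ch["hemoglobin_gdl"].to_numpy() <= 0),
           "hemoglobin must be positive", "hemoglobin_gdl")
    _check((ch["maternal_education_years"].to_numpy() < 0),
           "maternal education must be nonnegative", "maternal_education_years")
    _check(
        ch["normally_eats_wildmeat"].to_numpy()
        & ~ch["ever_ate_wildmeat"].to_numpy(),
        "normally_eats_wildmeat implies ever_ate_wildmeat",
        "normally_eats_wildmeat",
    )
    known = set(hh["household_id"])
    _check(~ch["household_id"].isin(known).to_numpy(),
           "child references unknown household_id", "household_id")


def write_cohort(households: pd.DataFrame, children: pd.DataFrame, path) -> None:
    """Validate and write both tables as CSV under directory `path`."""
    validate_cohort(households, children)
    os.makedirs(path, exist_ok=True)
    households.to_csv(os.path.join(path, HOUSEHOLD_FILE), index=False)
    children.to_csv(os.path.join(path, CHILD_FILE), index=False)


def _coerce_bools(df: pd.DataFrame, cols, table: str) -> None:
    mapping = {"True": True, "False": False, True: True, False: False,
               "true": True, "false": False, 1: True, 0: False, "1": True, "0": False}
    for col in cols:
        mapped = df[col].map(mapping)
        bad = mapped.isna() & df[col].notna()
        row = _first_bad(bad.to_numpy())
        if row is not None:
            raise SchemaError(
                f"{table} column '{col}' has a non-boolean value at row {row}",
                column=col, row=row)
        df[col] = mapped.astype(bool)


def read_cohort(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate a cohort written by :func:`write_cohort`."""
    hh = pd.read_csv(
        os.path.join(path, HOUSEHOLD_FILE),
        dtype={"community_id": str},
        keep_default_na=False,
        na_values=[],
    )
    ch = pd.read_csv(os.path.join(path, CHILD_FILE))
    _require_columns(hh, HOUSEHOLD_COLUMNS, "household")
    _require_columns(ch, CHILD_COLUMNS, "child")
    # numeric columns came back as strings because NA filtering is off
    for col in hh.columns:
        if col in ("household_id", "municipality_id", "community_id", "location",
                   "season") or col in _BOOL_HH:
            continue
        hh[col] = pd.to_numeric(hh[col])
    _coerce_bools(hh, _BOOL_HH, "household")
    _coerce_bools(ch, _BOOL_CH, "child")
    hh["n_members"] = hh["n_members"].astype(int)
    hh["wildmeat_meals_30d"] = hh["wildmeat_meals_30d"].astype(int)
    for asf in ("fish", "chicken", "beef"):
        hh[f"days_per_week_{asf}"] = hh[f"days_per_week_{asf}"].astype(int)
    validate_cohort(hh, ch)
    return hh, ch


CENSUS_COLUMNS = [
    "municipality_id",
    "pop_2010",
    "pop_2019",
    "rural_fraction",
    "children_6m_5y",
    "households_total",
    "hh_no_income",
    "hh_income_le_eighth_mw",
    "hh_income_eighth_to_quarter_mw",
    "hh_income_quarter_to_half_mw",
    "hh_income_above_half_mw",
]

_CLASS_COLUMNS = CENSUS_COLUMNS[6:]


def read_census(path) -> pd.DataFrame:
    """Read and validate a municipality census table."""
    df = pd.read_csv(path)
    _require_columns(df, CENSUS_COLUMNS, "census")
    _check((df["rural_fraction"].to_numpy() < 0) | (df["rural_fraction"].to_numpy() > 1),
           "rural_fraction must lie in [0, 1]", "rural_fraction")
    for col in ("pop_2010", "pop_2019", "children_6m_5y", "households_total",
                *_CLASS_COLUMNS):
        _check(df[col].to_numpy() < 0, "census counts must be nonnegative", col)
    total = sum(df[c].to_numpy() for c in _CLASS_COLUMNS)
    _check(total != df["households_total"].to_numpy(),
           "income-class counts must sum to households_total", "households_total")
    return df
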