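"""File formats of the pipeline: microdata in, estimate tables out.

All tables are UTF-8 comma-separated CSV with a mandatory header row and no
quoting of numerics.  Dates are century-month codes (CMC), the DHS standard
encoding: ``CMC = (year - 1900) * 12 + month``, so January 1900 is CMC 1.
Boolean flags are serialized as 0/1 integers.

Schemas
-------
``women.csv``
    woman_id, state_id, district_id, dob_cmc, interview_cmc,
    currently_married, using_any_method, weight
``births.csv``
    woman_id, birth_cmc
``district_estimates.csv``
    district_id, state_id, tfr, tfr_ci_low, tfr_ci_high, cpr,
    total_births_window
``averted.csv``
    district_id, group, tfrp, ba, pib, method
``state_aggregates.csv``
    unit_id, method, n_districts, n_below_replacement, n_cpr_above_50,
    total_births, ba_total, pib

Completed age in years is ``floor((later_cmc - dob_cmc) / 12)``; eligibility
(15-49) is evaluated at the interview, age-group attribution of a birth at
the birth month.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .errors import ReferentialIntegrityError, SchemaError, ValidationError

WOMEN_COLUMNS = [
    "woman_id",
    "state_id",
    "district_id",
    "dob_cmc",
    "interview_cmc",
    "currently_married",
    "using_any_method",
    "weight",
]

BIRTHS_COLUMNS = ["woman_id", "birth_cmc"]

ESTIMATE_COLUMNS = [
    "district_id",
    "state_id",
    "tfr",
    "tfr_ci_low",
    "tfr_ci_high",
    "cpr",
    "total_births_window",
]

AVERTED_COLUMNS = ["district_id", "group", "tfrp", "ba", "pib", "method"]

AGGREGATE_COLUMNS = [
    "unit_id",
    "method",
    "n_districts",
    "n_below_replacement",
    "n_cpr_above_50",
    "total_births",
    "ba_total",
    "pib",
]

#: Minimum mother's age at a birth, in months (10 completed years).
MIN_MOTHER_AGE_MONTHS = 120


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {missing}")


def validate_microdata(women: pd.DataFrame, births: pd.DataFrame) -> None:
    """Check every declared invariant; raise with offending row numbers.

    Row numbers are 1-based positions in the data (header excluded), i.e.
    ``df.index + 1`` for a freshly read table.
    """
    _require_columns(women, WOMEN_COLUMNS, "women table")
    _require_columns(births, BIRTHS_COLUMNS, "births table")

    problems: list[str] = []
    bad_rows: list[int] = []

    def flag(mask: pd.Series, message: str, frame: pd.DataFrame) -> None:
        if mask.any():
            rows = (np.flatnonzero(mask.to_numpy()) + 1).tolist()
            problems.append(f"{message} (rows {rows})")
            bad_rows.extend(rows)

    if women["woman_id"].duplicated().any():
        flag(women["woman_id"].duplicated(), "duplicate woman_id", women)

    flag(women["interview_cmc"] <= women["dob_cmc"],
         "interview_cmc must exceed dob_cmc", women)
    age_years = (women["interview_cmc"] - women["dob_cmc"]) // 12
    flag((age_years < 15) | (age_years > 49),
         "age at interview outside 15-49 completed years", women)
    flag(women["weight"] < 0, "negative sampling weight", women)

    known = set(women["woman_id"])
    orphan = ~births["woman_id"].isin(known)
    if orphan.any():
        rows = (np.flatnonzero(orphan.to_numpy()) + 1).tolist()
        raise ReferentialIntegrityError(
            f"births table: woman_id not present in women table (rows {rows})",
            rows=rows,
        )

    if len(births):
        mothers = women.set_index("woman_id")
        dob = births["woman_id"].map(mothers["dob_cmc"])
        interview = births["woman_id"].map(mothers["interview_cmc"])
        flag(births["birth_cmc"] <= dob + MIN_MOTHER_AGE_MONTHS,
             "birth before mother's 10th birthday", births)
        flag(births["birth_cmc"] > interview,
             "birth after the interview", births)

    if problems:
        raise ValidationError("; ".join(problems), rows=sorted(set(bad_rows)))


def read_microdata(women_path, births_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate the two-file microdata schema.

    Returns typed frames; any invariant breach raises listing every
    offending row, so no record is ever silently dropped.
    """
    women = pd.read_csv(women_path)
    births = pd.read_csv(births_path)
    _require_columns(women, WOMEN_COLUMNS, os.fspath(women_path))
    _require_columns(births, BIRTHS_COLUMNS, os.fspath(births_path))

    for col in ("dob_cmc", "interview_cmc"):
        women[col] = women[col].astype(np.int64)
    women["currently_married"] = women["currently_married"].astype(bool)
    women["using_any_method"] = women["using_any_method"].astype(bool)
    women["weight"] = women["weight"].astype(float)
    if len(births):
        births["birth_cmc"] = births["birth_cmc"].astype(np.int64)
    else:
        births = births.astype({"birth_cmc": np.int64}, errors="ignore")

    validate_microdata(women, births)
    return women[WOMEN_COLUMNS], births[BIRTHS_COLUMNS]


def write_microdata(women: pd.DataFrame, births: pd.DataFrame, out_dir) -> tuple[str, str]:
    """Write ``women.csv`` and ``births.csv`` under ``out_dir``."""
    os.makedirs(out_dir, exist_ok=True)
    wpath = os.path.join(out_dir, "women.csv")
    bpath = os.path.join(out_dir, "births.csv")
    w = women[WOMEN_COLUMNS].copy()
    w["currently_married"] = w["currently_married"].astype(int)
    w["using_any_method"] = w["using_any_method"].astype(int)
    w.to_csv(wpath, index=False)
    births[BIRTHS_COLUMNS].to_csv(bpath, index=False)
    return wpath, bpath


def write_estimates(records: pd.DataFrame, path, report: bool = False) -> None:
    """Write an estimate table with its fixed, documented column order.

    ``report=True`` rounds floats to 2 decimals for human-facing tables;
    the default writes full precision for lossless round-trips.
    """
    for schema in (ESTIMATE_COLUMNS, AVERTED_COLUMNS, AGGREGATE_COLUMNS):
        if set(schema) <= set(records.columns):
            out = records[schema].copy()
            break
    else:
        raise SchemaError(
            f"records match no known estimate schema: {list(records.columns)}"
        )
    if report:
        float_cols = out.select_dtypes(include=[float]).columns
        out[float_cols] = out[float_cols].round(2)
    out.to_csv(path, index=False)


def read_estimates(path) -> pd.DataFrame:
    """Read back a table written by :func:`write_estimates`."""
    df = pd.read_csv(path)
    for schema in (ESTIMATE_COLUMNS, AVERTED_COLUMNS, AGGREGATE_COLUMNS):
        if set(schema) <= set(df.columns):
            return df[schema]
    raise SchemaError(f"{path}: columns match no known estimate schema")
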