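"""Cohort CSV schema: reading, writing and validating respondent-level files.

One row per respondent.  Columns:

* ``respondent_id``
* 18 item columns named by scale/cluster/index (``ptsd_re1`` .. ``dso_fi3``),
  integer 0-4 (blank allowed only in lenient mode);
* check columns ``chk_<item>`` (plus ``chk_dso_ad2_v2`` / ``chk_dso_dr1_v2``
  for the two trialled second variants) with values ``yes`` / ``no`` / ``NA``;
  ``NA`` is valid only when the paired item scored below 2 (the check was
  never presented);
* exposure columns ``item01`` .. ``item21`` in {0, 1};
* optional ``worst_event`` (1-21) and ``time_since`` (free category).
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import pandas as pd

from .instrument import (
    DUAL_VARIANT_ITEMS,
    ITEMS,
    N_EXPOSURE_EVENTS,
    CheckAnswer,
    InvalidInputError,
    ItqRecord,
)

__all__ = [
    "CohortSchemaError",
    "EmptyCohortError",
    "check_columns",
    "cohort_columns",
    "frame_to_records",
    "records_to_frame",
    "read_cohort",
    "write_cohort",
]


class CohortSchemaError(ValueError):
    """The file does not conform to the cohort CSV schema."""


class EmptyCohortError(ValueError):
    """The cohort contains no respondents."""


def check_columns() -> list[str]:
    cols = []
    for item in ITEMS:
        cols.append(f"chk_{item.column}")
        if item in DUAL_VARIANT_ITEMS:
            cols.append(f"chk_{item.column}_v2")
    return cols


def cohort_columns() -> list[str]:
    """Canonical column order of a cohort CSV."""
    return (
        ["respondent_id"]
        + [i.column for i in ITEMS]
        + check_columns()
        + [f"item{j:02d}" for j in range(1, N_EXPOSURE_EVENTS + 1)]
    )


_ANSWERS = {"yes": CheckAnswer.YES, "no": CheckAnswer.NO, "NA": CheckAnswer.NOT_PRESENTED}


def frame_to_records(df: pd.DataFrame, lenient_missing: bool = False) -> list[ItqRecord]:
    """Convert a cohort frame to validated records.

    Gating-invariant violations are collected across the whole frame and
    reported together with their (1-based) row numbers.
    """
    required = set(cohort_columns())
    missing_cols = sorted(required - set(df.columns))
    if missing_cols:
        raise CohortSchemaError(f"missing columns: {missing_cols}")
    if df.empty:
        raise EmptyCohortError("cohort file contains no respondents")

    exposure_cols = [f"item{j:02d}" for j in range(1, N_EXPOSURE_EVENTS + 1)]
    records: list[ItqRecord] = []
    problems: list[str] = []
    for pos, (_, row) in enumerate(df.iterrows(), start=1):
        items = {}
        for item in ITEMS:
            raw = row[item.column]
            items[item] = None if pd.isna(raw) else int(raw)
        checks = {}
        for item in ITEMS:
            variants = (1, 2) if item in DUAL_VARIANT_ITEMS else (1,)
            for v in variants:
                col = f"chk_{item.column}" + ("" if v == 1 else "_v2")
                raw = row[col]
                key = "NA" if pd.isna(raw) else str(raw)
                if key not in _ANSWERS:
                    problems.append(f"row {pos}: bad check value {raw!r} in {col}")
                    continue
                ans = _ANSWERS[key]
                if ans is not CheckAnswer.NOT_PRESENTED:
                    checks[(item, v)] = ans
        try:
            rec = ItqRecord(
                respondent_id=str(row["respondent_id"]),
                items=items,
                checks=checks,
                exposures=tuple(int(row[c]) for c in exposure_cols),
                worst_event=None if "worst_event" not in row or pd.isna(row.get("worst_event"))
                else int(row["worst_event"]),
                time_since_event=None if "time_since" not in row or pd.isna(row.get("time_since"))
                else str(row["time_since"]),
            )
        except (InvalidInputError, ValueError) as exc:
            problems.append(f"row {pos}: {exc}")
            continue
        for msg in rec.validate_gating(lenient_missing=lenient_missing):
            problems.append(f"row {pos}: {msg}")
        records.append(rec)
    if problems:
        head = "; ".join(problems[:10])
        more = f" (+{len(problems) - 10} more)" if len(problems) > 10 else ""
        raise CohortSchemaError(f"{len(problems)} schema violation(s): {head}{more}")
    return records


def records_to_frame(records: Sequence[ItqRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        row: dict[str, object] = {"respondent_id": rec.respondent_id}
        for item in ITEMS:
            row[item.column] = rec.items[item]
        for item in ITEMS:
            variants = (1, 2) if item in DUAL_VARIANT_ITEMS else (1,)
            for v in variants:
                col = f"chk_{item.column}" + ("" if v == 1 else "_v2")
                row[col] = rec.check_answer(item, v).value.replace("not_presented", "NA")
        for j, e in enumerate(rec.exposures, start=1):
            row[f"item{j:02d}"] = e
        if rec.worst_event is not None:
            row["worst_event"] = rec.worst_event
        if rec.time_since_event is not None:
            row["time_since"] = rec.time_since_event
        rows.append(row)
    return pd.DataFrame(rows)


def read_cohort(path: str | os.PathLike, lenient_missing: bool = False) -> list[ItqRecord]:
    """Read and validate a cohort CSV; see module docstring for the schema."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise EmptyCohortError(f"{path}: empty file") from exc
    return frame_to_records(df, lenient_missing=lenient_missing)


def write_cohort(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a cohort frame as CSV with a stable column order."""
    ordered = [c for c in cohort_columns() if c in df.columns]
    extra = [c for c in df.columns if c not in ordered]
    df[ordered + extra].to_csv(path, index=False)
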