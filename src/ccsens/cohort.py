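"""Long-format cohort tables: reading, validation, and writing.

The analysis substrate is one row per mouse per test day, carrying the
total distance traveled (cm) in the 60-minute post-injection interval,
plus mouse-level covariates (strain, sex, test site, treatment arm,
day-1 body weight).

CSV dialect: comma-separated UTF-8 with a header row; missing numeric
values are empty fields; distances are written with 3 decimal places so
that write -> read is the identity on valid tables.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .protocol import DEFAULT_SCHEDULE, ProtocolSchedule, SEXES, SITES, TREATMENT_GROUPS

log = logging.getLogger(__name__)

SCHEMA_VERSION = "1.0"

CANONICAL_COLUMNS = (
    "mouse_id",
    "strain",
    "sex",
    "site",
    "treatment_group",
    "day",
    "distance",
    "body_weight",
)

#: header aliases accepted on input (MPD-style and common variants)
DEFAULT_ALIASES: dict[str, str] = {
    "animal_id": "mouse_id",
    "id": "mouse_id",
    "subject": "mouse_id",
    "strain_name": "strain",
    "test_site": "site",
    "treatment": "treatment_group",
    "group": "treatment_group",
    "test_day": "day",
    "total_distance": "distance",
    "distance_cm": "distance",
    "weight": "body_weight",
    "bw": "body_weight",
}

MOUSE_LEVEL_COLUMNS = ("strain", "sex", "site", "treatment_group", "body_weight")


class SchemaError(ValueError):
    """A required column is absent or a field has an invalid value."""


class IntegrityError(ValueError):
    """Rows violate cohort-level invariants (duplicates, bad days, ...)."""


@dataclass
class CohortTable:
    """Validated long-format locomotor table, one row per (mouse, day)."""

    records: pd.DataFrame
    source: str = ""
    schema_version: str = SCHEMA_VERSION

    def __post_init__(self) -> None:
        self.records = _normalize(self.records)

    @property
    def n_mice(self) -> int:
        return self.records["mouse_id"].nunique()

    def mouse_info(self) -> pd.DataFrame:
        """One row per mouse with its strain/sex/site/treatment/weight."""
        cols = ["mouse_id", *MOUSE_LEVEL_COLUMNS]
        return (
            self.records[cols]
            .drop_duplicates("mouse_id")
            .set_index("mouse_id")
            .sort_index()
        )

    def equals(self, other: "CohortTable") -> bool:
        a = self.records.reset_index(drop=True)
        b = other.records.reset_index(drop=True)
        return a.equals(b)


def _normalize(df: pd.DataFrame) -> pd.DataFrame:
    df = df.loc[:, list(CANONICAL_COLUMNS)].copy()
    df["mouse_id"] = df["mouse_id"].astype(str)
    df["strain"] = df["strain"].astype(str)
    df["sex"] = df["sex"].astype(str)
    df["site"] = df["site"].astype(str)
    df["treatment_group"] = df["treatment_group"].astype(str)
    df["day"] = df["day"].astype(int)
    df["distance"] = pd.to_numeric(df["distance"], errors="coerce").astype(float)
    df["body_weight"] = pd.to_numeric(df["body_weight"], errors="coerce").astype(float)
    return df.sort_values(["mouse_id", "day"], kind="mergesort").reset_index(drop=True)


def _check_records(df: pd.DataFrame, schedule: ProtocolSchedule, strict: bool) -> pd.DataFrame:
    bad_day = ~df["day"].isin(schedule.test_days)
    if bad_day.any():
        rows = df.index[bad_day].tolist()[:5]
        days = sorted(df.loc[bad_day, "day"].unique().tolist())
        raise IntegrityError(
            f"rows {rows} have day(s) {days} outside the protocol test days "
            f"{list(schedule.test_days)}"
        )
    if (df["distance"].dropna() < 0).any():
        raise SchemaError("negative distance values present")
    if (df["body_weight"].dropna() <= 0).any():
        raise SchemaError("non-positive body weights present")
    bad_sex = ~df["sex"].isin(SEXES)
    if bad_sex.any():
        raise SchemaError(f"invalid sex values: {sorted(df.loc[bad_sex, 'sex'].unique())}")
    bad_site = ~df["site"].isin(SITES)
    if bad_site.any():
        raise SchemaError(f"invalid site values: {sorted(df.loc[bad_site, 'site'].unique())}")
    bad_grp = ~df["treatment_group"].isin(TREATMENT_GROUPS)
    if bad_grp.any():
        raise SchemaError(
            f"invalid treatment_group values: {sorted(df.loc[bad_grp, 'treatment_group'].unique())}"
        )

    dup = df.duplicated(["mouse_id", "day"], keep="last")
    if dup.any():
        if strict:
            pairs = df.loc[dup, ["mouse_id", "day"]].values.tolist()[:5]
            raise IntegrityError(f"duplicate (mouse_id, day) rows, e.g. {pairs}")
        log.warning("dropping %d duplicate (mouse_id, day) rows (last row wins)", dup.sum())
        df = df[~dup]

    for col in MOUSE_LEVEL_COLUMNS:
        per_mouse = df.groupby("mouse_id", sort=False)[col].nunique(dropna=False)
        if (per_mouse > 1).any():
            bad = per_mouse.index[per_mouse > 1].tolist()[:5]
            raise IntegrityError(f"mice {bad} have inconsistent {col!r} across rows")
    return df


def make_cohort(
    df: pd.DataFrame,
    *,
    source: str = "",
    schedule: ProtocolSchedule = DEFAULT_SCHEDULE,
    strict: bool = True,
) -> CohortTable:
    """Validate a canonical-column DataFrame into a CohortTable."""
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    df = _check_records(_normalize(df), schedule, strict)
    return CohortTable(records=df, source=source)


def read_cohort(
    path: str | Path,
    *,
    strict: bool = False,
    aliases: dict[str, str] | None = None,
    schedule: ProtocolSchedule = DEFAULT_SCHEDULE,
) -> CohortTable:
    """Read a cohort CSV, applying header aliases, and validate it.

    Rows with a missing distance are retained (explicit NaN); duplicate
    (mouse, day) rows raise in strict mode, otherwise the last row wins.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"mouse_id": str}, encoding="utf-8")
    amap = dict(DEFAULT_ALIASES)
    if aliases:
        amap.update(aliases)
    df = df.rename(columns={c: amap.get(c.strip().lower(), c.strip().lower()) for c in df.columns})
    return make_cohort(df, source=str(path), schedule=schedule, strict=strict)


def write_cohort(table: CohortTable, path: str | Path) -> None:
    """Write a cohort CSV in canonical column order, sorted by (mouse_id, day).

    Distances and weights use 3 decimal places; missing values are empty
    fields, making write -> read lossless.
    """
    df = table.records.loc[:, list(CANONICAL_COLUMNS)]
    df.to_csv(Path(path), index=False, float_format="%.3f", na_rep="", encoding="utf-8")


@dataclass
class ValidationReport:
    """Report-only schedule check: per-mouse missing days and injection
    inconsistencies; derived phenotypes that cannot be computed."""

    missing_days: dict[str, list[int]] = field(default_factory=dict)
    inconsistencies: list[str] = field(default_factory=list)
    underivable: dict[str, list[str]] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not (self.missing_days or self.inconsistencies or self.underivable)

    def to_json(self) -> str:
        return json.dumps(
            {
                "ok": self.ok,
                "missing_days": self.missing_days,
                "inconsistencies": self.inconsistencies,
                "underivable": self.underivable,
            },
            indent=2,
        )


def validate_schedule(
    table: CohortTable,
    schedule: ProtocolSchedule = DEFAULT_SCHEDULE,
    injections: pd.Series | None = None,
) -> ValidationReport:
    """Check each mouse's observed days and injections against the protocol.

    `injections`, if given, is a per-row SAL/COC label (indexed like
    table.records) to cross-check against the arm's schedule.
    """
    from .phenotypes import PHENOTYPE_DAYS  # local import avoids a cycle

    report = ValidationReport()
    df = table.records
    for mouse_id, sub in df.groupby("mouse_id", sort=True):
        days = set(sub["day"])
        missing = [d for d in schedule.test_days if d not in days]
        if missing:
            report.missing_days[mouse_id] = missing
            lost = [
                name
                for name, need in PHENOTYPE_DAYS.items()
                if need and not set(need).issubset(days)
            ]
            if lost:
                report.underivable[mouse_id] = lost
    if injections is not None:
        for idx, inj in injections.items():
            row = df.loc[idx]
            expected = schedule.injection(row["treatment_group"], int(row["day"]))
            if inj != expected:
                report.inconsistencies.append(
                    f"mouse {row['mouse_id']} day {int(row['day'])}: "
                    f"labeled {inj}, schedule says {expected}"
                )
    return report


def concat_cohorts(tables: Iterable[CohortTable], source: str = "") -> CohortTable:
    df = pd.concat([t.records for t in tables], ignore_index=True)
    return make_cohort(df, source=source)
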