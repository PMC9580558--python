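"""Derived sensitization phenotypes from the 9-day distance series.

Eight per-mouse variables summarize the phases of behavioral
sensitization (all in cm of distance traveled, `D_d` = distance on day d):

==========================  =============================  ===========
variable                    definition                     days used
==========================  =============================  ===========
day1                        D1 (baseline, saline)          {1}
day2                        D2 (habituated, saline)        {2}
habituation                 D2 - D1                        {1, 2}
initial_response            D3 - D2 (first cocaine dose)   {2, 3}
initial_sensitization       D5 - D3                        {3, 5}
auc                         AUC over exposures 1..5        {3,5,7,9,11}
expression                  D19 - D11 (post-withdrawal)    {11, 19}
conditioned_activation      D12 - D2 (saline challenge)    {2, 12}
==========================  =============================  ===========

The AUC is the trapezoidal rule over the cocaine-exposure index with unit
spacing, (D3 + D11)/2 + D5 + D7 + D9; a plain sum of the five days is
available as an alternative rule. A derived field is missing whenever any
constituent day is missing; the day-set provenance above drives the
autocorrelation mask used by the correlation analysis.
"""
from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .protocol import SENSITIZATION_DAYS, TEST_DAYS

#: day-set provenance of every analysis variable (single days included)
PHENOTYPE_DAYS: dict[str, tuple[int, ...]] = {
    "day1": (1,),
    "day2": (2,),
    "habituation": (1, 2),
    "initial_response": (2, 3),
    "initial_sensitization": (3, 5),
    "auc": SENSITIZATION_DAYS,
    "expression": (11, 19),
    "conditioned_activation": (2, 12),
}

DERIVED_VARIABLES = tuple(PHENOTYPE_DAYS)

#: signed difference scores: name -> (later day, earlier day)
_DIFFS: dict[str, tuple[int, int]] = {
    "habituation": (2, 1),
    "initial_response": (3, 2),
    "initial_sensitization": (5, 3),
    "expression": (19, 11),
    "conditioned_activation": (12, 2),
}

AUC_RULES = ("trapezoid", "sum")


def auc_weights(rule: str = "trapezoid") -> np.ndarray:
    """Per-day weights over the five cocaine-exposure days (3,5,7,9,11)."""
    if rule == "trapezoid":
        return np.array([0.5, 1.0, 1.0, 1.0, 0.5])
    if rule == "sum":
        return np.ones(5)
    raise ValueError(f"unknown AUC rule {rule!r}; expected one of {AUC_RULES}")


def derive_variables(
    series: Mapping[int, float], auc_rule: str = "trapezoid"
) -> dict[str, float]:
    """Derive the eight phenotypes from one mouse's day -> distance map.

    A field whose constituent days are not all present (or are NaN) is
    returned as NaN.
    """
    d = {day: float(v) for day, v in series.items() if v is not None and np.isfinite(v)}
    if any(v < 0 for v in d.values()):
        raise ValueError("negative distance in series; validate the cohort upstream")
    out: dict[str, float] = {}
    out["day1"] = d.get(1, np.nan)
    out["day2"] = d.get(2, np.nan)
    for name, (later, earlier) in _DIFFS.items():
        if later in d and earlier in d:
            out[name] = d[later] - d[earlier]
        else:
            out[name] = np.nan
    if all(day in d for day in SENSITIZATION_DAYS):
        w = auc_weights(auc_rule)
        out["auc"] = float(np.dot(w, [d[day] for day in SENSITIZATION_DAYS]))
    else:
        out["auc"] = np.nan
    return out


def derive_cohort(table: CohortTable, auc_rule: str = "trapezoid") -> pd.DataFrame:
    """One row per mouse: derived phenotypes joined to mouse-level covariates.

    Columns: mouse_id (index), strain, sex, site, treatment_group,
    body_weight, the eight derived variables, and per-day distances as
    ``day_<d>`` columns. Rows are ordered by mouse_id.
    """
    wide = table.records.pivot(index="mouse_id", columns="day", values="distance")
    info = table.mouse_info()

    pheno = pd.DataFrame(index=wide.index)
    for day in TEST_DAYS:
        pheno[f"day_{day}"] = wide[day] if day in wide.columns else np.nan

    day_cols = {day: f"day_{day}" for day in TEST_DAYS}
    pheno["day1"] = pheno[day_cols[1]]
    pheno["day2"] = pheno[day_cols[2]]
    for name, (later, earlier) in _DIFFS.items():
        pheno[name] = pheno[day_cols[later]] - pheno[day_cols[earlier]]
    w = auc_weights(auc_rule)
    auc = np.zeros(len(pheno))
    for wi, day in zip(w, SENSITIZATION_DAYS):
        auc = auc + wi * pheno[day_cols[day]].to_numpy()
    pheno["auc"] = auc

    out = info.join(pheno).sort_index()
    ordered = [
        "strain", "sex", "site", "treatment_group", "body_weight",
        *DERIVED_VARIABLES,
        *[day_cols[d] for d in TEST_DAYS],
    ]
    return out[ordered]


def variable_day_set(variable: str) -> frozenset[int]:
    """Day-set provenance for the autocorrelation mask; body weight and
    other day-free covariates have the empty set."""
    if variable in PHENOTYPE_DAYS:
        return frozenset(PHENOTYPE_DAYS[variable])
    if variable.startswith("day_"):
        return frozenset({int(variable.split("_", 1)[1])})
    return frozenset()
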