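"""Strain-mean Pearson correlations with the autocorrelation mask.

Correlations among the analysis variables (per-day distances, derived
sensitization variables, day-1 body weight) are computed on strain
means, cocaine arm only. A pair of variables is *masked* — excluded from
reporting and from the multiple-testing family — when their day sets
overlap, because such correlations are partly arithmetic rather than
biological (e.g. the AUC against any of its constituent days). Two
single-day variables never share a day, and body weight carries no day
set, so neither is ever masked. Significance is Bonferroni-corrected
over the unmasked pairs actually reported.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .phenotypes import variable_day_set
from .protocol import TEST_DAYS

#: Fig-3 / Table-3 style variable order: days and derived variables
#: interleaved chronologically, body weight last
TABLE_ORDER: tuple[str, ...] = (
    "day_1", "day_2", "habituation", "day_3", "initial_response",
    "day_5", "initial_sensitization", "day_7", "day_9", "day_11",
    "auc", "conditioned_activation", "day_12", "expression", "day_19",
    "body_weight",
)

#: derived variables in cross-site (replicability) output order, using the
#: strain-mean matrix column names (day_1/day_2 are the day-level baselines)
CROSS_SITE_VARIABLES: tuple[str, ...] = (
    "day_1", "day_2", "habituation", "initial_response",
    "initial_sensitization", "auc", "expression", "conditioned_activation",
)


@dataclass
class CorrelationResult:
    var_a: str
    var_b: str
    r: float
    n: int
    p_unadjusted: float
    bonferroni_significant: bool
    masked: bool
    reason: str = ""


def autocorrelation_mask(variables: tuple[str, ...] = TABLE_ORDER) -> pd.DataFrame:
    """Boolean matrix: True where the pair must not be correlated.

    A pair is masked iff the two variables are distinct and their day
    sets intersect. Single-day pairs are structurally never masked, and
    day-free covariates (body weight) are exempt.
    """
    n = len(variables)
    M = np.zeros((n, n), dtype=bool)
    sets = [variable_day_set(v) for v in variables]
    for i, j in itertools.combinations(range(n), 2):
        if sets[i] & sets[j]:
            M[i, j] = M[j, i] = True
    return pd.DataFrame(M, index=list(variables), columns=list(variables))


def strain_means(
    phenotypes: pd.DataFrame,
    arm: str | None = "cocaine",
    variables: tuple[str, ...] = TABLE_ORDER,
) -> pd.DataFrame:
    """Strain x variable matrix of arithmetic means (missing-aware)."""
    sub = phenotypes if arm is None else phenotypes[phenotypes["treatment_group"] == arm]
    cols = [v for v in variables if v in sub.columns]
    return sub.groupby("strain")[cols].mean()


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 3:
        return np.nan, np.nan, n
    xs, ys = x[ok], y[ok]
    if np.std(xs) == 0 or np.std(ys) == 0:
        return np.nan, np.nan, n
    r = float(np.corrcoef(xs, ys)[0, 1])
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        return r, 0.0, n
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return r, p, n


def pearson_matrix(
    means: pd.DataFrame,
    mask: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> list[CorrelationResult]:
    """All lower-triangle pairwise correlations of the strain-mean matrix.

    Masked pairs carry no r or p; the Bonferroni denominator is the number
    of unmasked pairs with a reported (non-missing) correlation.
    """
    variables = list(means.columns)
    if mask is None:
        mask = autocorrelation_mask(tuple(variables))
    results: list[CorrelationResult] = []
    for a, b in itertools.combinations(variables, 2):
        if bool(mask.loc[a, b]):
            results.append(CorrelationResult(
                a, b, np.nan, 0, np.nan, False, True,
                reason=f"shared days {sorted(variable_day_set(a) & variable_day_set(b))}",
            ))
            continue
        r, p, n = _pearson(means[a].to_numpy(float), means[b].to_numpy(float))
        reason = "" if np.isfinite(r) else ("n < 3" if n < 3 else "zero variance")
        results.append(CorrelationResult(a, b, r, n, p, False, False, reason=reason))
    m_tests = sum(1 for c in results if not c.masked and np.isfinite(c.r))
    for c in results:
        if not c.masked and np.isfinite(c.p_unadjusted):
            c.bonferroni_significant = bool(c.p_unadjusted * m_tests < alpha)
    return results


def correlation_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "var_a": c.var_a, "var_b": c.var_b, "r": c.r, "n": c.n,
                "p_unadjusted": c.p_unadjusted,
                "bonferroni_significant": c.bonferroni_significant,
                "masked": c.masked, "reason": c.reason,
            }
            for c in results
        ]
    )


def correlation_table(results: list[CorrelationResult], variables: tuple[str, ...] = TABLE_ORDER) -> pd.DataFrame:
    """Lower-triangular matrix layout (masked and upper cells empty)."""
    tab = pd.DataFrame(np.nan, index=list(variables), columns=list(variables))
    order = {v: i for i, v in enumerate(variables)}
    for c in results:
        if c.masked or not np.isfinite(c.r):
            continue
        a, b = c.var_a, c.var_b
        if order[a] < order[b]:
            a, b = b, a
        tab.loc[a, b] = c.r
    return tab


def cross_site_correlation(
    means_a: pd.DataFrame,
    means_b: pd.DataFrame,
    variables: tuple[str, ...] = CROSS_SITE_VARIABLES,
) -> pd.DataFrame:
    """Between-site replicability: one correlation per derived variable
    across the strains measured at both sites. df is reported as n - 2."""
    shared = means_a.index.intersection(means_b.index)
    rows = []
    for var in variables:
        if var not in means_a.columns or var not in means_b.columns:
            warnings.warn(f"variable {var!r} absent from one site; skipped")
            continue
        x = means_a.loc[shared, var].to_numpy(float)
        y = means_b.loc[shared, var].to_numpy(float)
        r, p, n = _pearson(x, y)
        if n < 3:
            warnings.warn(f"variable {var!r}: fewer than 3 shared strains; skipped")
            continue
        rows.append({"variable": var, "r": r, "p": p, "n": n, "df": n - 2})
    return pd.DataFrame(rows)
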