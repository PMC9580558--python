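"""Broad-sense heritability from the one-way strain ANOVA.

For an inbred panel, all mice of a strain are genetically identical, so
the between-strain variance captures total genetic variance and

    H^2 = MS_strain / (MS_strain + (n_bar - 1) * MS_resid)

where MS_strain and MS_resid are the one-way ANOVA mean squares of the
per-mouse derived variable across strains and n_bar is the mean number
of mice per strain. The standard error comes from a model-based
(parametric) bootstrap: variance components are extracted from the mean
squares (sigma2_strain via the unbalanced-design effective n, clamped at
zero when negative), new cohorts are simulated from the fitted one-way
random-effects model preserving the observed per-strain counts, and the
estimator is recomputed on each (default 1,000 replicates).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phenotypes import DERIVED_VARIABLES
from .protocol import TEST_DAYS

log = logging.getLogger(__name__)

#: survey order: the eight derived variables, then per-day distances
SURVEY_VARIABLES: tuple[str, ...] = tuple(DERIVED_VARIABLES) + tuple(
    f"day_{d}" for d in TEST_DAYS
)


@dataclass
class MeanSquares:
    """One-way strain ANOVA summaries for a single derived variable."""

    ms_strain: float
    ms_resid: float
    df_strain: int
    df_resid: int
    n_bar: float          # arithmetic mean of per-strain counts
    n0: float             # unbalanced-design effective n
    grand_mean: float
    counts: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def n_strains(self) -> int:
        return self.df_strain + 1


@dataclass
class HeritabilityEstimate:
    variable: str
    h2: float
    se: float
    n_boot: int
    seed: int | None
    sigma2_strain: float
    sigma2_resid: float
    n_strains: int
    n_mice: int


def strain_anova(values, strains, min_per_strain: int = 1) -> MeanSquares:
    """One-way ANOVA decomposition of a per-mouse phenotype by strain.

    Missing values are dropped; strains left with fewer than
    `min_per_strain` observations are excluded (with a warning when any
    are dropped).
    """
    s = pd.Series(np.asarray(values, dtype=float), index=np.asarray(strains))
    s = s.dropna()
    counts = s.groupby(level=0).size()
    keep = counts[counts >= max(min_per_strain, 1)].index
    if len(keep) < len(counts):
        log.warning("excluding %d strain(s) with < %d observations",
                    len(counts) - len(keep), min_per_strain)
    s = s[s.index.isin(keep)]
    a = s.index.nunique()
    if a < 2:
        raise ValueError("need at least two strains with observations")
    N = len(s)
    grand = float(s.mean())
    g = s.groupby(level=0)
    ni = g.size().to_numpy(dtype=float)
    means = g.mean()
    ss_strain = float((ni * (means.to_numpy() - grand) ** 2).sum())
    ss_resid = float(((s - means.reindex(s.index).to_numpy()) ** 2).sum())
    df_strain = a - 1
    df_resid = N - a
    n0 = (N - float((ni**2).sum()) / N) / df_strain
    return MeanSquares(
        ms_strain=ss_strain / df_strain,
        ms_resid=ss_resid / df_resid if df_resid > 0 else 0.0,
        df_strain=df_strain,
        df_resid=df_resid,
        n_bar=float(ni.mean()),
        n0=n0,
        grand_mean=grand,
        counts=ni.astype(int),
    )


def h2_point(ms: MeanSquares) -> float:
    """H^2 = MS_strain / (MS_strain + (n_bar - 1) MS_resid); NaN when both
    mean squares are zero (no variance at all)."""
    denom = ms.ms_strain + (ms.n_bar - 1.0) * ms.ms_resid
    if denom <= 0.0:
        log.warning("both mean squares are zero; heritability undefined")
        return np.nan
    return ms.ms_strain / denom


def variance_components(ms: MeanSquares) -> tuple[float, float]:
    """Method-of-moments components (sigma2_strain, sigma2_resid) from the
    mean squares, using the effective per-strain n for unbalanced designs;
    a negative strain component is clamped to zero."""
    s2s = max(0.0, (ms.ms_strain - ms.ms_resid) / ms.n0)
    return s2s, ms.ms_resid


def h2_bootstrap(
    ms: MeanSquares,
    n_boot: int = 1000,
    seed: int | None = None,
    variable: str = "",
) -> HeritabilityEstimate:
    """Model-based bootstrap SE of the heritability estimate.

    Each replicate simulates y_ij = grand_mean + s_i + e_ij with
    s_i ~ N(0, sigma2_strain), e_ij ~ N(0, sigma2_resid), preserving the
    observed per-strain counts, then recomputes the point estimate; the
    SE is the standard deviation of the replicate values. Deterministic
    given the seed.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2 for a standard error")
    if ms.counts.size == 0:
        raise ValueError("MeanSquares must carry per-strain counts")
    s2s, s2e = variance_components(ms)
    rng = np.random.default_rng(seed)
    counts = ms.counts.astype(int)
    a = len(counts)
    N = int(counts.sum())
    strain_of = np.repeat(np.arange(a), counts)
    nbar = ms.n_bar
    # vectorized over replicates: (n_boot, N) residuals + per-strain effects
    s_eff = rng.normal(0.0, np.sqrt(s2s), size=(n_boot, a))
    e = rng.normal(0.0, np.sqrt(s2e), size=(n_boot, N))
    y = ms.grand_mean + s_eff[:, strain_of] + e
    group_sums = np.zeros((n_boot, a))
    np.add.at(group_sums.T, strain_of, y.T)  # accumulate per strain
    group_means = group_sums / counts
    grand = y.mean(axis=1)
    ss_strain = ((group_means - grand[:, None]) ** 2 * counts).sum(axis=1)
    resid = y - group_means[:, strain_of]
    ss_resid = (resid**2).sum(axis=1)
    ms_s = ss_strain / (a - 1)
    ms_e = ss_resid / (N - a)
    denom = ms_s + (nbar - 1.0) * ms_e
    with np.errstate(invalid="ignore", divide="ignore"):
        h2_rep = np.where(denom > 0, ms_s / denom, np.nan)
    se = float(np.nanstd(h2_rep, ddof=1))
    return HeritabilityEstimate(
        variable=variable,
        h2=h2_point(ms),
        se=se,
        n_boot=n_boot,
        seed=seed,
        sigma2_strain=s2s,
        sigma2_resid=s2e,
        n_strains=a,
        n_mice=N,
    )


def h2_survey(
    phenotypes: pd.DataFrame,
    arm: str = "cocaine",
    variables: tuple[str, ...] = SURVEY_VARIABLES,
    n_boot: int = 1000,
    seed: int | None = None,
) -> list[HeritabilityEstimate]:
    """Heritability of every derived variable and per-day distance, in the
    cocaine arm only (as the estimator is defined); missing values are
    dropped per variable."""
    sub = phenotypes[phenotypes["treatment_group"] == arm]
    rng = np.random.default_rng(seed)
    out: list[HeritabilityEstimate] = []
    for var in variables:
        if var not in sub.columns or sub[var].notna().sum() == 0:
            warnings.warn(f"variable {var!r} entirely missing; skipped")
            continue
        ms = strain_anova(sub[var], sub["strain"])
        est = h2_bootstrap(ms, n_boot=n_boot,
                           seed=int(rng.integers(2**31 - 1)), variable=var)
        out.append(est)
    return out


def survey_to_frame(estimates: list[HeritabilityEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "variable": e.variable, "h2": e.h2, "se": e.se,
                "n_boot": e.n_boot, "n_strains": e.n_strains, "n_mice": e.n_mice,
                "sigma2_strain": e.sigma2_strain, "sigma2_resid": e.sigma2_resid,
            }
            for e in estimates
        ]
    )
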