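"""Linear mixed model with a per-mouse random intercept, and the ANOVA
machinery built on it.

The model for a response y (typically sex-residualized distance) is::

    y = X beta + Z u + e,   u ~ N(0, s2_mouse I),   e ~ N(0, s2_e I)

with X a cell-means design over the requested fixed factors (full
factorial, e.g. day x treatment x strain) and Z the mouse incidence
matrix. REML estimation profiles the restricted likelihood down to a
single scalar, the variance ratio lam = s2_mouse / s2_e: given lam, beta
and s2_e have closed forms. Because every mouse sits in exactly one
level of each mouse-level factor, the whitened normal equations are
block-diagonal over groups of cells that share mice, which makes each
objective evaluation linear in the number of observations.

Inference: Type III Wald F tests through the cell-means
reparameterization (coding-independent), with Satterthwaite denominator
degrees of freedom obtained by the delta method on the REML
variance-parameter covariance; Tukey HSD p-values from the studentized
range distribution; per-strain cocaine-vs-saline responder contrasts.
"""
from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

log = logging.getLogger(__name__)

_LOG_LAM_LO, _LOG_LAM_HI = np.log(1e-8), np.log(1e8)


class RankDeficiencyError(ValueError):
    """The fixed-effects design is singular (aliased terms / empty cells)."""


def residualize_sex(values: np.ndarray | pd.Series, sex: np.ndarray | pd.Series) -> np.ndarray:
    """OLS residuals of the response on an intercept plus a sex indicator.

    Equivalent to centering within each sex, so residuals sum to zero
    overall and within each sex. Missing responses stay missing. With a
    single sex level this reduces to mean-centering (a warning is logged).
    Idempotent.
    """
    y = np.asarray(values, dtype=float)
    s = np.asarray(sex)
    out = np.full_like(y, np.nan)
    ok = np.isfinite(y)
    levels = pd.unique(s[ok])
    if len(levels) < 2:
        log.warning("single sex level present; residualizing reduces to mean-centering")
    for lev in levels:
        m = ok & (s == lev)
        out[m] = y[m] - y[m].mean()
    return out


@dataclass
class _MouseData:
    """Sufficient statistics of one mouse for the whitened cross-products."""
    block: int
    cells: np.ndarray    # local cell indices within the block
    counts: np.ndarray   # observations per cell (s_m = X_m' 1)
    ysum: np.ndarray     # per-cell response sums (X_m' y)
    n: int
    ytot: float
    yy: float


@dataclass
class _Block:
    cells: np.ndarray          # global cell indices
    mice: list[_MouseData]
    cell_n: np.ndarray         # total observations per cell
    cell_ysum: np.ndarray


@dataclass
class AnovaRow:
    term: str
    f_value: float
    df_num: float
    df_den: float
    p_value: float
    note: str = ""


@dataclass
class ContrastResult:
    strain: str
    estimate: float
    se: float
    t: float
    df: float
    p_unadjusted: float
    p_tukey: float
    responder: bool
    estimable: bool = True


@dataclass
class LMMFit:
    """REML fit of the random-intercept cell-means model."""

    factors: tuple[str, ...]
    levels: dict[str, list]
    cells: list[tuple]               # full factorial cell labels, product order
    observed: np.ndarray             # boolean mask over `cells`
    beta: np.ndarray                 # estimates for observed cells (NaN elsewhere)
    var_mouse: float
    var_resid: float
    reml_loglik: float
    n_obs: int
    n_groups: int
    boundary: bool                   # var_mouse hit the zero boundary
    degenerate: bool                 # residual variance ~ 0
    group: str = "mouse_id"
    _blocks: list[_Block] = field(default_factory=list, repr=False)
    _cell_to_block: dict[int, tuple[int, int]] = field(default_factory=dict, repr=False)
    _theta_cov: np.ndarray | None = field(default=None, repr=False)

    # -- covariance machinery -------------------------------------------------

    @property
    def ratio(self) -> float:
        return self.var_mouse / self.var_resid if self.var_resid > 0 else np.inf

    def _block_matrices(self, lam: float) -> list[np.ndarray]:
        mats = []
        for blk in self._blocks:
            G = np.diag(blk.cell_n.astype(float))
            for m in blk.mice:
                w = lam / (1.0 + lam * m.n)
                if w != 0.0:
                    G[np.ix_(m.cells, m.cells)] -= w * np.outer(m.counts, m.counts)
            mats.append(G)
        return mats

    def contrast_variance(self, ell: np.ndarray, theta: tuple[float, float] | None = None) -> float:
        """Variance of ell' beta at variance parameters theta=(s2_mouse, s2_e)."""
        return float(self.contrast_variances(ell[None, :], theta)[0])

    def contrast_variances(
        self, L: np.ndarray, theta: tuple[float, float] | None = None
    ) -> np.ndarray:
        """diag(L C(theta) L') for a matrix of row contrasts, in one sweep
        over the blocks."""
        if theta is None:
            theta = (self.var_mouse, self.var_resid)
        s2m, s2e = theta
        lam = s2m / s2e
        v = np.zeros(L.shape[0])
        for blk, G in zip(self._blocks, self._block_matrices(lam)):
            Lb = L[:, blk.cells]
            if np.any(Lb):
                v += np.einsum("ij,ji->i", Lb, np.linalg.solve(G, Lb.T))
        return s2e * v

    def cov_beta(self) -> np.ndarray:
        """Dense covariance of the observed-cell estimates (block diagonal)."""
        P = int(self.observed.sum())
        C = np.zeros((P, P))
        pos = {c: i for i, c in enumerate(np.flatnonzero(self.observed))}
        for blk, G in zip(self._blocks, self._block_matrices(self.ratio)):
            idx = [pos[c] for c in blk.cells]
            C[np.ix_(idx, idx)] = self.var_resid * np.linalg.inv(G)
        return C

    def satterthwaite_df(self, ell: np.ndarray) -> float:
        """Satterthwaite df for a single contrast by the delta method."""
        return float(self.satterthwaite_dfs(ell[None, :])[0])

    def satterthwaite_dfs(self, L: np.ndarray) -> np.ndarray:
        """Satterthwaite dfs for a matrix of row contrasts (batched: five
        block sweeps regardless of the number of contrasts)."""
        resid_df = float(self.n_obs - int(self.observed.sum()))
        if self.boundary or self._theta_cov is None or self.degenerate:
            return np.full(L.shape[0], resid_df)
        theta = np.array([self.var_mouse, self.var_resid])
        v0 = self.contrast_variances(L)
        grads = np.zeros((L.shape[0], 2))
        for i in range(2):
            h = max(1e-4 * theta[i], 1e-10)
            tp, tm = theta.copy(), theta.copy()
            tp[i] += h
            tm[i] = max(tm[i] - h, 1e-12 if i == 1 else 0.0)
            grads[:, i] = (
                self.contrast_variances(L, tuple(tp)) - self.contrast_variances(L, tuple(tm))
            ) / (tp[i] - tm[i])
        denom = np.einsum("ij,jk,ik->i", grads, self._theta_cov, grads)
        with np.errstate(invalid="ignore", divide="ignore"):
            nu = 2.0 * v0 * v0 / denom
        bad = ~np.isfinite(nu) | (nu <= 0) | (denom <= 0)
        nu[bad] = resid_df
        return nu


def _prepare(data: pd.DataFrame, response: str, fixed: tuple[str, ...], group: str):
    df = data.dropna(subset=[response]).copy()
    if df[group].nunique() < 2:
        raise ValueError("need at least two groups (mice) to separate variance components")
    levels = {f: sorted(pd.unique(df[f]).tolist()) for f in fixed}
    cells = list(itertools.product(*[levels[f] for f in fixed])) if fixed else [()]
    cell_pos = {c: i for i, c in enumerate(cells)}
    if fixed:
        keys = list(zip(*[df[f] for f in fixed]))
        cell_id = np.array([cell_pos[k] for k in keys])
    else:
        cell_id = np.zeros(len(df), dtype=int)
    return df, levels, cells, cell_id


def _build_blocks(df: pd.DataFrame, response: str, group: str, cell_id: np.ndarray, n_cells: int):
    """Union-find cells connected through shared mice; build per-mouse stats."""
    parent = np.arange(n_cells)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    y = df[response].to_numpy(dtype=float)
    gvals = df[group].to_numpy()
    order = np.argsort(gvals, kind="mergesort")
    mouse_rows: dict = {}
    for idx in order:
        mouse_rows.setdefault(gvals[idx], []).append(idx)
    for rows in mouse_rows.values():
        c0 = find(cell_id[rows[0]])
        for r in rows[1:]:
            c = find(cell_id[r])
            if c != c0:
                parent[c] = c0
    observed_cells = np.unique(cell_id)
    roots = {}
    for c in observed_cells:
        roots.setdefault(find(c), []).append(c)

    blocks: list[_Block] = []
    cell_local: dict[int, tuple[int, int]] = {}
    for root_cells in roots.values():
        cells_arr = np.array(sorted(root_cells))
        for j, c in enumerate(cells_arr):
            cell_local[c] = (len(blocks), j)
        blocks.append(
            _Block(cells=cells_arr, mice=[], cell_n=np.zeros(len(cells_arr)),
                   cell_ysum=np.zeros(len(cells_arr)))
        )
    for mouse, rows in mouse_rows.items():
        rows = np.array(rows)
        bi, _ = cell_local[cell_id[rows[0]]]
        blk = blocks[bi]
        local = np.array([cell_local[c][1] for c in cell_id[rows]])
        counts = np.bincount(local, minlength=len(blk.cells)).astype(float)
        ysum = np.bincount(local, weights=y[rows], minlength=len(blk.cells))
        used = np.flatnonzero(counts)
        md = _MouseData(
            block=bi, cells=used, counts=counts[used], ysum=ysum[used],
            n=len(rows), ytot=float(y[rows].sum()), yy=float(y[rows] @ y[rows]),
        )
        blk.mice.append(md)
        blk.cell_n += counts
        blk.cell_ysum += ysum
    return blocks, cell_local, observed_cells


def _reml_deviance(blocks: list[_Block], lam: float, n_obs: int):
    """Profiled REML deviance at ratio lam; returns (dev, beta_blocks, rss, logdets)."""
    rss = 0.0
    logdet_v = 0.0
    logdet_xtx = 0.0
    betas = []
    p = sum(len(b.cells) for b in blocks)
    for blk in blocks:
        G = np.diag(blk.cell_n.astype(float))
        h = blk.cell_ysum.copy()
        yy = 0.0
        for m in blk.mice:
            w = lam / (1.0 + lam * m.n)
            logdet_v += np.log1p(lam * m.n)
            if w != 0.0:
                G[np.ix_(m.cells, m.cells)] -= w * np.outer(m.counts, m.counts)
                h[m.cells] -= w * m.ytot * m.counts
            yy += m.yy - w * m.ytot**2
        sign, ld = np.linalg.slogdet(G)
        if sign <= 0:
            return np.inf, None, np.inf, (np.nan, np.nan)
        logdet_xtx += ld
        beta = np.linalg.solve(G, h)
        betas.append(beta)
        rss += yy - float(h @ beta)
    rss = max(rss, 0.0)
    nmp = n_obs - p
    if nmp <= 0:
        raise ValueError("no residual degrees of freedom")
    if rss <= 0:
        return -np.inf, betas, rss, (logdet_v, logdet_xtx)
    s2e = rss / nmp
    dev = nmp * np.log(s2e) + logdet_v + logdet_xtx + nmp + nmp * np.log(2 * np.pi)
    return dev, betas, rss, (logdet_v, logdet_xtx)


def _full_deviance(blocks, s2m: float, s2e: float, n_obs: int) -> float:
    """REML deviance as a function of both variance parameters."""
    lam = s2m / s2e
    rss = 0.0
    logdet_v = 0.0
    logdet_xtx = 0.0
    p = sum(len(b.cells) for b in blocks)
    for blk in blocks:
        G = np.diag(blk.cell_n.astype(float))
        h = blk.cell_ysum.copy()
        yy = 0.0
        for m in blk.mice:
            w = lam / (1.0 + lam * m.n)
            logdet_v += np.log1p(lam * m.n)
            if w != 0.0:
                G[np.ix_(m.cells, m.cells)] -= w * np.outer(m.counts, m.counts)
                h[m.cells] -= w * m.ytot * m.counts
            yy += m.yy - w * m.ytot**2
        _, ld = np.linalg.slogdet(G)
        logdet_xtx += ld
        beta = np.linalg.solve(G, h)
        rss += yy - float(h @ beta)
    nmp = n_obs - p
    return nmp * np.log(s2e) + logdet_v + logdet_xtx + rss / s2e + nmp * np.log(2 * np.pi)


def fit_lmm(
    data: pd.DataFrame,
    response: str = "distance",
    fixed: tuple[str, ...] = ("day", "treatment_group", "strain"),
    group: str = "mouse_id",
) -> LMMFit:
    """REML fit of the full-factorial cell-means model with a random
    intercept per `group`.

    The restricted likelihood is profiled over lam = s2_mouse / s2_e and
    minimized by bounded scalar search on log(lam) (tolerance 1e-8 on the
    ratio), with the lam = 0 boundary checked explicitly. Boundary
    estimates are reported as exact zeros.
    """
    df, levels, cells, cell_id = _prepare(data, response, fixed, group)
    # mouse-level factors must be constant within a mouse
    for f in fixed:
        if f == "day":
            continue
        nun = df.groupby(group, sort=False)[f].nunique()
        if (nun > 1).any():
            raise ValueError(f"factor {f!r} varies within a group; not a valid design")
    n_obs = len(df)
    blocks, cell_local, observed_cells = _build_blocks(df, response, group, cell_id, len(cells))
    p = len(observed_cells)
    if n_obs - p <= 0:
        raise RankDeficiencyError(
            "saturated design: no residual degrees of freedom (one observation per cell)"
        )

    def objective(u: float) -> float:
        return _reml_deviance(blocks, np.exp(u), n_obs)[0]

    grid = np.linspace(_LOG_LAM_LO, _LOG_LAM_HI, 33)
    vals = np.array([objective(u) for u in grid])
    k = int(np.argmin(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        objective, bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-10},
    )
    lam = float(np.exp(res.x))
    dev = float(res.fun)
    dev0, *_ = _reml_deviance(blocks, 0.0, n_obs)
    boundary = False
    if dev0 <= dev + 1e-9 or lam < 1e-7:
        # profile maximized at (or indistinguishably near) the boundary
        lam, dev, boundary = 0.0, float(dev0), True

    dev, betas, rss, _ = _reml_deviance(blocks, lam, n_obs)
    degenerate = False
    s2e = rss / (n_obs - p)
    if not np.isfinite(dev) or s2e <= 1e-300:
        degenerate = True
        s2e = 0.0
        warnings.warn("residual variance is (numerically) zero; fit flagged degenerate")
    s2m = lam * s2e

    beta_full = np.full(len(cells), np.nan)
    for blk, b in zip(blocks, betas):
        beta_full[blk.cells] = b
    observed_mask = np.zeros(len(cells), dtype=bool)
    observed_mask[observed_cells] = True

    fit = LMMFit(
        factors=fixed, levels=levels, cells=cells, observed=observed_mask,
        beta=beta_full, var_mouse=s2m, var_resid=s2e,
        reml_loglik=-0.5 * dev if np.isfinite(dev) else np.nan,
        n_obs=n_obs, n_groups=df[group].nunique(),
        boundary=boundary, degenerate=degenerate, group=group,
        _blocks=blocks, _cell_to_block=cell_local,
    )
    if not boundary and not degenerate:
        fit._theta_cov = _theta_covariance(blocks, s2m, s2e, n_obs)
    return fit


def _theta_covariance(blocks, s2m, s2e, n_obs) -> np.ndarray | None:
    """Asymptotic covariance of (s2_mouse, s2_e): twice the inverse Hessian
    of the REML deviance, by central finite differences."""
    theta = np.array([s2m, s2e])
    h = np.maximum(1e-4 * theta, 1e-10)

    def d(t):
        return _full_deviance(blocks, max(t[0], 0.0), max(t[1], 1e-300), n_obs)

    H = np.zeros((2, 2))
    f0 = d(theta)
    for i in range(2):
        for j in range(i, 2):
            if i == j:
                e = np.zeros(2); e[i] = h[i]
                H[i, i] = (d(theta + e) - 2 * f0 + d(theta - e)) / h[i] ** 2
            else:
                ei = np.zeros(2); ei[i] = h[i]
                ej = np.zeros(2); ej[j] = h[j]
                H[i, j] = H[j, i] = (
                    d(theta + ei + ej) - d(theta + ei - ej)
                    - d(theta - ei + ej) + d(theta - ei - ej)
                ) / (4 * h[i] * h[j])
    try:
        cov = 2.0 * np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None
    if not np.all(np.isfinite(cov)) or cov[0, 0] < 0 or cov[1, 1] < 0:
        return None
    return cov


# -- Type III ANOVA -----------------------------------------------------------

def _diff_matrix(a: int) -> np.ndarray:
    D = np.zeros((a - 1, a))
    for i in range(a - 1):
        D[i, i], D[i, i + 1] = 1.0, -1.0
    return D


def _term_contrast(fit: LMMFit, term_factors: tuple[str, ...]) -> np.ndarray:
    parts = []
    for f in fit.factors:
        a = len(fit.levels[f])
        if f in term_factors:
            parts.append(_diff_matrix(a))
        else:
            parts.append(np.full((1, a), 1.0 / a))
    L = parts[0]
    for Pm in parts[1:]:
        L = np.kron(L, Pm)
    return L


def _all_terms(factors: tuple[str, ...]) -> list[tuple[str, ...]]:
    terms = []
    for r in range(1, len(factors) + 1):
        terms.extend(itertools.combinations(factors, r))
    return terms


def anova_table(fit: LMMFit) -> list[AnovaRow]:
    """Type III Wald F tests for every main effect and interaction, with
    Satterthwaite denominator df.

    Requires the full factorial of cells to be observed (otherwise the
    marginal means are aliased). For multi-df terms the df come from the
    eigen-decomposition of the contrast covariance, combining per-direction
    Satterthwaite dfs; if the variance-parameter covariance is unavailable
    (boundary or ill-conditioned Hessian) the residual df are used and the
    row is annotated.
    """
    if not fit.observed.all():
        missing = [fit.cells[i] for i in np.flatnonzero(~fit.observed)][:5]
        raise RankDeficiencyError(f"empty cells alias Type III terms, e.g. {missing}")
    rows: list[AnovaRow] = []
    resid_df = float(fit.n_obs - int(fit.observed.sum()))
    fallback = fit.boundary or fit.degenerate or fit._theta_cov is None
    for term in _all_terms(fit.factors):
        L = _term_contrast(fit, term)
        q = L.shape[0]
        est = L @ fit.beta
        M = np.zeros((q, q))
        lam = fit.ratio if np.isfinite(fit.ratio) else 0.0
        for blk, G in zip(fit._blocks, fit._block_matrices(lam)):
            Lb = L[:, blk.cells]
            if np.any(Lb):
                M += fit.var_resid * (Lb @ np.linalg.solve(G, Lb.T))
        if fit.degenerate:
            rows.append(AnovaRow(":".join(term), np.inf, q, resid_df, 0.0, "degenerate fit"))
            continue
        Fstat = float(est @ np.linalg.solve(M, est)) / q
        note = ""
        if fallback:
            nu = resid_df
            note = "residual df (no Satterthwaite)"
        else:
            evals, evecs = np.linalg.eigh(M)
            nus = fit.satterthwaite_dfs(evecs.T @ L)
            ok = nus > 2
            if ok.sum() == 0:
                nu, note = resid_df, "residual df (Satterthwaite unstable)"
            else:
                E = float(np.sum(nus[ok] / (nus[ok] - 2.0)))
                nu = 2.0 * E / (E - ok.sum()) if E > ok.sum() else resid_df
        pval = float(stats.f.sf(Fstat, q, nu))
        rows.append(AnovaRow(":".join(term), Fstat, float(q), float(nu), pval, note))
    return rows


# -- Tukey HSD ----------------------------------------------------------------

def tukey_hsd(
    means: np.ndarray,
    se_diff: np.ndarray,
    df: float,
    labels: list[str] | None = None,
) -> pd.DataFrame:
    """All-pairs comparisons via the studentized range distribution.

    `se_diff` is the matrix of standard errors of pairwise differences;
    q_ij = |m_i - m_j| / (se_ij / sqrt(2)) and p = P(Q_{k,df} > q).
    At k = 2 this reduces exactly to the two-sided t-test.
    """
    means = np.asarray(means, dtype=float)
    k = len(means)
    if k < 2:
        raise ValueError("need at least two means")
    if df <= 0:
        raise ValueError("df must be positive")
    se_diff = np.asarray(se_diff, dtype=float)
    labels = labels if labels is not None else [str(i) for i in range(k)]
    recs = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = means[i] - means[j]
            se = se_diff[i, j]
            q = np.abs(diff) / (se / np.sqrt(2.0)) if se > 0 else np.inf
            p = float(stats.studentized_range.sf(q, k, df)) if np.isfinite(q) else 0.0
            recs.append((labels[i], labels[j], diff, se, q, min(max(p, 0.0), 1.0)))
    return pd.DataFrame(recs, columns=["a", "b", "difference", "se", "q", "p_tukey"])


# -- responder classification -------------------------------------------------

def classify_responders(fit: LMMFit, alpha: float = 0.05) -> list[ContrastResult]:
    """Per-strain cocaine - saline contrast of marginal means (averaged over
    days), with Tukey adjustment over the family of all strain x treatment
    marginal means.

    A strain is a responder when the Tukey-adjusted p is below `alpha` and
    the cocaine arm is more active. Strains observed in only one arm are
    returned as inestimable. Both adjusted and unadjusted p-values are
    reported.
    """
    if "strain" not in fit.factors or "treatment_group" not in fit.factors:
        raise ValueError("fit must include strain and treatment_group factors")
    idx = {c: i for i, c in enumerate(fit.cells)}
    day_levels = fit.levels.get("day", [None])
    strains = fit.levels["strain"]
    fpos = {f: i for i, f in enumerate(fit.factors)}

    def cell_key(day, treat, strain):
        key = [None] * len(fit.factors)
        if "day" in fpos:
            key[fpos["day"]] = day
        key[fpos["treatment_group"]] = treat
        key[fpos["strain"]] = strain
        return tuple(key)

    # family size: all strain x treatment marginal means
    k_family = 2 * len(strains)
    ells: dict[str, np.ndarray] = {}
    for strain in strains:
        ell = np.zeros(len(fit.cells))
        estimable = True
        for treat, sign in (("cocaine", 1.0), ("saline", -1.0)):
            for day in day_levels:
                ci = idx[cell_key(day, treat, strain)]
                if not fit.observed[ci]:
                    estimable = False
                    break
                ell[ci] = sign / len(day_levels)
            if not estimable:
                break
        if estimable and not fit.degenerate:
            ells[strain] = ell

    results: list[ContrastResult] = []
    if ells:
        L = np.vstack(list(ells.values()))
        variances = fit.contrast_variances(L)
        dfs = fit.satterthwaite_dfs(L)
        beta0 = np.where(fit.observed, np.nan_to_num(fit.beta), 0.0)
        ests = L @ beta0
        stats_by_strain = dict(zip(ells, zip(ests, variances, dfs)))
    for strain in strains:
        if strain not in ells:
            results.append(
                ContrastResult(strain, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                               responder=False, estimable=False)
            )
            continue
        est, var, df = stats_by_strain[strain]
        est, df = float(est), float(df)
        se = float(np.sqrt(var))
        t = est / se if se > 0 else np.inf
        p_un = float(2.0 * stats.t.sf(abs(t), df))
        p_tk = float(stats.studentized_range.sf(np.sqrt(2.0) * abs(t), k_family, df))
        p_tk = min(max(p_tk, p_un), 1.0)
        results.append(
            ContrastResult(strain, est, se, t, df, p_un, p_tk,
                           responder=bool(p_tk < alpha and est > 0))
        )
    return results


def responder_count(results: list[ContrastResult]) -> int:
    return sum(r.responder for r in results if r.estimable)


# -- fixed-effects ANOVA (cross-site replicability) ---------------------------

def _sum_code(values: pd.Series, levels: list) -> np.ndarray:
    """Sum-to-zero (deviation) coding: a-1 columns, last level = -1 row."""
    a = len(levels)
    X = np.zeros((len(values), a - 1))
    pos = {lev: i for i, lev in enumerate(levels)}
    for r, v in enumerate(values):
        i = pos[v]
        if i < a - 1:
            X[r, i] = 1.0
        else:
            X[r, :] = -1.0
    return X


def anova_fixed(
    data: pd.DataFrame,
    response: str,
    factors: tuple[str, ...] = ("strain", "sex", "site"),
) -> list[AnovaRow]:
    """Type III fixed-effects ANOVA with all two-way interactions of the
    named factors, on one-row-per-mouse data.

    Uses sum-to-zero coding, under which dropping a term's columns from the
    full model yields the Type III test. Factors with a single observed
    level, and interaction terms aliased by empty cells, are dropped with a
    warning and reported with an annotation.
    """
    df = data.dropna(subset=[response]).copy()
    y = df[response].to_numpy(dtype=float)
    levels = {f: sorted(pd.unique(df[f]).tolist()) for f in factors}
    usable = [f for f in factors if len(levels[f]) > 1]
    dropped_rows = []
    for f in factors:
        if f not in usable:
            log.warning("factor %r has a single level; term dropped", f)
            dropped_rows.append(AnovaRow(f, np.nan, np.nan, np.nan, np.nan, "dropped: single level"))

    main_cols = {f: _sum_code(df[f], levels[f]) for f in usable}
    terms: list[tuple[str, ...]] = [(f,) for f in usable]
    terms += list(itertools.combinations(usable, 2))
    blocks: dict[tuple[str, ...], np.ndarray] = {}
    for term in terms:
        if len(term) == 1:
            blocks[term] = main_cols[term[0]]
        else:
            A, B = main_cols[term[0]], main_cols[term[1]]
            cols = [A[:, i] * B[:, j] for i in range(A.shape[1]) for j in range(B.shape[1])]
            blocks[term] = np.column_stack(cols)

    def rss_of(design_blocks: list[np.ndarray]) -> tuple[float, int]:
        X = np.column_stack([np.ones(len(df))] + design_blocks)
        coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        return float(resid @ resid), rank

    full_rss, full_rank = rss_of(list(blocks.values()))
    n = len(df)
    df_resid = n - full_rank
    full_p = sum(b.shape[1] for b in blocks.values()) + 1
    aliased = full_p - full_rank
    rows: list[AnovaRow] = []
    for term in terms:
        reduced = [b for t, b in blocks.items() if t != term]
        red_rss, red_rank = rss_of(reduced)
        q = full_rank - red_rank
        if q <= 0:
            log.warning("term %s is aliased (empty cells); dropped", term)
            rows.append(AnovaRow(":".join(term), np.nan, np.nan, np.nan, np.nan,
                                 "dropped: aliased"))
            continue
        note = "" if aliased == 0 else f"{aliased} aliased column(s) in full design"
        if df_resid <= 0 or full_rss <= 0:
            rows.append(AnovaRow(":".join(term), np.inf, float(q), float(df_resid), 0.0,
                                 "saturated"))
            continue
        F = ((red_rss - full_rss) / q) / (full_rss / df_resid)
        p = float(stats.f.sf(F, q, df_resid))
        rows.append(AnovaRow(":".join(term), float(F), float(q), float(df_resid), p, note))
    return rows + dropped_rows
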