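"""Per-cohort confounder-adjusted association models.

Diversity metrics and CLR species abundances are regressed on the 33
exposure terms (11 antibiotic classes x 3 look-back periods, number of
courses) plus covariates. Cohorts without family structure use ordinary
least squares; the family-structured cohort uses a linear model with a
family-level random intercept fitted by REML. The module also provides
restricted cubic splines (Harrell parameterization, 3 knots), estimated
marginal means with pairwise contrasts, the generalized variance inflation
factor, interaction likelihood-ratio tests (ML refits), and partial Spearman
correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("abxgut")

#: Covariate sets; basic is a subset of full. Categorical covariates are
#: dummy-coded dropping the first level; the plate label is always cohort
#: specific.
BASIC_NUMERIC: tuple[str, ...] = ("age",)
BASIC_CATEGORICAL: tuple[str, ...] = ("sex", "education", "smoking", "birth_country", "plate")
FULL_NUMERIC: tuple[str, ...] = ("age", "bmi")
FULL_CATEGORICAL: tuple[str, ...] = BASIC_CATEGORICAL + (
    "charlson2", "polypharmacy", "ppi", "metformin", "ssri",
    "statin", "beta_blocker", "antipsychotic",
)


def covariate_sets(which: str) -> tuple[tuple[str, ...], tuple[str, ...]]:
    if which == "basic":
        return BASIC_NUMERIC, BASIC_CATEGORICAL
    if which == "full":
        return FULL_NUMERIC, FULL_CATEGORICAL
    raise ValueError(f"unknown covariate set {which!r}")


def build_design(
    data: pd.DataFrame,
    numeric: Sequence[str] = (),
    categorical: Sequence[str] = (),
    intercept: bool = True,
) -> pd.DataFrame:
    """Design matrix: intercept, numeric columns, and dummy-coded categoricals
    (first level dropped). Binary 0/1 flags may be listed as categorical."""
    parts = []
    if intercept:
        parts.append(pd.DataFrame({"Intercept": np.ones(len(data))}, index=data.index))
    if numeric:
        parts.append(data[list(numeric)].astype(float))
    for col in categorical:
        s = data[col]
        if s.dtype.kind in "biufc" and s.nunique(dropna=True) <= 2:
            parts.append(s.astype(float).to_frame(col))
            continue
        d = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
        parts.append(d)
    if not parts:
        return pd.DataFrame(index=data.index)
    return pd.concat(parts, axis=1)


def _check_rank(X: pd.DataFrame) -> None:
    """Raise listing aliased columns if the design is rank deficient."""
    Xv = X.to_numpy(dtype=float)
    _, R, piv = _qr_pivot(Xv)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(Xv.shape) * np.finfo(float).eps
    bad = piv[np.flatnonzero(diag < tol)] if (diag < tol).any() else []
    deficient = len(diag) < Xv.shape[1] or len(bad) > 0
    if deficient:
        names = [X.columns[i] for i in bad] or list(X.columns[len(diag):])
        raise ValueError(f"design matrix is rank deficient; aliased terms: {names}")


def _qr_pivot(X):
    from scipy.linalg import qr

    Q, R, piv = qr(X, mode="economic", pivoting=True)
    return Q, R, piv


def _drop_constant_covariates(X: pd.DataFrame, protected: Sequence[str]) -> pd.DataFrame:
    """Drop zero-variance covariate columns (a flag with no carriers in a
    small cohort); protected columns (intercept, exposures) are kept and
    still trip the rank check if constant."""
    keep = []
    dropped = []
    for c in X.columns:
        if c == "Intercept" or c in protected or X[c].nunique() > 1:
            keep.append(c)
        else:
            dropped.append(c)
    if dropped:
        logger.info("dropping %d constant covariate column(s): %s", len(dropped), dropped)
    return X[keep]


@dataclass
class AssociationResult:
    """Fit summary for one outcome in one cohort."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    cov: pd.DataFrame
    df_resid: float
    llf: float
    n: int
    method: str  # "ols" | "mixedlm"
    exposure_terms: list[str] = field(default_factory=list)

    def table(self) -> pd.DataFrame:
        """Long (term, beta, se, p) table for the exposure terms."""
        t = self.exposure_terms
        return pd.DataFrame(
            {"term": t, "beta": self.params[t].values, "se": self.bse[t].values,
             "p": self.pvalues[t].values}
        )


def drop_sparse_exposures(
    data: pd.DataFrame, exposure_cols: Sequence[str], min_exposed: int = 5
) -> list[str]:
    """Exposure terms with more than ``min_exposed`` exposed individuals.

    Used in stratified analyses where a stratum may hold too few exposed
    individuals for a stable estimate; dropped terms are logged.
    """
    kept, dropped = [], []
    for c in exposure_cols:
        if (data[c] > 0).sum() > min_exposed:
            kept.append(c)
        else:
            dropped.append(c)
    if dropped:
        logger.info("drop_sparse_exposures: dropped %d term(s): %s", len(dropped), dropped)
    return kept


def fit_association(
    data: pd.DataFrame,
    outcome: str,
    exposure_cols: Sequence[str],
    covariates: str | tuple[Sequence[str], Sequence[str]] = "full",
    group: str | None = None,
    reml: bool = True,
) -> AssociationResult:
    """Fit one confounder-adjusted linear model (complete-case).

    OLS when ``group`` is None; otherwise a linear model with a random
    intercept per level of ``data[group]`` fitted by REML (or ML when
    ``reml=False``, as needed for likelihood-ratio tests). A rank-deficient
    design raises, listing the aliased terms.
    """
    numeric, categorical = (
        covariate_sets(covariates) if isinstance(covariates, str) else covariates
    )
    used = [outcome, *exposure_cols, *numeric, *categorical] + ([group] if group else [])
    d = data[used].dropna()
    X = pd.concat(
        [
            build_design(d, numeric=(), categorical=()),  # intercept
            d[list(exposure_cols)].astype(float),
            build_design(d, numeric, categorical, intercept=False),
        ],
        axis=1,
    )
    X = _drop_constant_covariates(X, protected=list(exposure_cols))
    _check_rank(X)
    y = d[outcome].astype(float)

    import statsmodels.api as sm

    if group is None:
        fit = sm.OLS(y.to_numpy(), X.to_numpy()).fit()
        cov = pd.DataFrame(fit.cov_params(), index=X.columns, columns=X.columns)
        res = AssociationResult(
            params=pd.Series(fit.params, index=X.columns),
            bse=pd.Series(fit.bse, index=X.columns),
            pvalues=pd.Series(fit.pvalues, index=X.columns),
            cov=cov, df_resid=float(fit.df_resid), llf=float(fit.llf),
            n=len(d), method="ols", exposure_terms=list(exposure_cols),
        )
    else:
        # standardize columns (intercept excluded) for optimizer stability;
        # a pure linear reparameterization, mapped back afterwards
        Xv = X.to_numpy(dtype=float)
        scale = Xv.std(axis=0)
        scale[X.columns.get_loc("Intercept")] = 1.0
        scale[scale == 0] = 1.0
        model = sm.MixedLM(y.to_numpy(), Xv / scale, groups=d[group].to_numpy())
        with np.errstate(all="ignore"):
            try:
                fit = model.fit(reml=reml, method=["bfgs", "cg"])
            except np.linalg.LinAlgError:
                fit = model.fit(reml=reml, method="powell")
        k = X.shape[1]
        cov_s = np.asarray(fit.cov_params())[:k, :k]
        cov = pd.DataFrame(
            cov_s / np.outer(scale, scale), index=X.columns, columns=X.columns
        )
        params = np.asarray(fit.params)[:k] / scale
        bse = np.asarray(fit.bse)[:k] / scale
        res = AssociationResult(
            params=pd.Series(params, index=X.columns),
            bse=pd.Series(bse, index=X.columns),
            pvalues=pd.Series(np.asarray(fit.pvalues)[:k], index=X.columns),
            cov=cov, df_resid=float(len(d) - k), llf=float(fit.llf),
            n=len(d), method="mixedlm", exposure_terms=list(exposure_cols),
        )
    return res


def fit_many_ols(
    data: pd.DataFrame,
    outcomes: pd.DataFrame,
    exposure_cols: Sequence[str],
    covariates: str | tuple[Sequence[str], Sequence[str]] = "full",
) -> pd.DataFrame:
    """OLS of many outcomes (species) on one shared design, factored fit.

    Returns a long DataFrame (outcome, term, beta, se, p) over the exposure
    terms. Equivalent to calling :func:`fit_association` per outcome but
    computes the pseudo-inverse once.
    """
    numeric, categorical = (
        covariate_sets(covariates) if isinstance(covariates, str) else covariates
    )
    used = [*exposure_cols, *numeric, *categorical]
    d = data[used].dropna()
    Y = outcomes.loc[d.index].to_numpy(dtype=float)
    X = pd.concat(
        [
            build_design(d, numeric=(), categorical=()),
            d[list(exposure_cols)].astype(float),
            build_design(d, numeric, categorical, intercept=False),
        ],
        axis=1,
    )
    X = _drop_constant_covariates(X, protected=list(exposure_cols))
    _check_rank(X)
    Xv = X.to_numpy(dtype=float)
    n, p = Xv.shape
    XtX_inv = np.linalg.inv(Xv.T @ Xv)
    B = XtX_inv @ (Xv.T @ Y)  # p x n_outcomes
    resid = Y - Xv @ B
    df = n - p
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))
    tstat = B / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
    idx = [X.columns.get_loc(c) for c in exposure_cols]
    rows = []
    for k, name in enumerate(outcomes.columns):
        for j, term in zip(idx, exposure_cols):
            rows.append((name, term, B[j, k], se[j, k], pvals[j, k]))
    return pd.DataFrame(rows, columns=["outcome", "term", "beta", "se", "p"])


# ---------------------------------------------------------------------------
# Restricted cubic splines and estimated marginal means
# ---------------------------------------------------------------------------


def rcs_basis(x, knots) -> np.ndarray:
    """Harrell-parameterized restricted cubic spline basis with 3 knots.

    Column 1 is x; column 2 is
    [(x-k1)+^3 - (x-k2)+^3 (k3-k1)/(k3-k2) + (x-k3)+^3 (k2-k1)/(k3-k2)]
    / (k3-k1)^2. The expansion is linear for x <= k1 and x >= k3.
    """
    k1, k2, k3 = (float(k) for k in knots)
    if not (k1 < k2 < k3):
        raise ValueError(f"knots must be strictly increasing, got {knots}")
    x = np.asarray(x, dtype=float)

    def cube(v):
        return np.clip(v, 0.0, None) ** 3

    num = (
        cube(x - k1)
        - cube(x - k2) * (k3 - k1) / (k3 - k2)
        + cube(x - k3) * (k2 - k1) / (k3 - k2)
    )
    return np.column_stack([x, num / (k3 - k1) ** 2])


def default_knots(x) -> tuple[float, float, float]:
    """Knots at the 10th/50th/90th percentiles, collapsed to the nearest
    distinct observed values; error if fewer than 3 distinct values."""
    x = np.asarray(x, dtype=float)
    distinct = np.unique(x)
    if distinct.size < 3:
        raise ValueError("default_knots: fewer than 3 distinct values")
    qs = np.quantile(x, [0.1, 0.5, 0.9])
    knots = []
    for q in qs:
        cand = distinct[np.argmin(np.abs(distinct - q))]
        knots.append(cand)
    out = sorted(set(knots))
    i = 0
    while len(out) < 3 and i < distinct.size:  # fill from remaining observed values
        v = distinct[i]
        if v not in out:
            out.append(v)
        i += 1
    return tuple(sorted(out)[:3])


@dataclass
class EmmGrid:
    """Estimated marginal means over a course-count grid for one period."""

    period: str
    grid: np.ndarray
    emm: np.ndarray
    se: np.ndarray
    contrasts: pd.DataFrame  # columns a, b, diff, se, p, q


def emm_curve(
    data: pd.DataFrame,
    outcome: str,
    period_cols: dict[str, str],
    target_period: str,
    covariates: str | tuple[Sequence[str], Sequence[str]] = "full",
    grid: Sequence[int] = (0, 1, 2, 3, 4),
    knots: dict[str, tuple[float, float, float]] | None = None,
) -> EmmGrid:
    """EMMs of the outcome at fixed course counts of one period.

    All periods' pooled course counts enter one linear model, each coded with
    a 3-knot restricted cubic spline, plus covariates. EMM(c) is the average
    over the observed covariate rows of the prediction with the target
    period's count set to c (for a linear model this equals the prediction
    with categorical covariates weighted by observed frequencies and
    continuous ones at their means). Pairwise differences use the delta
    contrast against the fit covariance; q-values are Benjamini-Hochberg
    within the returned contrast family.
    """
    from .meta import bh_fdr

    numeric, categorical = (
        covariate_sets(covariates) if isinstance(covariates, str) else covariates
    )
    used = [outcome, *period_cols.values(), *numeric, *categorical]
    d = data[used].dropna()
    knots = dict(knots or {})
    for per, col in period_cols.items():
        knots.setdefault(per, default_knots(d[col]))

    def spline_block(values, per):
        b = rcs_basis(values, knots[per])
        return pd.DataFrame(
            b, columns=[f"{per}_rcs1", f"{per}_rcs2"], index=d.index
        )

    blocks = [spline_block(d[col].astype(float), per) for per, col in period_cols.items()]
    X = pd.concat(
        [build_design(d, numeric=(), categorical=()), *blocks,
         build_design(d, numeric, categorical, intercept=False)],
        axis=1,
    )
    spline_cols = [c for b in blocks for c in b.columns]
    X = _drop_constant_covariates(X, protected=spline_cols)
    _check_rank(X)
    y = d[outcome].astype(float).to_numpy()
    Xv = X.to_numpy(dtype=float)
    XtX_inv = np.linalg.inv(Xv.T @ Xv)
    beta = XtX_inv @ (Xv.T @ y)
    resid = y - Xv @ beta
    df = Xv.shape[0] - Xv.shape[1]
    V = XtX_inv * float(resid @ resid / df)

    obs_max = d[period_cols[target_period]].max()
    a_vecs = {}
    for c in grid:
        if c > obs_max:
            logger.warning(
                "emm_curve: grid point %s outside observed range (max %s): extrapolating",
                c, obs_max,
            )
        Xc = X.copy()
        sb = rcs_basis(np.full(len(d), float(c)), knots[target_period])
        Xc[f"{target_period}_rcs1"] = sb[:, 0]
        Xc[f"{target_period}_rcs2"] = sb[:, 1]
        a_vecs[c] = Xc.to_numpy(dtype=float).mean(axis=0)

    emm = np.array([a_vecs[c] @ beta for c in grid])
    se = np.array([np.sqrt(a_vecs[c] @ V @ a_vecs[c]) for c in grid])

    rows = []
    for i, a in enumerate(grid):
        for b_ in list(grid)[i + 1:]:
            dvec = a_vecs[a] - a_vecs[b_]
            diff = float(dvec @ beta)
            dse = float(np.sqrt(dvec @ V @ dvec))
            pval = float(2 * stats.t.sf(abs(diff / dse), df))
            rows.append((a, b_, diff, dse, pval))
    contrasts = pd.DataFrame(rows, columns=["a", "b", "diff", "se", "p"])
    contrasts["q"] = bh_fdr(contrasts["p"].to_numpy())
    return EmmGrid(
        period=target_period, grid=np.asarray(list(grid), dtype=float),
        emm=emm, se=se, contrasts=contrasts,
    )


# ---------------------------------------------------------------------------
# Collinearity, interactions, partial correlations
# ---------------------------------------------------------------------------


def gvif(X: pd.DataFrame, blocks: dict[str, Sequence[str]]) -> pd.DataFrame:
    """Generalized variance inflation factor per term block.

    On the correlation matrix R of the centered model matrix (intercept
    excluded): GVIF = det(R11) det(R22) / det(R), where R11 is the block's
    own correlation submatrix. Also reports GVIF^(1/(2 d)) with d the number
    of columns in the block.
    """
    cols = [c for c in X.columns if c != "Intercept"]
    M = X[cols].to_numpy(dtype=float)
    if (M.std(axis=0) == 0).any():
        const = [c for c, s in zip(cols, M.std(axis=0)) if s == 0]
        raise ValueError(f"gvif: constant column(s) {const}")
    R = np.corrcoef(M, rowvar=False)
    det_R = np.linalg.det(R)
    idx = {c: i for i, c in enumerate(cols)}
    rows = []
    for name, members in blocks.items():
        i1 = [idx[c] for c in members]
        i2 = [i for i in range(len(cols)) if i not in i1]
        g = (
            np.linalg.det(R[np.ix_(i1, i1)])
            * np.linalg.det(R[np.ix_(i2, i2)])
            / det_R
        )
        d = len(i1)
        rows.append((name, d, g, g ** (1.0 / (2 * d))))
    return pd.DataFrame(rows, columns=["term", "df", "gvif", "gvif_adj"]).set_index("term")


def interaction_eligible(
    data: pd.DataFrame,
    class_period_cols: Sequence[str],
    modifier: str,
) -> bool:
    """Eligibility rules for interaction tests: with a binary sex modifier,
    >5 exposed men and women in all three periods; with continuous age, >10
    exposed in all three periods."""
    if modifier == "sex":
        for col in class_period_cols:
            by = data.groupby("sex", observed=True)[col].apply(lambda s: (s > 0).sum())
            if len(by) < 2 or (by <= 5).any():
                return False
        return True
    for col in class_period_cols:
        if (data[col] > 0).sum() <= 10:
            return False
    return True


def interaction_lrt(
    data: pd.DataFrame,
    outcome: str,
    class_period_cols: Sequence[str],
    modifier: str,
    all_exposure_cols: Sequence[str],
    covariates: str | tuple[Sequence[str], Sequence[str]] = "full",
    group: str | None = None,
) -> float:
    """Likelihood-ratio p-value for modifier-by-class interaction.

    The full model adds products of the class's three period terms with the
    modifier (sex coded as an indicator, age continuous and centered); the
    reduced model omits them. Both are ML fits (REML likelihoods are not
    comparable across fixed-effect structures); the statistic is referred to
    chi-square with df = number of added terms.
    """
    numeric, categorical = (
        covariate_sets(covariates) if isinstance(covariates, str) else covariates
    )
    d = data.dropna(
        subset=[outcome, *all_exposure_cols, *numeric, *categorical]
        + ([group] if group else [])
    ).copy()
    if modifier == "sex":
        levels = sorted(d["sex"].astype(str).unique())
        mod = (d["sex"].astype(str) == levels[-1]).astype(float)
    else:
        mod = d[modifier].astype(float)
        mod = mod - mod.mean()
    added = []
    for col in class_period_cols:
        name = f"{col}:x:{modifier}"
        d[name] = d[col].astype(float) * mod
        added.append(name)
    if not added:
        return 1.0  # reduced model equals full model

    def _llf(exposures):
        res = fit_association(
            d, outcome, exposures, covariates=(numeric, categorical),
            group=group, reml=False,
        )
        return res.llf

    ll_reduced = _llf(list(all_exposure_cols))
    ll_full = _llf(list(all_exposure_cols) + added)
    lr = max(0.0, 2.0 * (ll_full - ll_reduced))
    return float(stats.chi2.sf(lr, len(added)))


def partial_spearman(
    x, y, covariates: pd.DataFrame | None = None
) -> tuple[float, float]:
    """Partial Spearman correlation: Pearson correlation of rank residuals
    after removing the covariates from both rank-transformed variables.

    With no covariates this is the plain Spearman rho. The p-value uses the
    t reference with df = n - 2 - k. Zero-variance input is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("partial_spearman: zero-variance input")
    if covariates is None or covariates.shape[1] == 0:
        rho, p = stats.spearmanr(x, y)
        return float(rho), float(p)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    Z = covariates.to_numpy(dtype=float)
    Zr = np.column_stack([np.ones(len(Z))] + [stats.rankdata(z) for z in Z.T])
    ex = rx - Zr @ np.linalg.lstsq(Zr, rx, rcond=None)[0]
    ey = ry - Zr @ np.linalg.lstsq(Zr, ry, rcond=None)[0]
    rho = float(np.corrcoef(ex, ey)[0, 1])
    n, k = len(x), covariates.shape[1]
    df = n - 2 - k
    t = rho * np.sqrt(df / max(1e-300, 1.0 - rho**2))
    p = float(2 * stats.t.sf(abs(t), df))
    return rho, p
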