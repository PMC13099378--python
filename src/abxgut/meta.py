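"""Cross-cohort inference: fixed-effect meta-analysis, FDR, Fisher's method,
and the dfbeta robustness screen.

Per-cohort regression coefficients are pooled with inverse-variance weighted
fixed-effect meta-analysis; Cochran's Q and I-squared quantify between-cohort
heterogeneity. Associations that are significant after Benjamini-Hochberg
correction but heterogeneous (Q p < 0.05) are re-checked by removing the
single most influential observation (largest |dfbeta|) per cohort, refitting,
and re-pooling; an updated pooled p > 0.05 marks the association non-robust.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("abxgut")


@dataclass
class MetaRecord:
    """Pooled fixed-effect result for one term."""

    beta: float
    se: float
    z: float
    p: float
    cochran_q: float
    q_df: int
    q_pvalue: float
    i2: float  # percent, floored at 0
    cohort_betas: np.ndarray = field(default_factory=lambda: np.array([]))
    cohort_ses: np.ndarray = field(default_factory=lambda: np.array([]))


def fixed_effect_meta(betas, ses) -> MetaRecord:
    """Inverse-variance weighted fixed-effect pooling.

    w_i = 1/se_i^2; pooled beta = sum(w b)/sum(w); pooled se = sum(w)^-1/2;
    Q = sum w (b - pooled)^2 ~ chi2(k-1); I2 = max(0, (Q - (k-1))/Q) * 100.
    Two-sided normal p for the pooled estimate.
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size == 0:
        raise ValueError("fixed_effect_meta: no cohorts")
    if (s <= 0).any():
        raise ValueError("fixed_effect_meta: non-positive standard error")
    w = 1.0 / s**2
    pooled = float((w * b).sum() / w.sum())
    se = float(w.sum() ** -0.5)
    z = pooled / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    q = float((w * (b - pooled) ** 2).sum())
    k = b.size
    q_df = max(k - 1, 0)
    q_p = float(stats.chi2.sf(q, q_df)) if q_df > 0 else 1.0
    i2 = float(max(0.0, (q - q_df) / q) * 100.0) if q > 0 else 0.0
    return MetaRecord(
        beta=pooled, se=se, z=z, p=p,
        cochran_q=q, q_df=q_df, q_pvalue=q_p, i2=i2,
        cohort_betas=b, cohort_ses=s,
    )


def meta_table(long: pd.DataFrame, by: list[str]) -> pd.DataFrame:
    """Pool a long table of per-cohort results term-wise.

    ``long`` needs columns ``beta`` and ``se`` plus the grouping columns
    ``by`` (e.g. outcome and term); each group is pooled with
    :func:`fixed_effect_meta`. Returns one row per group.
    """
    rows = []
    for key, grp in long.groupby(by, observed=True, sort=False):
        m = fixed_effect_meta(grp["beta"].to_numpy(), grp["se"].to_numpy())
        key = key if isinstance(key, tuple) else (key,)
        rows.append(
            dict(zip(by, key))
            | {
                "beta": m.beta, "se": m.se, "z": m.z, "p": m.p,
                "cochran_q": m.cochran_q, "q_pvalue": m.q_pvalue, "i2": m.i2,
                "k": len(grp),
            }
        )
    return pd.DataFrame(rows)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q for the i-th smallest p is min over j >= i of p_(j) * m / j, capped at
    1; monotone in p.
    """
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def fisher_combine(pvalues) -> float:
    """Fisher's method: X = -2 sum ln p ~ chi2 with 2k df; returns survival p.

    Zero p-values are clipped at the smallest positive float with a warning.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("fisher_combine: empty input")
    if (p <= 0).any():
        logger.warning("fisher_combine: %d zero p-value(s) clipped", int((p <= 0).sum()))
        p = np.clip(p, np.finfo(float).tiny, 1.0)
    x = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(x, 2 * p.size))


# ---------------------------------------------------------------------------
# dfbeta robustness screen
# ---------------------------------------------------------------------------


def dfbetas_ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Leave-one-out coefficient changes for least squares, closed form.

    dfbeta_i = (X'X)^-1 x_i e_i / (1 - h_i): the change in the coefficient
    vector when observation i is deleted. Returns an (n, p) array.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta
    hat = np.einsum("ij,jk,ik->i", X, XtX_inv, X)
    return (X @ XtX_inv) * (resid / (1.0 - hat))[:, None]


def _refit_term(X: np.ndarray, y: np.ndarray, j: int) -> tuple[float, float]:
    """OLS beta and se of column j."""
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta
    df = X.shape[0] - X.shape[1]
    sigma2 = float(resid @ resid) / df
    return float(beta[j]), float(np.sqrt(sigma2 * XtX_inv[j, j]))


def _mixed_fit(X, y, groups):
    import statsmodels.api as sm

    scale = X.std(axis=0)
    scale[0] = 1.0
    scale[scale == 0] = 1.0
    with np.errstate(all="ignore"):
        fit = sm.MixedLM(y, X / scale, groups=groups).fit(
            reml=True, method=["bfgs", "cg"]
        )
    k = X.shape[1]
    params = np.asarray(fit.params)[:k] / scale
    bse = np.asarray(fit.bse)[:k] / scale
    sigma2 = float(fit.scale)
    tau2 = float(np.asarray(fit.cov_re).ravel()[0])
    return params, bse, sigma2, tau2


def _gls_beta(X, y, groups, sigma2, tau2, j) -> float:
    """GLS coefficient j under a single random intercept with the variance
    parameters held fixed: V_g = sigma2 I + tau2 J per group."""
    XtVX = X.T @ X / sigma2
    XtVy = X.T @ y / sigma2
    for g in pd.unique(groups):
        rows = np.flatnonzero(groups == g)
        m = len(rows)
        c = tau2 / (sigma2 * (sigma2 + m * tau2))
        sx = X[rows].sum(axis=0)
        sy = y[rows].sum()
        XtVX -= c * np.outer(sx, sx)
        XtVy -= c * sx * sy
    return float(np.linalg.solve(XtVX, XtVy)[j])


@dataclass
class ScreenResult:
    robust: bool
    updated: MetaRecord
    removed: list[int]  # positional index removed per cohort


def dfbeta_screen(
    cohorts: list[dict],
    term: int | str,
    alpha: float = 0.05,
    n_candidates: int = 50,
) -> ScreenResult:
    """Single-observation influence screen for one flagged term.

    ``cohorts`` is a list of dicts with keys ``X`` (DataFrame or array,
    intercept included), ``y``, and optionally ``groups`` (family labels for
    a random-intercept model). In each cohort the observation with the
    largest |dfbeta| for ``term`` is removed (closed form for least squares;
    refit over the ``n_candidates`` highest residual-leverage observations
    for random-intercept models), the model is refitted, and the updated
    per-cohort estimates are re-pooled. ``robust`` is True iff the updated
    pooled p <= alpha.

    Intended to run only for associations with q < 0.05 and Cochran's Q
    p < 0.05 (the caller enforces the trigger).
    """
    betas, ses, removed = [], [], []
    for c in cohorts:
        X = c["X"]
        cols = list(X.columns) if isinstance(X, pd.DataFrame) else None
        j = cols.index(term) if (cols is not None and isinstance(term, str)) else int(term)
        Xv = np.asarray(X, dtype=float)
        yv = np.asarray(c["y"], dtype=float)
        n, p = Xv.shape
        if n - 1 <= p:
            raise ValueError("dfbeta_screen: too few observations after removal")
        groups = c.get("groups")
        if groups is None:
            dfb = dfbetas_ols(Xv, yv)[:, j]
            drop = int(np.argmax(np.abs(dfb)))
            keep = np.ones(n, dtype=bool)
            keep[drop] = False
            try:
                b, s = _refit_term(Xv[keep], yv[keep], j)
            except np.linalg.LinAlgError:
                # removing the observation left the term inestimable in this
                # cohort (e.g. its only exposed individual); cohort drops out
                logger.info(
                    "dfbeta_screen: term inestimable after removal in one "
                    "cohort; cohort skipped"
                )
                continue
        else:
            groups = np.asarray(groups)
            params, _, sigma2, tau2 = _mixed_fit(Xv, yv, groups)
            b_full = params[j]
            # residual-leverage prefilter; candidate leave-one-out refits by
            # GLS with the variance parameters fixed at the full-fit values,
            # then one true REML refit for the chosen observation
            XtX_inv = np.linalg.inv(Xv.T @ Xv)
            beta_ols = XtX_inv @ (Xv.T @ yv)
            resid = yv - Xv @ beta_ols
            hat = np.einsum("ij,jk,ik->i", Xv, XtX_inv, Xv)
            score = np.abs(resid) * np.sqrt(hat / np.clip(1 - hat, 1e-12, None))
            cand = np.argsort(score)[::-1][: min(n_candidates, n)]
            best, best_df = None, -np.inf
            for i in cand:
                keep = np.ones(n, dtype=bool)
                keep[i] = False
                try:
                    b_i = _gls_beta(Xv[keep], yv[keep], groups[keep], sigma2, tau2, j)
                except np.linalg.LinAlgError:
                    continue
                if abs(b_full - b_i) > best_df:
                    best_df, best = abs(b_full - b_i), int(i)
            if best is None:
                logger.info("dfbeta_screen: no estimable removal; cohort skipped")
                continue
            drop = best
            keep = np.ones(n, dtype=bool)
            keep[drop] = False
            try:
                params_d, bse_d, _, _ = _mixed_fit(Xv[keep], yv[keep], groups[keep])
            except np.linalg.LinAlgError:
                logger.info(
                    "dfbeta_screen: term inestimable after removal in one "
                    "cohort; cohort skipped"
                )
                continue
            b, s = params_d[j], bse_d[j]
        betas.append(b)
        ses.append(s)
        removed.append(drop)
    if not betas:
        logger.info("dfbeta_screen: term=%s inestimable in every cohort -> non-robust", term)
        return ScreenResult(robust=False, updated=None, removed=removed)
    updated = fixed_effect_meta(betas, ses)
    robust = updated.p <= alpha
    logger.info(
        "dfbeta_screen: term=%s updated p=%.3g -> %s",
        term, updated.p, "robust" if robust else "non-robust",
    )
    return ScreenResult(robust=robust, updated=updated, removed=removed)
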