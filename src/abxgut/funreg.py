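"""Scalar-on-function regression of diversity on monthly exposure history.

The 96-month binary exposure history of each antibiotic class is a
functional predictor X_j(t); its coefficient beta_j(t) — the expected change
in the diversity outcome associated with exposure in month t before sampling
— is expanded in a cubic B-spline basis, which reduces the fit to an
ordinary multiple regression of the outcome on per-basis projected exposure
scores plus covariates. Pointwise standard errors come from a participant
bootstrap (family-block resampling where a family grouping exists), and
per-month estimates are pooled across cohorts by fixed-effect meta-analysis.

Rarely prescribed classes (cephalosporins, macrolides, amoxicillin-
clavulanic acid, sulfamethoxazole-trimethoprim, nitrofurantoin) are merged
into one predictor — the elementwise OR of their monthly matrices — for
model stability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .exposure import ANTIBIOTIC_CLASSES, N_MONTHS
from .meta import fixed_effect_meta

logger = logging.getLogger("abxgut")

RARE_CLASSES: tuple[str, ...] = (
    "cephalosporins", "macrolides", "amox_clav", "smz_tmp", "nitrofurantoin",
)
MERGED_CLASS = "rare_combined"
RETAINED_CLASSES: tuple[str, ...] = tuple(
    c for c in ANTIBIOTIC_CLASSES if c not in RARE_CLASSES
)
FUNCTIONAL_CLASSES: tuple[str, ...] = RETAINED_CLASSES + (MERGED_CLASS,)


def merge_rare_classes(monthly: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Reduce 11 class matrices to 7 predictors (6 retained + merged OR).

    Retained classes are passed through unchanged; the merged matrix cell is
    1 iff any of the five rare classes was used in that month.
    """
    out = {c: monthly[c] for c in RETAINED_CLASSES}
    merged = np.zeros_like(monthly[RARE_CLASSES[0]])
    for c in RARE_CLASSES:
        merged = merged | (monthly[c] > 0)
    out[MERGED_CLASS] = merged.astype(monthly[RARE_CLASSES[0]].dtype)
    return out


def bspline_basis(n_basis: int = 6, n_months: int = N_MONTHS) -> np.ndarray:
    """Cubic B-spline basis evaluated at month midpoints.

    ``n_basis`` cubic B-splines on [0, n_months] with ``n_basis - 4`` equally
    spaced interior knots, evaluated at t = m - 0.5 for m = 1..n_months.
    Returns an (n_months, n_basis) matrix.
    """
    if n_basis < 4:
        raise ValueError("n_basis must be >= 4 for a cubic basis")
    n_interior = n_basis - 4
    interior = np.linspace(0, n_months, n_interior + 2)[1:-1]
    t = np.concatenate([[0.0] * 4, interior, [float(n_months)] * 4])
    x = np.arange(1, n_months + 1) - 0.5
    return BSpline.design_matrix(x, t, k=3).toarray()


@dataclass
class FunctionalCurve:
    """beta(t) on the monthly grid with pointwise uncertainty."""

    abx_class: str
    months: np.ndarray  # 1..96
    beta: np.ndarray
    se: np.ndarray | None = None

    @property
    def ci_lower(self) -> np.ndarray:
        return self.beta - 1.96 * self.se

    @property
    def ci_upper(self) -> np.ndarray:
        return self.beta + 1.96 * self.se


@dataclass
class FunFit:
    """Point-estimate fit of the scalar-on-function model."""

    curves: dict[str, FunctionalCurve]
    coefs: dict[str, np.ndarray]  # per-class basis coefficients
    basis: np.ndarray             # (n_months, K)
    skipped: list[str] = field(default_factory=list)


def fit_scalar_on_function(
    y: np.ndarray,
    monthly: dict[str, np.ndarray],
    covar_X: np.ndarray,
    n_basis: int = 6,
    basis: np.ndarray | None = None,
    ridge: float = 0.0,
) -> FunFit:
    """Fit beta_j(t) for every class predictor jointly.

    Each participant contributes, per class j and basis function phi_k, the
    projected score sum_t X_j(t) phi_k(t); the outcome is regressed on these
    scores plus the covariate design (which must include an intercept). A
    class with an all-zero exposure matrix is skipped with a log entry. An
    optional ridge penalty on the basis coefficients is off by default.
    """
    y = np.asarray(y, dtype=float)
    covar_X = np.asarray(covar_X, dtype=float)
    n = y.shape[0]
    first = next(iter(monthly.values()))
    n_months = first.shape[1]
    Phi = bspline_basis(n_basis, n_months) if basis is None else np.asarray(basis, float)
    K = Phi.shape[1]

    classes, score_blocks, skipped = [], [], []
    for name, M in monthly.items():
        M = np.asarray(M, dtype=float)
        if M.shape != (n, n_months):
            raise ValueError(f"monthly matrix for {name!r} has shape {M.shape}")
        if not M.any():
            skipped.append(name)
            logger.info("fit_scalar_on_function: class %r never used; skipped", name)
            continue
        classes.append(name)
        score_blocks.append(M @ Phi)

    if not classes:
        raise ValueError("fit_scalar_on_function: no usable class predictors")
    X = np.hstack([covar_X] + score_blocks)
    p = X.shape[1]
    if ridge > 0:
        pen = np.zeros(p)
        pen[covar_X.shape[1]:] = ridge
        XtX = X.T @ X + np.diag(pen)
        beta = np.linalg.solve(XtX, X.T @ y)
    else:
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        if rank < p:
            raise np.linalg.LinAlgError(
                f"functional design rank deficient ({rank} < {p})"
            )
    months = np.arange(1, n_months + 1)
    curves, coefs = {}, {}
    off = covar_X.shape[1]
    for i, name in enumerate(classes):
        b = beta[off + i * K: off + (i + 1) * K]
        coefs[name] = b
        curves[name] = FunctionalCurve(abx_class=name, months=months, beta=Phi @ b)
    return FunFit(curves=curves, coefs=coefs, basis=Phi, skipped=skipped)


def bootstrap_pointwise_se(
    y: np.ndarray,
    monthly: dict[str, np.ndarray],
    covar_X: np.ndarray,
    n_boot: int = 200,
    seed: int = 0,
    families: np.ndarray | None = None,
    n_basis: int = 6,
    basis: np.ndarray | None = None,
    max_retries: int = 10,
) -> dict[str, np.ndarray]:
    """Bootstrap pointwise SE of beta_j(t).

    Participants are resampled with replacement (whole families when
    ``families`` is given), the model refitted, and the SE at each month is
    the standard deviation of beta_j(t) across replicates. A rank-deficient
    replicate is redrawn, up to ``max_retries`` times, then raises.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    point = fit_scalar_on_function(y, monthly, covar_X, n_basis=n_basis, basis=basis)
    names = list(point.curves)
    draws = {name: [] for name in names}

    if families is not None:
        families = np.asarray(families)
        fam_ids = pd.unique(families)
        fam_rows = {f: np.flatnonzero(families == f) for f in fam_ids}

    for _ in range(n_boot):
        for attempt in range(max_retries + 1):
            if families is None:
                idx = rng.integers(0, n, size=n)
            else:
                chosen = rng.integers(0, len(fam_ids), size=len(fam_ids))
                idx = np.concatenate([fam_rows[fam_ids[c]] for c in chosen])
            try:
                fit = fit_scalar_on_function(
                    y[idx], {k: v[idx] for k, v in monthly.items()},
                    np.asarray(covar_X, float)[idx],
                    n_basis=n_basis, basis=basis,
                )
                if set(fit.curves) != set(names):
                    raise np.linalg.LinAlgError("class dropped in replicate")
                break
            except np.linalg.LinAlgError:
                if attempt == max_retries:
                    raise
        for name in names:
            draws[name].append(fit.curves[name].beta)
    return {name: np.std(np.asarray(d), axis=0, ddof=1) for name, d in draws.items()}


def meta_curves(curves: list[FunctionalCurve]) -> FunctionalCurve:
    """Pool per-cohort curves month-wise by fixed-effect meta-analysis."""
    months = curves[0].months
    for c in curves[1:]:
        if not np.array_equal(c.months, months):
            raise ValueError("meta_curves: mismatched month grids")
    beta = np.empty(len(months))
    se = np.empty(len(months))
    for m in range(len(months)):
        rec = fixed_effect_meta(
            [c.beta[m] for c in curves], [c.se[m] for c in curves]
        )
        beta[m], se[m] = rec.beta, rec.se
    return FunctionalCurve(
        abx_class=curves[0].abx_class, months=months, beta=beta, se=se
    )


def curve_table(curves: dict[str, FunctionalCurve], cohort: str) -> pd.DataFrame:
    """Long (class, month, beta, se, lo, hi, cohort) table."""
    rows = []
    for name, c in curves.items():
        se = c.se if c.se is not None else np.full(len(c.months), np.nan)
        for m, b, s in zip(c.months, c.beta, se):
            rows.append((name, int(m), b, s, b - 1.96 * s, b + 1.96 * s, cohort))
    return pd.DataFrame(
        rows, columns=["abx_class", "month", "beta", "se", "lo", "hi", "cohort"]
    )
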