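"""Marginal and decorrelation-adjusted trait/age association.

Marginal association uses Spearman's rank correlation (monotone link)
and the correlation ratio eta-squared (variance in age explained by
stage groups). Because ordinal skeletal traits are strongly
inter-correlated, marginal ranking is myopic; CAR scores fix this by
sphering (Mahalanobis-whitening) the predictors first and taking the
correlations of the decorrelated predictors with age. Squared CAR
scores decompose the multiple R² of the full linear fit, which makes
CAR ranking a principled feature-ordering criterion.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def spearman_rho(stages: np.ndarray, ages: np.ndarray) -> tuple[float, float]:
    """Tie-corrected Spearman rank correlation and two-sided p-value.

    Returns (nan, nan) when either vector is constant.
    """
    stages = np.asarray(stages, dtype=float)
    ages = np.asarray(ages, dtype=float)
    keep = ~(np.isnan(stages) | np.isnan(ages))
    stages, ages = stages[keep], ages[keep]
    if len(stages) < 3:
        raise ValueError("spearman_rho requires at least 3 paired observations")
    if np.ptp(stages) == 0 or np.ptp(ages) == 0:
        return np.nan, np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.spearmanr(stages, ages)
    return float(res.statistic), float(res.pvalue)


def eta_squared(stages: np.ndarray, ages: np.ndarray) -> float:
    """Correlation ratio η²: between-stage sum of squares of age over the
    total sum of squares, treating each stage as a group."""
    stages = np.asarray(stages, dtype=float)
    ages = np.asarray(ages, dtype=float)
    keep = ~(np.isnan(stages) | np.isnan(ages))
    stages, ages = stages[keep], ages[keep]
    groups = np.unique(stages)
    if len(groups) < 2:
        raise ValueError("eta_squared requires at least 2 stage groups")
    sst = float(np.sum((ages - ages.mean()) ** 2))
    if sst == 0:
        return np.nan
    ssb = 0.0
    for g in groups:
        grp = ages[stages == g]
        ssb += len(grp) * (grp.mean() - ages.mean()) ** 2
    return float(ssb / sst)


# ---------------------------------------------------------------------
# sphering
# ---------------------------------------------------------------------

def shrink_correlation(X: np.ndarray) -> tuple[np.ndarray, float]:
    """Analytic convex shrinkage of the sample correlation matrix toward
    the identity (Schäfer–Strimmer estimator).

    Returns the shrunk correlation matrix and the shrinkage intensity
    λ* = Σ Var̂(r_ij) / Σ r_ij² over off-diagonal entries, clipped to
    [0, 1].
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    r = (xs.T @ xs) / (n - 1)
    w = xs[:, :, None] * xs[:, None, :]  # n × p × p products
    var_r = n / (n - 1) ** 3 * np.sum((w - w.mean(axis=0)) ** 2, axis=0)
    off = ~np.eye(p, dtype=bool)
    denom = float(np.sum(r[off] ** 2))
    lam = 1.0 if denom == 0 else float(np.clip(np.sum(var_r[off]) / denom, 0.0, 1.0))
    r_shrunk = (1 - lam) * r + lam * np.eye(p)
    return r_shrunk, lam


def _inv_sqrt(R: np.ndarray) -> np.ndarray:
    """Symmetric inverse square root via eigendecomposition."""
    evals, evecs = np.linalg.eigh(R)
    if evals.min() <= 1e-12:
        raise np.linalg.LinAlgError("correlation matrix numerically singular")
    return evecs @ np.diag(evals**-0.5) @ evecs.T


def sphere(
    X: np.ndarray, shrinkage: bool | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Mahalanobis-whiten a column-standardised matrix.

    Returns ``(Z, W_sph)`` with ``Z = X @ W_sph`` and ``W_sph = R^{-1/2}``
    the symmetric inverse square root of the (optionally shrunk)
    correlation matrix, so that the empirical covariance of ``Z`` is the
    identity. ``shrinkage=None`` auto-applies shrinkage when the sample
    correlation matrix is singular or ill-conditioned (e.g. n ≤ p), with
    a warning.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    R = np.corrcoef(X, rowvar=False) if p > 1 else np.ones((1, 1))
    if shrinkage is None:
        cond_bad = n <= p or not np.isfinite(R).all() or np.linalg.cond(R) > 1e10
        if cond_bad:
            warnings.warn(
                "sample correlation matrix ill-conditioned; "
                "applying analytic shrinkage toward the identity",
                stacklevel=2,
            )
        shrinkage = cond_bad
    if shrinkage:
        R, lam = shrink_correlation(X)
        logger.info("correlation shrinkage intensity %.4f", lam)
    w_sph = _inv_sqrt(R)
    return X @ w_sph, w_sph


# ---------------------------------------------------------------------
# CAR scores
# ---------------------------------------------------------------------

@dataclass
class FeatureReport:
    """Per-trait association statistics and CAR-based ranking.

    ``table`` columns: rho, rho_p, rho_significant, eta2, car, car_t,
    car_p, car_significant, car_rank (1 = strongest |CAR|).
    """

    table: pd.DataFrame
    shrinkage_intensity: float | None = None

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="trait_id")


def car_scores(
    X: np.ndarray, y: np.ndarray, shrinkage: bool | None = None
) -> tuple[np.ndarray, float | None]:
    """CAR score vector ω = R^{-1/2} r_xy of standardized predictors.

    ``r_xy`` is the vector of marginal Pearson correlations between each
    (standardized) column of X and (standardized) y. Falls back to the
    shrinkage correlation estimator when R is singular.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    ys = (y - y.mean()) / y.std(ddof=1)
    r_xy = xs.T @ ys / (n - 1)
    lam = None
    try:
        _, w_sph = sphere(xs, shrinkage=shrinkage)
    except np.linalg.LinAlgError:
        logger.warning("singular correlation matrix; using shrinkage estimator")
        R, lam = shrink_correlation(xs)
        w_sph = _inv_sqrt(R)
    return w_sph @ r_xy, lam


def analyze_features(
    stages: pd.DataFrame,
    ages: pd.Series,
    alpha: float = 0.05,
    shrinkage: bool | None = None,
) -> FeatureReport:
    """Full marginal + CAR association report for a complete trait matrix.

    Traits enter as their integer stage codes (standardized internally).
    Significance flags are two-sided at ``alpha``, unadjusted; the CAR
    t-statistic uses n − 2 degrees of freedom on each decorrelated
    correlation.
    """
    y = ages.to_numpy(dtype=float)
    n = len(y)
    rows = {}
    for tid in stages.columns:
        x = stages[tid].to_numpy(dtype=float)
        rho, rho_p = spearman_rho(x, y)
        rows[tid] = {
            "rho": rho,
            "rho_p": rho_p,
            "rho_significant": bool(rho_p < alpha) if np.isfinite(rho_p) else False,
            "eta2": eta_squared(x, y),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")

    car, lam = car_scores(stages.to_numpy(), y, shrinkage=shrinkage)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = car * np.sqrt((n - 2) / np.clip(1 - car**2, 1e-12, None))
    car_p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    table["car"] = car
    table["car_t"] = t
    table["car_p"] = car_p
    table["car_significant"] = car_p < alpha
    order = np.argsort(-(car**2), kind="stable")
    rank = np.empty(len(car), dtype=int)
    rank[order] = np.arange(1, len(car) + 1)
    table["car_rank"] = rank
    return FeatureReport(table=table, shrinkage_intensity=lam)
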