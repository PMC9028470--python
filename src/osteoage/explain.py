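"""Global linear surrogate for interpreting network age estimates.

The network's cross-validated predictions are regressed (ordinary
least squares) on the sphered, standardized trait codes. Because the
sphered predictors have zero mean, the surrogate intercept is exactly
the average network estimate — a natural "baseline age" — and each
case's estimate decomposes additively into per-trait contributions in
years. The surrogate R² and residual spread quantify how faithful the
linear reading of the network is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .drnn import DRNNResults
from .features import _inv_sqrt, shrink_correlation, sphere

logger = logging.getLogger(__name__)


@dataclass
class SurrogateModel:
    """Additive linear approximation of a fitted network."""

    trait_ids: list[str]
    x_mean: np.ndarray
    x_scale: np.ndarray
    w_sph: np.ndarray          # sphering transform (R^{-1/2})
    coef: np.ndarray           # years per sphered-standardized unit
    intercept: float           # mean network estimate, years
    r2: float
    resid_sd: float            # surrogate approximation error spread, years

    def _sphered(self, x: np.ndarray) -> np.ndarray:
        return ((x - self.x_mean) / self.x_scale) @ self.w_sph

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return self._sphered(x) @ self.coef + self.intercept


@dataclass
class CaseExplanation:
    """Per-trait additive decomposition of one estimate."""

    contributions: pd.Series   # years, sorted by |contribution|
    baseline: float
    approximation: float       # baseline + sum of contributions
    resid_sd: float

    def __str__(self) -> str:
        lines = [f"baseline (mean estimate): {self.baseline:8.2f} years"]
        for tid, c in self.contributions.items():
            lines.append(f"  {tid:<12} {c:+8.2f}")
        lines.append(
            f"surrogate approximation:  {self.approximation:8.2f} years "
            f"(± {self.resid_sd:.2f} surrogate residual SD)"
        )
        return "\n".join(lines)


def fit_surrogate(results: DRNNResults) -> SurrogateModel:
    """Fit the linear surrogate on the network's LOO predictions."""
    x = results.model.exog.to_numpy(dtype=float)
    target = results.loo_predictions.to_numpy()
    x_mean = x.mean(axis=0)
    x_scale = x.std(axis=0)
    x_scale = np.where(x_scale > 0, x_scale, 1.0)
    xs = (x - x_mean) / x_scale
    try:
        z, w_sph = sphere(xs)
    except np.linalg.LinAlgError:
        logger.warning("rank-deficient traits; sphering with shrinkage")
        r, _ = shrink_correlation(xs)
        w_sph = _inv_sqrt(r)
        z = xs @ w_sph
    intercept = float(target.mean())
    coef, *_ = np.linalg.lstsq(z, target - intercept, rcond=None)
    resid = target - intercept - z @ coef
    sst = float(np.sum((target - intercept) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else np.nan
    return SurrogateModel(
        trait_ids=list(results.model.exog.columns),
        x_mean=x_mean,
        x_scale=x_scale,
        w_sph=w_sph,
        coef=coef,
        intercept=intercept,
        r2=r2,
        resid_sd=float(np.std(resid, ddof=1)),
    )


def explain_case(surrogate: SurrogateModel, x_row) -> CaseExplanation:
    """Decompose one individual's estimate into per-trait contributions.

    contribution_k = coefficient_k × sphered standardized value_k;
    baseline + Σ contributions equals the surrogate approximation of the
    network estimate exactly.
    """
    if isinstance(x_row, pd.Series):
        x_row = x_row[surrogate.trait_ids].to_numpy(dtype=float)
    x_row = np.asarray(x_row, dtype=float).ravel()
    if len(x_row) != len(surrogate.trait_ids):
        raise ValueError(
            f"expected {len(surrogate.trait_ids)} trait values, "
            f"got {len(x_row)}"
        )
    if np.isnan(x_row).any():
        raise ValueError("case has missing values; impute first")
    contrib = surrogate._sphered(x_row[None, :])[0] * surrogate.coef
    series = pd.Series(contrib, index=surrogate.trait_ids)
    series = series.reindex(series.abs().sort_values(ascending=False).index)
    return CaseExplanation(
        contributions=series,
        baseline=surrogate.intercept,
        approximation=surrogate.intercept + float(contrib.sum()),
        resid_sd=surrogate.resid_sd,
    )
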