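"""Regression uncertainty model (RUM) and prediction intervals.

Age-at-death errors are heteroskedastic: senescence variability grows
with age. Instead of a constant-width interval, the conditional spread
is learned by regressing absolute leave-one-out residuals on the
predicted age. The predicted absolute residual is scaled by
√(π/2) ≈ 1.2533 — the standard-deviation-to-mean-absolute-deviation
ratio of a Gaussian — to obtain a conditional standard deviation, and
the prediction interval is read off the quantiles of a Gaussian
truncated to plausible ages (by default bounded below at the training
minimum age).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .ridge import RidgeSolution, optimize_c

#: SD / E|X−μ| for a Gaussian: √(π/2) = 1.2533 to four decimals.
ABS_TO_SD = float(np.sqrt(np.pi / 2.0))


@dataclass
class PredictionInterval:
    point: np.ndarray
    sd: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    alpha: float


@dataclass
class UncertaintyModel:
    """Conditional-spread model mapping predicted age → standard deviation.

    ``family`` is ``"rvfl"`` (single random-layer network with skip
    connection, the default) or ``"linear"``. ``bounds`` are the
    truncation limits of the interval Gaussian in years; ``floor`` is the
    minimum predicted absolute residual (years), preventing zero-width
    intervals.
    """

    family: str
    x_mean: float
    x_scale: float
    layer_w: np.ndarray | None       # (2, width): weights row + bias row
    pre_mean: np.ndarray | None
    pre_scale: np.ndarray | None
    post_mean: np.ndarray | None
    post_scale: np.ndarray | None
    solution: RidgeSolution | None
    lin_coef: tuple[float, float] | None
    floor: float
    bounds: tuple[float, float]
    degenerate: bool = False
    scale_constant: float = field(default=ABS_TO_SD)

    # ---- residual regressor -----------------------------------------

    def _design(self, x: np.ndarray) -> np.ndarray:
        xs = (x - self.x_mean) / self.x_scale
        z = xs[:, None] * self.layer_w[0] + self.layer_w[1]
        z = (z - self.pre_mean) / self.pre_scale
        h = np.maximum(z, 0.0)
        h = (h - self.post_mean) / self.post_scale
        return np.column_stack([h, xs])

    def predict_abs_residual(self, point) -> np.ndarray:
        x = np.atleast_1d(np.asarray(point, dtype=float))
        if self.degenerate:
            return np.full(x.shape, self.floor)
        if self.family == "linear":
            a, b = self.lin_coef
            pred = a + b * (x - self.x_mean) / self.x_scale
        else:
            pred = self.solution.predict(self._design(x))
        return np.maximum(pred, self.floor)

    def predict_sd(self, point) -> np.ndarray:
        """Conditional standard deviation: √(π/2) × predicted |residual|."""
        return self.scale_constant * self.predict_abs_residual(point)

    # ---- intervals ---------------------------------------------------

    def interval(self, point, alpha: float = 0.05) -> PredictionInterval:
        """α/2 and 1−α/2 quantiles of a Gaussian centred at the point
        estimate with the conditional sd, truncated to ``bounds``."""
        if not 0 < alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        point = np.atleast_1d(np.asarray(point, dtype=float))
        sd = self.predict_sd(point)
        lb, ub = self.bounds
        # anchor far-out points a few sd beyond the bounds so the
        # truncated quantiles stay numerically defined (widest valid)
        lo_anchor = lb - 8.0 * sd if np.isfinite(lb) else -np.inf
        hi_anchor = ub + 8.0 * sd if np.isfinite(ub) else np.inf
        center = np.clip(point, lo_anchor, hi_anchor)
        if np.any(center != point):
            warnings.warn(
                "point estimate far outside truncation bounds; "
                "returning widest valid interval",
                stacklevel=2,
            )
        a = (lb - center) / sd if np.isfinite(lb) else np.full_like(point, -np.inf)
        b = (ub - center) / sd if np.isfinite(ub) else np.full_like(point, np.inf)
        lower = stats.truncnorm.ppf(alpha / 2, a, b, loc=center, scale=sd)
        upper = stats.truncnorm.ppf(1 - alpha / 2, a, b, loc=center, scale=sd)
        return PredictionInterval(
            point=point, sd=sd, lower=lower, upper=upper, alpha=alpha
        )


def fit_rum(
    loo_predictions: np.ndarray,
    y: np.ndarray,
    *,
    family: str = "rvfl",
    width: int | None = None,
    seed: int = 0,
    floor: float = 1.0,
    bounds: tuple[float, float] | None = None,
    c_exponents=None,
) -> UncertaintyModel:
    """Fit the regression uncertainty model on leave-one-out residuals.

    Regresses |y − loo_prediction| on loo_prediction with, by default, a
    single random-layer network (heuristic per-layer width, skip
    connection, PRESS-optimised ridge output). ``bounds`` default to
    [min(y), +∞).
    """
    x = np.asarray(loo_predictions, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("loo_predictions and y must be equal-length vectors")
    if len(x) < 10:
        raise ValueError("fit_rum requires at least 10 paired observations")
    if family not in ("rvfl", "linear"):
        raise ValueError(f"unknown residual regressor family {family!r}")
    t = np.abs(y - x)
    if bounds is None:
        bounds = (float(y.min()), np.inf)
    if bounds[0] >= bounds[1]:
        raise ValueError("lower truncation bound must be below the upper")

    x_mean, x_scale = float(x.mean()), float(x.std())
    x_scale = x_scale if x_scale > 0 else 1.0
    base = dict(
        family=family,
        x_mean=x_mean,
        x_scale=x_scale,
        layer_w=None,
        pre_mean=None,
        pre_scale=None,
        post_mean=None,
        post_scale=None,
        solution=None,
        lin_coef=None,
        floor=float(floor),
        bounds=bounds,
    )
    if np.allclose(t, 0.0):
        warnings.warn("all residuals are zero; uncertainty model floored",
                      stacklevel=2)
        return UncertaintyModel(**base, degenerate=True)

    xs = (x - x_mean) / x_scale
    if family == "linear":
        b1, b0 = np.polyfit(xs, t, 1)
        base["lin_coef"] = (float(b0), float(b1))
        return UncertaintyModel(**base)

    if width is None:
        from .drnn import architecture_heuristic

        width = architecture_heuristic(len(x)).width
    rng = np.random.default_rng(seed)
    w = rng.standard_normal((2, width))  # one input row + one bias row
    model = UncertaintyModel(**base)
    model.layer_w = w
    z = xs[:, None] * w[0] + w[1]
    model.pre_mean = z.mean(axis=0)
    s = z.std(axis=0)
    model.pre_scale = np.where(s > 0, s, 1.0)
    h = np.maximum((z - model.pre_mean) / model.pre_scale, 0.0)
    model.post_mean = h.mean(axis=0)
    s = h.std(axis=0)
    model.post_scale = np.where(s > 0, s, 1.0)
    d = model._design(x)
    kwargs = {} if c_exponents is None else {"exponents": tuple(c_exponents)}
    model.solution = optimize_c(d, t, **kwargs)
    return model
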