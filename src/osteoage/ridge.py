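"""Analytic ridge output layer: SVD solve, leverages and PRESS
leave-one-out, with regularization chosen on a power-of-two grid.

The output layer of a randomized network is a ridge regression with
penalty I/C (larger C = weaker shrinkage). With the thin SVD
D = U Σ Vᵀ of the centered/scaled design, the per-component shrinkage
factors are φ_i = σ_i² / (σ_i² + 1/C); the fitted values are
U diag(φ) Uᵀ y, the hat diagonal is h_ii = Σ_k φ_k U_ik², and the
leave-one-out residuals follow from the PRESS identity
r_i = (y_i − ŷ_i) / (1 − h_ii). A single SVD therefore prices the whole
C grid: only φ changes with C.

Centering and scaling statistics are frozen from the training design;
the leave-one-out identity is exact with respect to that frozen
preprocessing (the intercept is the training-target mean and is not
counted in the leverages, so Σ h_ii equals the effective degrees of
freedom Σ φ).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Paper-default exponent grid: C = 2^x, x ∈ {−6, −4, …, 12}.
DEFAULT_C_EXPONENTS = tuple(range(-6, 13, 2))


class RidgeError(ValueError):
    """Raised on degenerate ridge problems (interpolation, bad inputs)."""


@dataclass
class RidgeSolution:
    """Fitted ridge output layer on a frozen-standardization design."""

    beta: np.ndarray           # coefficients in scaled-design space
    c: float                   # regularization C (penalty is I/C)
    col_mean: np.ndarray
    col_scale: np.ndarray
    y_mean: float
    h: np.ndarray              # leverage diagonal (excl. intercept)
    fitted: np.ndarray         # in-sample predictions, original y scale
    loo: np.ndarray = field(default=None)       # LOO predictions
    e_loo: float = field(default=None)          # PRESS mean squared error

    def predict(self, D_new: np.ndarray) -> np.ndarray:
        Z = (np.asarray(D_new, dtype=float) - self.col_mean) / self.col_scale
        return Z @ self.beta + self.y_mean


def _standardize_columns(D: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = D.mean(axis=0)
    scale = D.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    return (D - mean) / scale, mean, scale


@dataclass
class _SVDFactors:
    """Thin SVD of the centered/scaled design, shared across the C grid."""

    u: np.ndarray
    s: np.ndarray
    vt: np.ndarray
    col_mean: np.ndarray
    col_scale: np.ndarray

    @classmethod
    def decompose(cls, D: np.ndarray) -> "_SVDFactors":
        D = np.asarray(D, dtype=float)
        if not np.isfinite(D).all():
            raise RidgeError("design matrix contains non-finite entries")
        Z, mean, scale = _standardize_columns(D)
        u, s, vt = np.linalg.svd(Z, full_matrices=False)
        return cls(u=u, s=s, vt=vt, col_mean=mean, col_scale=scale)

    def phi(self, c: float) -> np.ndarray:
        return self.s**2 / (self.s**2 + 1.0 / c)

    def solve(self, y: np.ndarray, c: float) -> RidgeSolution:
        y = np.asarray(y, dtype=float)
        if not np.isfinite(y).all():
            raise RidgeError("target vector contains non-finite entries")
        if c <= 0:
            raise RidgeError("C must be positive")
        y_mean = float(y.mean())
        yc = y - y_mean
        phi = self.phi(c)
        uty = self.u.T @ yc
        beta = self.vt.T @ (self.s / (self.s**2 + 1.0 / c) * uty)
        fitted = self.u @ (phi * uty) + y_mean
        h = np.einsum("ik,k,ik->i", self.u, phi, self.u)
        return RidgeSolution(
            beta=beta,
            c=float(c),
            col_mean=self.col_mean,
            col_scale=self.col_scale,
            y_mean=y_mean,
            h=h,
            fitted=fitted,
        )


def ridge_solve_svd(D: np.ndarray, y: np.ndarray, c: float) -> RidgeSolution:
    """Solve the ridge output layer (penalty I/C) for one value of C."""
    sol = _SVDFactors.decompose(D).solve(y, c)
    sol.loo, sol.e_loo = loo_press(sol, y)
    return sol


def loo_press(sol: RidgeSolution, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Analytic leave-one-out predictions and PRESS error.

    r_i = (y_i − ŷ_i)/(1 − h_ii); E_LOO = mean(r_i²); the LOO prediction
    for sample i is y_i − r_i. Raises when any leverage reaches 1
    (interpolating fit: C too large for the data).
    """
    y = np.asarray(y, dtype=float)
    if np.any(sol.h >= 1.0 - 1e-12):
        raise RidgeError("leverage h_ii >= 1: interpolating fit, reduce C")
    r = (y - sol.fitted) / (1.0 - sol.h)
    return y - r, float(np.mean(r**2))


def optimize_c(
    D: np.ndarray,
    y: np.ndarray,
    exponents: tuple[int, ...] = DEFAULT_C_EXPONENTS,
) -> RidgeSolution:
    """Pick C = 2^x from the grid by minimum PRESS leave-one-out error.

    A single SVD of the design is reused for every grid value. Grid
    members whose fit interpolates (some h_ii = 1) are skipped; if all
    do, an error is raised.
    """
    if not len(exponents):
        raise RidgeError("empty C grid")
    factors = _SVDFactors.decompose(D)
    y = np.asarray(y, dtype=float)
    best = None
    for x in exponents:
        sol = factors.solve(y, 2.0**x)
        try:
            sol.loo, sol.e_loo = loo_press(sol, y)
        except RidgeError:
            continue
        if best is None or sol.e_loo < best.e_loo:
            best = sol
    if best is None:
        raise RidgeError("every grid value of C produced an interpolating fit")
    return best
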