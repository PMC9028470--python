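"""Performance metrics and the Monte Carlo cross-validation harness.

Four properties of an age estimator are tracked: accuracy (mean
absolute error), bias (slope of residuals on known age — positive means
the classic over-young / under-old pattern), validity (empirical
coverage of the prediction intervals against the nominal level) and
efficiency (quantiles of the interval widths). The MCCV harness
repeatedly draws disjoint random train/test partitions, refits the
network and its uncertainty model on each training partition, and
aggregates the per-iteration metrics as median and 2.5/97.5% quantiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .drnn import DRNN, DRNNConfig
from .traits import ObservationMatrix, impute_nn1_jaccard

#: Quantiles reported for prediction-interval widths.
PIW_TAUS = (0.5, 0.025, 0.975)


# ---------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------

def mae(y, y_hat) -> float:
    """Mean absolute error in years."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.size == 0:
        raise ValueError("y and y_hat must be nonempty and aligned")
    return float(np.mean(np.abs(y - y_hat)))


def bias_slope(y, y_hat) -> float:
    """Slope of the regression of residuals e = y − ŷ on known y.

    Zero for an unbiased estimator; 1 for the mean predictor.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if len(y) < 3:
        raise ValueError("bias_slope requires at least 3 pairs")
    if np.var(y) == 0:
        raise ValueError("bias_slope undefined for constant y")
    e = y - y_hat
    return float(np.cov(y, e, ddof=1)[0, 1] / np.var(y, ddof=1))


def coverage(y, lower, upper) -> float:
    """Fraction of known values inside their closed intervals."""
    y = np.asarray(y, dtype=float)
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    if np.any(lower > upper):
        raise ValueError("interval with lower > upper")
    return float(np.mean((y >= lower) & (y <= upper)))


def piw(lower, upper, taus=PIW_TAUS) -> dict[float, float]:
    """Quantiles (linear interpolation) of the interval widths u − l."""
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    if lower.size == 0:
        raise ValueError("empty interval set")
    if np.any(lower > upper):
        raise ValueError("interval with lower > upper")
    widths = upper - lower
    return {t: float(np.quantile(widths, t)) for t in taus}


# ---------------------------------------------------------------------
# MCCV
# ---------------------------------------------------------------------

@dataclass
class MCCVConfig:
    """Monte Carlo cross-validation settings.

    ``B = 1000`` and 80% training mirror the reference experimental
    design; ``B = 50`` is a desk-scale default for quick assessment.
    ``trait_subset_fraction`` draws a fresh random subset of traits each
    iteration (the available-traits experiment); ``preset`` restricts to
    a named anatomical trait set. ``global_impute`` reproduces the
    impute-once-then-split order of operations instead of the
    leakage-safe default (impute the test partition from training
    donors only).
    """

    B: int = 50
    train_fraction: float = 0.8
    alpha: float = 0.05
    seed: int = 0
    trait_subset_fraction: float | None = None
    preset: str | None = None
    global_impute: bool = False
    drnn_config: DRNNConfig = field(default_factory=DRNNConfig)


@dataclass
class EvaluationReport:
    """Per-iteration MCCV metrics plus their aggregate quantiles."""

    iterations: pd.DataFrame      # B rows × metric columns
    summary: pd.DataFrame         # metric × {median, ci_low, ci_high}
    config: MCCVConfig

    def to_csv(self, iterations_path, summary_path) -> None:
        self.iterations.to_csv(iterations_path, index_label="iteration")
        self.summary.to_csv(summary_path, index_label="metric")


METRIC_COLUMNS = (
    "mae", "bias_slope", "coverage", "piw_median", "piw_low", "piw_high",
)


def split_sizes(n: int, train_fraction: float) -> tuple[int, int]:
    """Disjoint train/test partition sizes (train rounded, rest tested)."""
    n_train = int(round(n * train_fraction))
    if not 0 < n_train < n:
        raise ValueError("train fraction leaves an empty partition")
    return n_train, n - n_train


def _evaluate_split(
    train: ObservationMatrix,
    test: ObservationMatrix,
    cfg: MCCVConfig,
    seed: int,
) -> dict[str, float]:
    if not cfg.global_impute:
        train = impute_nn1_jaccard(train)
        test = impute_nn1_jaccard(test, donors=train)
    res = DRNN.from_observations(train, config=cfg.drnn_config).fit(seed=seed)
    pred = res.predict(test, alpha=cfg.alpha)
    y = test.ages.to_numpy()
    widths = piw(pred["lower"], pred["upper"])
    return {
        "mae": mae(y, pred["point"]),
        "bias_slope": bias_slope(y, pred["point"]),
        "coverage": coverage(y, pred["lower"], pred["upper"]),
        "piw_median": widths[0.5],
        "piw_low": widths[0.025],
        "piw_high": widths[0.975],
    }


def mccv(data: ObservationMatrix, config: MCCVConfig | None = None) -> EvaluationReport:
    """Monte Carlo cross-validation of the network + uncertainty model.

    Each iteration samples a disjoint train/test partition without
    replacement, optionally restricts the traits (named preset and/or a
    random fraction), fits the network and uncertainty model on the
    training rows, predicts the test rows with intervals at ``alpha``,
    and records the four metrics. Fully reproducible from ``config.seed``.
    """
    cfg = config or MCCVConfig()
    if cfg.B < 1:
        raise ValueError("B must be >= 1")
    if data.ages is None:
        raise ValueError("data must carry known ages")
    if cfg.preset is not None:
        data = data.subset_traits(data.schema.resolve_preset(cfg.preset))
    if cfg.global_impute:
        data = impute_nn1_jaccard(data)

    n = data.n_individuals
    n_train, _ = split_sizes(n, cfg.train_fraction)
    if n_train < 4:
        raise ValueError("training partition too small for the architecture")

    rng = np.random.default_rng(cfg.seed)
    rows = []
    index = np.asarray(data.individuals, dtype=object)
    trait_ids = np.asarray(data.trait_ids, dtype=object)
    for b in range(cfg.B):
        perm = rng.permutation(n)
        train_idx, test_idx = index[perm[:n_train]], index[perm[n_train:]]
        subset = data
        if cfg.trait_subset_fraction is not None:
            m = max(1, int(round(cfg.trait_subset_fraction * len(trait_ids))))
            chosen = rng.choice(len(trait_ids), size=m, replace=False)
            subset = data.subset_traits(list(trait_ids[np.sort(chosen)]))
        rows.append(_evaluate_split(
            subset.subset_individuals(train_idx),
            subset.subset_individuals(test_idx),
            cfg,
            seed=int(rng.integers(2**31 - 1)),
        ))

    iterations = pd.DataFrame(rows, columns=list(METRIC_COLUMNS))
    summary = pd.DataFrame({
        "median": iterations.median(),
        "ci_low": iterations.quantile(0.025),
        "ci_high": iterations.quantile(0.975),
    })
    return EvaluationReport(iterations=iterations, summary=summary, config=cfg)
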