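"""Deep randomized neural network regressor for age-at-death.

The learner is a deep random vector functional link network: every
hidden layer has fixed random weights and a ReLU nonlinearity, each
layer past the first receives the previous layer's activations
concatenated with the raw (standardized) input (skip connections), and
at every depth j the stacked design D(j) = [H(1) … H(j), X] feeds an
analytically solved ridge output layer whose regularization C is chosen
by PRESS leave-one-out error on a power-of-two grid. The final
prediction is the average of the per-depth estimates — an implicit
ensemble along the network depth, which stabilises the randomized fit.

Architecture is set from the training size n by a sizing heuristic:
with k = log2(n), the total number of randomized units is
S = 2^⌊log2(8·2^k/k)⌋ spread over L = 2^⌊log2 k⌋ equal layers
(n = 500 → 8 layers × 32 units = 256).

Shapes follow the statsmodels convention: :class:`DRNN` is constructed
from data and ``fit()`` returns a :class:`DRNNResults` carrying the
estimates, leave-one-out diagnostics, the uncertainty model, and a
``summary()`` table.
"""

from __future__ import annotations

import io
import json
import math
import os
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import uncertainty as unc
from .ridge import DEFAULT_C_EXPONENTS, RidgeSolution, optimize_c
from .schema import TraitSchema
from .traits import ObservationMatrix, ValidationError

SERIAL_VERSION = 1


# ---------------------------------------------------------------------
# architecture
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class Architecture:
    """Rectangular network topology derived from the training size."""

    n_train: int
    k: float
    total_units: int
    depth: int
    width: int


def architecture_heuristic(n: int) -> Architecture:
    """Size the network from the number of training samples.

    k = log2(n); total units S = 2^⌊log2(8·(2^k / k))⌋; depth
    L = 2^⌊log2(k)⌋; per-layer width S/L. Requires n ≥ 4 (k ≥ 2).
    """
    if n < 4:
        raise ValueError("architecture heuristic requires n >= 4")
    k = math.log2(n)
    total = 2 ** math.floor(math.log2(8.0 * (n / k)))
    depth = 2 ** math.floor(math.log2(k))
    return Architecture(
        n_train=n, k=k, total_units=total, depth=depth, width=total // depth
    )


# ---------------------------------------------------------------------
# random layers
# ---------------------------------------------------------------------

@dataclass
class RandomLayer:
    """Fixed random layer: weights (last row = bias) and the frozen
    pre-/post-activation standardization statistics."""

    w: np.ndarray
    pre_mean: np.ndarray | None = None
    pre_scale: np.ndarray | None = None
    post_mean: np.ndarray | None = None
    post_scale: np.ndarray | None = None


def init_layers(
    arch: Architecture,
    n_inputs: int,
    rng: np.random.Generator,
    distribution: str = "gaussian",
) -> list[RandomLayer]:
    """Draw the fixed random weights for all layers.

    Layer 1 maps the n_inputs traits; each deeper layer maps the
    previous layer's width activations concatenated with the inputs
    (skip connection). Weight shape is (fan_in + 1, width): the extra
    row is the bias.
    """
    if distribution not in ("gaussian", "uniform"):
        raise ValueError(f"unknown weight distribution {distribution!r}")
    layers = []
    for j in range(arch.depth):
        fan_in = n_inputs if j == 0 else arch.width + n_inputs
        if distribution == "gaussian":
            w = rng.standard_normal((fan_in + 1, arch.width))
        else:
            w = rng.uniform(-1.0, 1.0, size=(fan_in + 1, arch.width))
        layers.append(RandomLayer(w=w))
    return layers


def _safe_scale(s: np.ndarray) -> np.ndarray:
    return np.where(s > 0, s, 1.0)


def forward(
    layers: list[RandomLayer],
    xs: np.ndarray,
    *,
    train: bool,
    standardize_pre: bool = True,
    standardize_post: bool = True,
) -> list[np.ndarray]:
    """Propagate standardized inputs through the random layers.

    Returns the per-layer activation matrices H(1..L). With
    ``train=True`` the per-unit standardization statistics (before and
    after the ReLU) are estimated and stored on the layers; otherwise
    the stored training statistics are reused, making prediction-time
    designs reproduce training designs bit-exactly on training rows.
    """
    hs: list[np.ndarray] = []
    prev = None
    for layer in layers:
        inp = xs if prev is None else np.hstack([prev, xs])
        if inp.shape[1] + 1 != layer.w.shape[0]:
            raise ValidationError(
                f"layer input dimension {inp.shape[1]} incompatible with "
                f"weights of shape {layer.w.shape}"
            )
        z = inp @ layer.w[:-1] + layer.w[-1]
        if standardize_pre:
            if train:
                layer.pre_mean = z.mean(axis=0)
                layer.pre_scale = _safe_scale(z.std(axis=0))
            z = (z - layer.pre_mean) / layer.pre_scale
        h = np.maximum(z, 0.0)
        if standardize_post:
            if train:
                layer.post_mean = h.mean(axis=0)
                layer.post_scale = _safe_scale(h.std(axis=0))
            h = (h - layer.post_mean) / layer.post_scale
        hs.append(h)
        prev = h
    return hs


def stacked_designs(hs: list[np.ndarray], xs: np.ndarray) -> list[np.ndarray]:
    """Per-depth output-layer designs D(j) = [H(1) … H(j), X]."""
    designs = []
    for j in range(len(hs)):
        designs.append(np.hstack(hs[: j + 1] + [xs]))
    return designs


# ---------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------

@dataclass
class DRNNConfig:
    """Tunable settings for the network and its uncertainty model.

    Defaults follow the reference parameterization: C grid 2^x with
    x ∈ {−6, −4, …, 12}, Gaussian random weights, architecture from the
    sizing heuristic, alpha = 0.05 intervals truncated below at the
    training minimum age.
    """

    c_exponents: tuple[int, ...] = DEFAULT_C_EXPONENTS
    weight_distribution: str = "gaussian"
    depth: int | None = None
    width: int | None = None
    alpha: float = 0.05
    standardize_pre: bool = True
    standardize_post: bool = True
    rum_family: str = "rvfl"
    sd_floor: float = 1.0
    truncation: tuple[float, float] | None = None
    noise_sd: float = 0.0  # reserved hook; only 0.0 is supported

    def __post_init__(self) -> None:
        if self.noise_sd != 0.0:
            raise NotImplementedError(
                "additive Gaussian noise injection is a reserved hook"
            )


# ---------------------------------------------------------------------
# model
# ---------------------------------------------------------------------

class DRNN:
    """Deep randomized network age-at-death model.

    Parameters
    ----------
    endog : array-like
        Known ages-at-death in years.
    exog : DataFrame, ndarray or ObservationMatrix
        Complete (imputed) individuals × traits stage matrix.
    schema : TraitSchema, optional
        Trait metadata; taken from ``exog`` when it is an
        ObservationMatrix. Enables stage-code validation at predict time.
    config : DRNNConfig, optional
    """

    def __init__(self, endog, exog, schema: TraitSchema | None = None,
                 config: DRNNConfig | None = None):
        if isinstance(exog, ObservationMatrix):
            schema = schema or exog.schema
            if endog is None:
                endog = exog.ages
            exog = exog.stages
        if isinstance(exog, pd.DataFrame):
            x = exog.astype(float)
        else:
            x = pd.DataFrame(np.asarray(exog, dtype=float))
            x.columns = [str(c) for c in x.columns]
        if x.isna().to_numpy().any():
            raise ValidationError(
                "exog contains missing values; impute first "
                "(osteoage.traits.impute_nn1_jaccard)"
            )
        if endog is None:
            raise ValidationError("endog (ages) is required")
        y = pd.Series(np.asarray(endog, dtype=float), index=x.index, name="age")
        if not np.isfinite(y.to_numpy()).all():
            raise ValidationError("ages must be finite")
        if y.nunique() < 2:
            raise ValidationError("constant ages: nothing to regress on")
        if len(y) != len(x):
            raise ValidationError("endog and exog lengths differ")
        self.endog = y
        self.exog = x
        self.schema = schema
        self.config = config or DRNNConfig()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, age_col: str = "age",
                       schema: TraitSchema | None = None,
                       config: DRNNConfig | None = None) -> "DRNN":
        df = df.copy()
        if age_col not in df.columns:
            raise ValidationError(f"age column {age_col!r} not found")
        y = df.pop(age_col)
        return cls(y, df, schema=schema, config=config)

    @classmethod
    def from_observations(cls, obs: ObservationMatrix,
                          config: DRNNConfig | None = None) -> "DRNN":
        if obs.ages is None:
            raise ValidationError("observations carry no ages")
        return cls(obs.ages, obs, config=config)

    # ---- fitting -----------------------------------------------------

    def fit(self, seed: int = 0) -> "DRNNResults":
        """Fit the per-depth ridge output layers and uncertainty model."""
        cfg = self.config
        x = self.exog.to_numpy()
        y = self.endog.to_numpy()
        n, p = x.shape

        arch = architecture_heuristic(n)
        if cfg.depth is not None or cfg.width is not None:
            depth = cfg.depth or arch.depth
            width = cfg.width or arch.width
            arch = Architecture(
                n_train=n, k=math.log2(n), total_units=depth * width,
                depth=depth, width=width,
            )

        x_mean = x.mean(axis=0)
        x_scale = _safe_scale(x.std(axis=0))
        xs = (x - x_mean) / x_scale

        rng = np.random.default_rng(seed)
        layers = init_layers(arch, p, rng, cfg.weight_distribution)
        hs = forward(
            layers, xs, train=True,
            standardize_pre=cfg.standardize_pre,
            standardize_post=cfg.standardize_post,
        )
        solutions: list[RidgeSolution] = []
        loo_by_depth = []
        fit_by_depth = []
        for d in stacked_designs(hs, xs):
            sol = optimize_c(d, y, exponents=tuple(cfg.c_exponents))
            solutions.append(sol)
            loo_by_depth.append(sol.loo)
            fit_by_depth.append(sol.fitted)

        loo = np.mean(loo_by_depth, axis=0)
        fitted = np.mean(fit_by_depth, axis=0)

        bounds = cfg.truncation or (float(y.min()), np.inf)
        rum = unc.fit_rum(
            loo, y,
            family=cfg.rum_family,
            seed=int(rng.integers(2**31 - 1)),
            floor=cfg.sd_floor,
            bounds=bounds,
            c_exponents=cfg.c_exponents,
        )
        return DRNNResults(
            model=self,
            architecture=arch,
            layers=layers,
            solutions=solutions,
            x_mean=x_mean,
            x_scale=x_scale,
            loo_predictions=pd.Series(loo, index=self.exog.index, name="loo"),
            fitted=pd.Series(fitted, index=self.exog.index, name="fitted"),
            rum=rum,
            seed=seed,
        )


# ---------------------------------------------------------------------
# results
# ---------------------------------------------------------------------

@dataclass
class DRNNResults:
    """Fitted deep randomized network with diagnostics.

    Attributes
    ----------
    loo_predictions : Series
        Cross-validated (analytic leave-one-out, ensembled over depth)
        age predictions in years for the training individuals.
    fitted : Series
        In-sample ensemble predictions.
    rum : UncertaintyModel
        Residual-based conditional-spread model for intervals.
    """

    model: DRNN
    architecture: Architecture
    layers: list[RandomLayer]
    solutions: list[RidgeSolution]
    x_mean: np.ndarray
    x_scale: np.ndarray
    loo_predictions: pd.Series
    fitted: pd.Series
    rum: unc.UncertaintyModel
    seed: int

    # ---- diagnostics -------------------------------------------------

    @property
    def c_values(self) -> list[float]:
        return [s.c for s in self.solutions]

    @property
    def e_loo(self) -> list[float]:
        return [s.e_loo for s in self.solutions]

    @property
    def cv_mae(self) -> float:
        """Leave-one-out mean absolute error, years."""
        y = self.model.endog.to_numpy()
        return float(np.mean(np.abs(y - self.loo_predictions.to_numpy())))

    @property
    def cv_bias_slope(self) -> float:
        """Slope of LOO residuals on known age (0 = unbiased)."""
        y = self.model.endog.to_numpy()
        e = y - self.loo_predictions.to_numpy()
        return float(np.cov(y, e)[0, 1] / np.var(y, ddof=1))

    # ---- prediction --------------------------------------------------

    def _prepare_exog(self, exog) -> np.ndarray:
        trait_order = list(self.model.exog.columns)
        if isinstance(exog, ObservationMatrix):
            exog = exog.stages
        if isinstance(exog, pd.DataFrame):
            missing = [c for c in trait_order if c not in exog.columns]
            if missing:
                raise ValidationError(f"missing trait columns: {missing}")
            exog = exog[trait_order]
            x = exog.to_numpy(dtype=float)
        else:
            x = np.asarray(exog, dtype=float)
            if x.ndim == 1:
                x = x[None, :]
        if x.shape[1] != len(trait_order):
            raise ValidationError(
                f"expected {len(trait_order)} trait columns, got {x.shape[1]}"
            )
        if np.isnan(x).any():
            raise ValidationError("prediction input has missing values; impute first")
        if self.model.schema is not None:
            for j, tid in enumerate(trait_order):
                if tid in self.model.schema:
                    ns = self.model.schema[tid].n_stages
                    col = x[:, j]
                    if ((col < 0) | (col >= ns) | (col % 1 != 0)).any():
                        raise ValidationError(
                            f"trait {tid!r}: stage codes outside 0..{ns - 1}"
                        )
        return x

    def predict(self, exog, alpha: float | None = None):
        """Point estimates in years; with ``alpha``, a DataFrame with
        truncated-Gaussian interval bounds."""
        index = exog.stages.index if isinstance(exog, ObservationMatrix) else (
            exog.index if isinstance(exog, pd.DataFrame) else None
        )
        x = self._prepare_exog(exog)
        xs = (x - self.x_mean) / self.x_scale
        cfg = self.model.config
        hs = forward(
            self.layers, xs, train=False,
            standardize_pre=cfg.standardize_pre,
            standardize_post=cfg.standardize_post,
        )
        preds = [
            sol.predict(d)
            for sol, d in zip(self.solutions, stacked_designs(hs, xs))
        ]
        point = np.mean(preds, axis=0)
        if index is None:
            index = pd.RangeIndex(len(point))
        if alpha is None:
            return pd.Series(point, index=index, name="age_estimate")
        pi = self.rum.interval(point, alpha=alpha)
        return pd.DataFrame(
            {"point": pi.point, "sd": pi.sd, "lower": pi.lower, "upper": pi.upper},
            index=index,
        )

    # ---- summary -----------------------------------------------------

    def summary(self) -> str:
        a = self.architecture
        y = self.model.endog
        lines = [
            "Deep Randomized Neural Network — age-at-death regression",
            "=" * 60,
            f"n individuals:        {a.n_train}",
            f"n traits:             {self.model.exog.shape[1]}",
            f"architecture:         {a.depth} layers x {a.width} units "
            f"({a.total_units} total)",
            f"age range (train):    {y.min():.1f} - {y.max():.1f} years",
            f"seed:                 {self.seed}",
            "",
            "Per-depth output layers",
            "-" * 60,
            f"{'depth':>5} {'C':>10} {'E_LOO':>12} {'edof':>8}",
        ]
        for j, sol in enumerate(self.solutions, start=1):
            lines.append(
                f"{j:>5} {sol.c:>10.4g} {sol.e_loo:>12.4f} "
                f"{float(sol.h.sum()):>8.1f}"
            )
        cov = self._loo_coverage(self.model.config.alpha)
        lines += [
            "",
            "Cross-validated (LOO) ensemble diagnostics",
            "-" * 60,
            f"MAE:                  {self.cv_mae:.3f} years",
            f"bias slope:           {self.cv_bias_slope:.3f}",
            f"coverage (alpha={self.model.config.alpha:.2f}): {cov:.3f}",
            f"interval truncation:  [{self.rum.bounds[0]:.1f}, "
            f"{self.rum.bounds[1]:.1f}] years",
        ]
        return "\n".join(lines)

    def _loo_coverage(self, alpha: float) -> float:
        pi = self.rum.interval(self.loo_predictions.to_numpy(), alpha=alpha)
        y = self.model.endog.to_numpy()
        return float(np.mean((y >= pi.lower) & (y <= pi.upper)))

    # ---- plotting ----------------------------------------------------

    def plot_fit(self, ax=None):
        """Known vs LOO-predicted age scatter with the identity line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        y = self.model.endog.to_numpy()
        ax.scatter(y, self.loo_predictions.to_numpy(), s=12, alpha=0.6)
        lims = [min(y.min(), self.loo_predictions.min()),
                max(y.max(), self.loo_predictions.max())]
        ax.plot(lims, lims, "r--", lw=1)
        ax.set_xlabel("known age-at-death (years)")
        ax.set_ylabel("LOO predicted age (years)")
        return ax

    # ---- serialization ----------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write a versioned archive (atomically) with everything needed
        to reload and predict."""
        path = Path(path)
        cfg = self.model.config
        meta = {
            "version": SERIAL_VERSION,
            "seed": self.seed,
            "trait_ids": list(self.model.exog.columns),
            "individuals": [str(i) for i in self.model.exog.index],
            "config": {**asdict(cfg),
                       "c_exponents": list(cfg.c_exponents),
                       "truncation": list(cfg.truncation) if cfg.truncation
                       else None},
            "architecture": asdict(self.architecture),
            "rum": {
                "family": self.rum.family,
                "x_mean": self.rum.x_mean,
                "x_scale": self.rum.x_scale,
                "floor": self.rum.floor,
                "bounds": [self.rum.bounds[0],
                           None if np.isinf(self.rum.bounds[1])
                           else self.rum.bounds[1]],
                "degenerate": self.rum.degenerate,
                "lin_coef": list(self.rum.lin_coef) if self.rum.lin_coef
                else None,
            },
            "schema": [
                {"trait_id": t.trait_id, "n_stages": t.n_stages,
                 "bilateral": t.bilateral, "block": t.block}
                for t in (self.model.schema or [])
            ] or None,
        }
        arrays = {
            "x_mean": self.x_mean,
            "x_scale": self.x_scale,
            "endog": self.model.endog.to_numpy(),
            "exog": self.model.exog.to_numpy(),
            "loo": self.loo_predictions.to_numpy(),
            "fitted": self.fitted.to_numpy(),
        }
        for i, layer in enumerate(self.layers):
            arrays[f"layer{i}_w"] = layer.w
            for nm in ("pre_mean", "pre_scale", "post_mean", "post_scale"):
                val = getattr(layer, nm)
                if val is not None:
                    arrays[f"layer{i}_{nm}"] = val
        for i, sol in enumerate(self.solutions):
            arrays[f"sol{i}_beta"] = sol.beta
            arrays[f"sol{i}_col_mean"] = sol.col_mean
            arrays[f"sol{i}_col_scale"] = sol.col_scale
            arrays[f"sol{i}_h"] = sol.h
            arrays[f"sol{i}_fitted"] = sol.fitted
            arrays[f"sol{i}_loo"] = sol.loo
            arrays[f"sol{i}_scalars"] = np.array(
                [sol.c, sol.y_mean, sol.e_loo]
            )
        if self.rum.layer_w is not None:
            for nm in ("layer_w", "pre_mean", "pre_scale", "post_mean",
                       "post_scale"):
                arrays[f"rum_{nm}"] = getattr(self.rum, nm)
            rsol = self.rum.solution
            arrays["rum_sol_beta"] = rsol.beta
            arrays["rum_sol_col_mean"] = rsol.col_mean
            arrays["rum_sol_col_scale"] = rsol.col_scale
            arrays["rum_sol_h"] = rsol.h
            arrays["rum_sol_fitted"] = rsol.fitted
            arrays["rum_sol_scalars"] = np.array(
                [rsol.c, rsol.y_mean, rsol.e_loo if rsol.e_loo else np.nan]
            )
        buf = io.BytesIO()
        np.savez_compressed(buf, meta=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)
        tmp = path.with_suffix(path.suffix + ".tmp")
        tmp.write_bytes(buf.getvalue())
        os.replace(tmp, path)

    @classmethod
    def load(cls, path: str | Path) -> "DRNNResults":
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"]).decode())
            if meta["version"] != SERIAL_VERSION:
                raise ValidationError(
                    f"model archive version {meta['version']} unsupported "
                    f"(expected {SERIAL_VERSION})"
                )
            arrays = {k: z[k] for k in z.files if k != "meta"}

        from .schema import Trait

        cfg_d = dict(meta["config"])
        cfg_d["c_exponents"] = tuple(cfg_d["c_exponents"])
        if cfg_d["truncation"] is not None:
            cfg_d["truncation"] = tuple(cfg_d["truncation"])
        cfg = DRNNConfig(**cfg_d)
        schema = None
        if meta["schema"]:
            schema = TraitSchema(Trait(**r) for r in meta["schema"])
        exog = pd.DataFrame(arrays["exog"], columns=meta["trait_ids"],
                            index=meta["individuals"])
        model = DRNN(arrays["endog"], exog, schema=schema, config=cfg)
        arch = Architecture(**meta["architecture"])

        layers = []
        for i in range(arch.depth):
            layers.append(RandomLayer(
                w=arrays[f"layer{i}_w"],
                **{nm: arrays.get(f"layer{i}_{nm}")
                   for nm in ("pre_mean", "pre_scale", "post_mean",
                              "post_scale")},
            ))
        solutions = []
        for i in range(arch.depth):
            c, y_mean, e_loo = arrays[f"sol{i}_scalars"]
            solutions.append(RidgeSolution(
                beta=arrays[f"sol{i}_beta"], c=float(c),
                col_mean=arrays[f"sol{i}_col_mean"],
                col_scale=arrays[f"sol{i}_col_scale"],
                y_mean=float(y_mean), h=arrays[f"sol{i}_h"],
                fitted=arrays[f"sol{i}_fitted"], loo=arrays[f"sol{i}_loo"],
                e_loo=float(e_loo),
            ))
        rm = meta["rum"]
        bounds = (rm["bounds"][0],
                  np.inf if rm["bounds"][1] is None else rm["bounds"][1])
        rum = unc.UncertaintyModel(
            family=rm["family"], x_mean=rm["x_mean"], x_scale=rm["x_scale"],
            layer_w=arrays.get("rum_layer_w"),
            pre_mean=arrays.get("rum_pre_mean"),
            pre_scale=arrays.get("rum_pre_scale"),
            post_mean=arrays.get("rum_post_mean"),
            post_scale=arrays.get("rum_post_scale"),
            solution=None, lin_coef=tuple(rm["lin_coef"]) if rm["lin_coef"]
            else None,
            floor=rm["floor"], bounds=bounds, degenerate=rm["degenerate"],
        )
        if "rum_sol_beta" in arrays:
            c, y_mean, e_loo = arrays["rum_sol_scalars"]
            rum.solution = RidgeSolution(
                beta=arrays["rum_sol_beta"], c=float(c),
                col_mean=arrays["rum_sol_col_mean"],
                col_scale=arrays["rum_sol_col_scale"],
                y_mean=float(y_mean), h=arrays["rum_sol_h"],
                fitted=arrays["rum_sol_fitted"],
                e_loo=None if np.isnan(e_loo) else float(e_loo),
            )
        return cls(
            model=model, architecture=arch, layers=layers,
            solutions=solutions, x_mean=arrays["x_mean"],
            x_scale=arrays["x_scale"],
            loo_predictions=pd.Series(arrays["loo"], index=exog.index,
                                      name="loo"),
            fitted=pd.Series(arrays["fitted"], index=exog.index,
                             name="fitted"),
            rum=rum, seed=meta["seed"],
        )
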