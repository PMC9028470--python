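"""Synthetic skeletal-trait generator.

Emulates the statistical structure of a reference osteological dataset:
ages-at-death uniform over the adult span (19–101 by default), a panel
of 64 ordinal traits (2–3 stages) spread over eight anatomical blocks
with block-typical informativeness, bilateral redundancy for 35 traits,
and ~9.5% missing cells completely at random.

The generating model is an ordered probit on a shared latent senescence
score: s_i = z(age_i) + frailty noise, and trait k's stage is obtained
by thresholding λ_k·s_i + unit Gaussian noise at fixed equal-probability
cut-points. λ_k ≥ 0 controls how informative the trait is (λ = 0 gives
a pure-noise trait); the induced stage/age link is monotone by
construction. Bilateral traits copy the left stage to the right side,
flipped to an adjacent stage with a small disagreement probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .schema import Trait, TraitSchema
from .traits import ObservationMatrix, collapse_laterality


@dataclass(frozen=True)
class TraitSpec:
    """One simulated trait: schema metadata plus informativeness λ."""

    trait_id: str
    n_stages: int
    informativeness: float
    bilateral: bool
    block: str


def default_panel() -> list[TraitSpec]:
    """The default 64-trait panel.

    Block sizes and stage counts follow the reference protocol (9
    sutures, 16 axial, 23 appendicular, 2 clavicle, 2 first rib, 3 pubic
    symphysis, 6 sacroiliac, 3 acetabulum; 35 bilateral + 29 unilateral
    = 99 side-expanded columns). Informativeness is block-typical:
    sutures weak, axial/appendicular degenerative and pelvic traits
    moderate to strong, echoing the rank-correlation ranges reported for
    real collections.
    """
    specs: list[TraitSpec] = []

    def block(prefix, count, stages, lams, bilateral, name):
        lams = np.broadcast_to(np.asarray(lams, dtype=float), (count,))
        stages = np.broadcast_to(np.asarray(stages), (count,))
        for i in range(count):
            specs.append(TraitSpec(
                trait_id=f"{prefix}{i + 1:02d}",
                n_stages=int(stages[i]),
                informativeness=float(lams[i]),
                bilateral=bool(bilateral[i]) if np.ndim(bilateral) else bilateral,
                block=name,
            ))

    block("CS", 9, 2, np.linspace(0.4, 0.8, 9), False, "sutures")
    block("VC", 16, 3, np.linspace(2.2, 3.0, 16), False, "axial")
    block("AP", 23, 2, np.linspace(0.6, 2.2, 23), True, "appendicular")
    block("CL", 2, [3, 2], [2.8, 2.2], True, "clavicle")
    block("FR", 2, [3, 2], [2.4, 2.3], True, "first_rib")
    block("PS", 3, 3, [1.8, 1.9, 2.0], True, "pubic_symphysis")
    block("SI", 6, [3, 3, 3, 3, 2, 2],
          np.linspace(1.4, 2.2, 6), np.array([1, 1, 0, 0, 0, 0]), "sacroiliac")
    block("AC", 3, 3, [2.2, 2.35, 2.5], True, "acetabulum")
    return specs


@dataclass
class GeneratorConfig:
    """Study-condition settings for the synthetic generator."""

    n: int = 500
    age_range: tuple[float, float] = (19.0, 101.0)
    traits: list[TraitSpec] = field(default_factory=default_panel)
    frailty_sd: float = 0.3
    bilateral_disagreement: float = 0.05
    missing_rate: float = 0.095
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0 <= self.bilateral_disagreement <= 1:
            raise ValueError("bilateral_disagreement must be in [0, 1]")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("degenerate age range")
        for t in self.traits:
            if not np.isfinite(t.informativeness) or t.informativeness < 0:
                raise ValueError(f"trait {t.trait_id}: λ must be finite and >= 0")


@dataclass
class TruthRecord:
    """Latent generating state, kept for validation of downstream stages."""

    ages: pd.Series
    senescence: np.ndarray
    lambdas: pd.Series
    cutpoints: dict[str, np.ndarray]


def schema_from_specs(specs: list[TraitSpec]) -> TraitSchema:
    return TraitSchema(
        Trait(t.trait_id, t.n_stages, t.bilateral, t.block) for t in specs
    )


def _cutpoints(spec: TraitSpec, latent_sd: float) -> np.ndarray:
    """Equal-probability thresholds of the trait's marginal latent law."""
    probs = np.arange(1, spec.n_stages) / spec.n_stages
    cuts = stats.norm.ppf(probs, scale=latent_sd)
    if not np.all(np.diff(cuts) > 0) and spec.n_stages > 2:
        raise ValueError(f"trait {spec.trait_id}: degenerate cut-points")
    return cuts


def _latent_stages(cfg: GeneratorConfig, rng: np.random.Generator):
    """Complete left-side stages for every trait, plus the truth record."""
    lo, hi = cfg.age_range
    ages = rng.uniform(lo, hi, cfg.n)
    z = (ages - (lo + hi) / 2.0) / ((hi - lo) / np.sqrt(12.0))
    s = z + rng.normal(0.0, cfg.frailty_sd, cfg.n)
    s_var = 1.0 + cfg.frailty_sd**2

    stages = {}
    cuts_record = {}
    for spec in cfg.traits:
        lam = spec.informativeness
        latent = lam * s + rng.standard_normal(cfg.n)
        cuts = _cutpoints(spec, np.sqrt(lam**2 * s_var + 1.0))
        stages[spec.trait_id] = np.searchsorted(cuts, latent).astype(float)
        cuts_record[spec.trait_id] = cuts

    ids = [f"I{i + 1:04d}" for i in range(cfg.n)]
    truth = TruthRecord(
        ages=pd.Series(ages, index=ids, name="age"),
        senescence=s,
        lambdas=pd.Series(
            {t.trait_id: t.informativeness for t in cfg.traits}, name="lambda"
        ),
        cutpoints=cuts_record,
    )
    return pd.DataFrame(stages, index=ids), truth


def _flip_adjacent(stages: np.ndarray, n_stages: int,
                   rng: np.random.Generator, p: float) -> np.ndarray:
    """Move flagged entries to an adjacent stage (inward at boundaries)."""
    out = stages.copy()
    flip = rng.random(len(stages)) < p
    if not flip.any():
        return out
    step = np.where(rng.random(len(stages)) < 0.5, -1.0, 1.0)
    moved = np.clip(out + step, 0, n_stages - 1)
    # at a boundary the clipped step may be a no-op; force the inward move
    stuck = flip & (moved == out)
    moved[stuck] = out[stuck] + np.where(out[stuck] == 0, 1.0, -1.0)
    out[flip] = moved[flip]
    return out


def _apply_mcar(df: pd.DataFrame, rate: float,
                rng: np.random.Generator) -> pd.DataFrame:
    if rate == 0:
        return df
    mask = rng.random(df.shape) < rate
    out = df.copy()
    out.values[mask] = np.nan
    return out


def generate_raw(cfg: GeneratorConfig | None = None):
    """Side-expanded table: 99 columns (``.L``/``.R`` for bilateral traits).

    Returns ``(raw_frame, schema, ages, truth)`` with MCAR missingness at
    ``cfg.missing_rate`` applied to the raw cells, mimicking taphonomic
    loss before laterality collapse.
    """
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    left, truth = _latent_stages(cfg, rng)
    raw = {}
    for spec in cfg.traits:
        col = left[spec.trait_id].to_numpy()
        if spec.bilateral:
            raw[f"{spec.trait_id}.L"] = col
            raw[f"{spec.trait_id}.R"] = _flip_adjacent(
                col, spec.n_stages, rng, cfg.bilateral_disagreement
            )
        else:
            raw[spec.trait_id] = col
    frame = _apply_mcar(pd.DataFrame(raw, index=left.index),
                        cfg.missing_rate, rng)
    return frame, schema_from_specs(cfg.traits), truth.ages, truth


def generate(cfg: GeneratorConfig | None = None,
             collapse: bool = True):
    """Generate a synthetic trait dataset.

    With ``collapse=True`` (default) returns ``(ObservationMatrix,
    TruthRecord)``: one column per unique trait with MCAR missingness at
    ``cfg.missing_rate`` on the collapsed cells. With ``collapse=False``
    delegates to :func:`generate_raw` and returns its four-tuple.
    """
    cfg = cfg or GeneratorConfig()
    if not collapse:
        return generate_raw(cfg)
    rng = np.random.default_rng(cfg.seed)
    left, truth = _latent_stages(cfg, rng)
    raw = {}
    for spec in cfg.traits:
        col = left[spec.trait_id].to_numpy()
        if spec.bilateral:
            raw[f"{spec.trait_id}.L"] = col
            raw[f"{spec.trait_id}.R"] = _flip_adjacent(
                col, spec.n_stages, rng, cfg.bilateral_disagreement
            )
        else:
            raw[spec.trait_id] = col
    schema = schema_from_specs(cfg.traits)
    obs = collapse_laterality(pd.DataFrame(raw, index=left.index), schema,
                              ages=truth.ages)
    stages = _apply_mcar(obs.stages, cfg.missing_rate, rng)
    return ObservationMatrix(stages, schema, truth.ages), truth
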