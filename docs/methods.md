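# Methods

## Problem and data model

`osteoage` estimates adult age-at-death (years) from ordinal morphoscopic
skeletal traits. A trait is a 0-based stage code with two or three levels
(binary presence/absence of degeneration, or a three-stage metamorphic
scale); a schema records each trait's stage count, laterality and
anatomical block (sutures, axial, appendicular, clavicle, first rib, pubic
symphysis, sacroiliac, acetabulum). Observations arrive as an individuals ×
traits matrix with missing cells (taphonomic loss).

Preprocessing mirrors standard osteological practice:

1. **Laterality collapse.** Bilateral traits are scored on both sides but
   carry largely redundant information; the left side is kept, the right
   substitutes when the left is missing. This reduces side-expanded columns
   to one column per unique trait (99 → 64 under the default panel).
2. **1-NN Jaccard imputation.** Remaining gaps are filled from the single
   most similar individual: similarity is Jaccard on one-hot encoded
   stages restricted to traits observed in both, the donor must observe
   every trait the recipient is missing, and all of a recipient's gaps are
   copied from that one donor. Single-donor copying preserves joint trait
   structure better than per-trait donors; ties break to the lowest donor
   position for determinism. The operation never alters observed values
   and is idempotent.

## The learner

The regressor is a deep random vector functional link (RVFL) network.
Hidden weights and biases are drawn i.i.d. standard Gaussian (a `uniform`
switch exists) and never trained. Layer 1 maps the standardized traits;
every deeper layer maps the previous activations concatenated with the
inputs (skip connections are always on — dropping the direct links is
known to hurt randomized networks). ReLU pre-activations and activations
are each standardized per unit with training statistics that are frozen
and reused at prediction time (both standardizations are toggleable).

At each depth `j`, the design `D(j) = [H(1) … H(j), X]` feeds a ridge
output layer with penalty `I/C` (larger `C` = weaker shrinkage), solved via
the thin SVD of the column-standardized design. Because the ridge smoother
does not depend on the targets, the leave-one-out identity

    r_i = (y_i − ŷ_i) / (1 − h_ii),   h_ii = Σ_k φ_k U_ik²,
    φ_k = σ_k² / (σ_k² + 1/C)

is exact with respect to the frozen centering/scaling, and one SVD prices
the entire grid `C = 2^x`, `x ∈ {−6, −4, …, 12}` — only `φ` changes with
`C`. The intercept is the training-target mean and is excluded from the
penalty and the leverages, so `Σ h_ii = Σ φ_k` is the effective degrees of
freedom. Targets are centered; further scaling of `y` would not change the
predictions of a linear smoother, so it is not applied. `C` is optimized
independently per depth by minimum PRESS error; grid values whose fit
interpolates (`h_ii → 1`) are skipped. The model's estimate, and its
cross-validated estimate, average the per-depth (LOO) predictions — an
implicit ensemble that stabilizes the randomized features.

**Architecture.** With `k = log2 n`, total units
`S = 2^⌊log2(8·2^k/k)⌋` over `L = 2^⌊log2 k⌋` equal layers. `S` is read as
the *total* count with per-layer width `S/L`, the only reading consistent
with the reference instantiation (n = 500 → 8 × 32 = 256). The heuristic
needs `n ≥ 4`; depth/width can be overridden in `DRNNConfig`.

## Uncertainty model

Senescence is heteroskedastic, so interval width must vary with predicted
age. A regression uncertainty model regresses `|y − loo|` on the LOO
prediction; the fitted absolute residual, floored at 1 year (preventing
zero-width intervals) and scaled by `√(π/2) = 1.2533` (the SD/MAD ratio of
a Gaussian), is the conditional standard deviation. The interval at level
`alpha` takes the `alpha/2` and `1 − alpha/2` quantiles of a Gaussian at
the point estimate, truncated to bounds that default to
`[min(training age), +∞)` — a skeleton cannot be younger than the youngest
case the model ever saw, while no hard upper bound is imposed; bounds are
configurable. The residual regressor is, by default, the package's own
machinery at depth 1: a single random layer of the heuristic's per-layer
width (full `S` units on a one-dimensional input would be
overparameterized) with a PRESS-optimized ridge output; a `linear` family
is available for auditability. Points that fall implausibly far outside
the truncation bounds are anchored just beyond the bound, yielding the
widest valid interval with a warning.

## Feature analysis

Marginal association uses tie-corrected Spearman ρ and the correlation
ratio η² (between-stage over total sum of squares of age). Because traits
are strongly inter-correlated, ranking uses CAR scores:
`ω = R^{−1/2} r_xy`, the marginal correlations of the sphered
(Mahalanobis-whitened) standardized traits with standardized age. Traits
enter as their integer stage codes (one-hot coding is used only for
imputation similarity). `Σ ω²` equals the OLS R² in the full-rank case —
the property tests pin this. When the correlation matrix is singular or
ill-conditioned (n ≤ p), an analytic convex shrinkage toward the identity
(Schäfer–Strimmer intensity, logged) is applied automatically. Per-trait
significance is two-sided at 0.05, unadjusted; the CAR t-statistic uses
n − 2 degrees of freedom.

## Explanation

A global linear surrogate regresses the network's LOO predictions on the
sphered standardized traits. The sphered columns have zero mean, so the
intercept equals the mean network estimate (the "baseline age") exactly,
and each case decomposes additively: contribution_k = coefficient_k ×
sphered value_k, in years. The surrogate's R² and residual SD are reported
with every explanation so the linear reading is never mistaken for the
network itself.

## Evaluation harness

Metrics: MAE; bias slope (regression of residuals on known age — 0 is
unbiased, 1 is the mean predictor); empirical interval coverage; and
interval-width quantiles at τ ∈ {0.5, 0.025, 0.975} (linear interpolation
between order statistics). Monte Carlo cross-validation draws disjoint
train/test partitions without replacement (default 80/20; B = 1000 mirrors
the reference design, B = 50 is the desk-scale default used by the tests
and the acceptance script), refits the network and uncertainty model per
partition, and aggregates per-iteration metrics as median and 2.5/97.5%
quantiles. Imputation is leakage-safe by default — the test partition is
imputed from training donors only — with a `global_impute` switch to
reproduce the impute-once-then-split order of operations. Named trait
presets resolve through the schema's blocks (each block, `degenerative` =
axial + appendicular, `standard` = clavicle + first rib + pubic symphysis +
sacroiliac + acetabulum, `all`); a `trait_subset_fraction` draws a fresh
random trait subset each iteration (the available-traits experiment).

## Synthetic-data generator

The generator emulates the statistical structure of an identified
reference collection, not any particular collection's values. Defaults:
n = 500 individuals, ages uniform on 19–101 (a uniform design counters
age-mimicry), 64 traits in the block composition above with 35 bilateral
traits (99 side-expanded columns), and 9.5% missing cells completely at
random.

Generating model: a latent senescence score `s_i = z(age_i) + ε_i` with
Gaussian frailty (SD 0.3) shared by all traits, and an ordered probit per
trait — stage = number of fixed cut-points below `λ_k s_i + unit noise`,
with cut-points at equal-probability quantiles of the trait's marginal
latent law. The ordered probit was chosen over a proportional-odds logit
because it composes in closed form with the Gaussian frailty; tests should
not over-interpret the family. `λ_k` sets informativeness: block defaults
(sutures 0.4–0.8; axial 2.2–3.0; appendicular 0.6–2.2; clavicle/first
rib/acetabulum ≈ 2.2–2.8; pubic symphysis 1.8–2.0; sacroiliac 1.4–2.2)
were chosen so the induced stage/age rank correlations fall in the ranges
reported for real collections (weak sutures, strong axial and pelvic
traits). Bilateral right sides copy the left, flipped to an adjacent stage
with probability 0.05. The MCAR rate applies to the cells of the matrix
the caller receives (collapsed 64-column by default; the 99-column raw
table with `collapse=False`).

What the generator does *not* emulate: demographic cohort structure, sex
differences, non-random (taphonomy-driven, element-wise) missingness,
inter-trait dependence beyond the single shared senescence factor, and
observer error beyond the bilateral disagreement flip. Passing tests
therefore demonstrate that the machinery is correct and calibrated under a
well-specified monotone-link world, not that any particular accuracy will
transfer to real skeletal collections.

## Numerical choices and degenerate inputs

- Zero-variance columns standardize with scale 1 (no division by zero).
- Leverages are checked against 1 (tolerance 1e-12); interpolating fits
  raise rather than return infinite LOO residuals.
- Eigenvalues below 1e-12 make a correlation matrix "singular" for
  sphering; shrinkage is the fallback.
- Constant ages, constant ratings (Kendall's W), and single-stage groups
  (η²) are reported as errors or NaN, never silently zero.
- Model archives are versioned; loading a mismatched version fails loudly.
- Problem sizes in the tests and acceptance script (n = 500, B = 50 for
  coverage; B = 10 for the trait-fraction sweep) are desk-scale choices
  that keep the full pipeline exercised end to end while each check stays
  in the seconds-to-minutes range; B is configurable to 1000 for
  full-scale replication.

## Known limitations

- Real trait panels require a user-supplied schema; the bundled 64-trait
  panel is synthetic and its scoring semantics are placeholders.
- The uncertainty model calibrates average conditional spread; it is not a
  conformal or Bayesian interval and carries no finite-sample coverage
  guarantee.
- Interval truncation at the training minimum assumes the training sample
  spans the plausible age range.
- The surrogate explanation is global and linear; strongly non-linear
  network behaviour shows up only as a wider surrogate residual SD.
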