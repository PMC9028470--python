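# osteoage

Multifactorial adult skeletal age-at-death estimation with deep randomized
neural networks.

Estimating age-at-death from an adult skeleton is a core step of the
biological profile in forensic anthropology, and a notoriously hard one:
single indicators (pubic symphysis, cranial sutures, auricular surface)
saturate early and leave open-ended estimates for the elderly. `osteoage`
implements a holistic alternative: many ordinal morphoscopic traits (stages
0–2) scored across the whole skeleton are combined by a regression model
that produces both a point estimate and a calibrated prediction interval.
It is aimed at forensic anthropologists and biostatisticians who want a
reproducible, scriptable pipeline — and a synthetic-data generator so every
stage can be exercised without access to an identified skeletal collection.

## The model

The learner is a **deep random vector functional link network**. Hidden
weights are random and fixed; each layer applies a ReLU,
`H(1) = g(X W(1))`, `H(j) = g([H(j−1) X] W(j))` (skip connections
throughout), and at every depth `j` the stacked design
`D(j) = [H(1) … H(j), X]` feeds a ridge output layer

```
β = (D'D + I/C)^{-1} D'y
```

solved through the thin SVD `D = UΣV'`. The shrinkage factors
`φ_i = σ_i²/(σ_i² + 1/C)` give the hat diagonal `h_ii = Σ_k φ_k U_ik²` and
the PRESS leave-one-out error

```
E_LOO = (1/n) Σ_i ((y_i − ŷ_i)/(1 − h_ii))²
```

so one SVD prices the whole regularization grid `C = 2^x`,
`x ∈ {−6, −4, …, 12}`. Architecture follows a sizing heuristic on the
training size `n`: with `k = log2 n`, `S = 2^⌊log2(8·2^k/k)⌋` total units in
`L = 2^⌊log2 k⌋` layers (`n = 500` → 8 × 32 = 256). The final estimate
averages the per-depth estimates (an implicit ensemble). Intervals come
from a **regression uncertainty model**: absolute leave-one-out residuals
regressed on predicted age, scaled by `√(π/2) ≈ 1.2533` to a conditional
standard deviation, and read off a Gaussian truncated below at the training
minimum age. Supporting analyses include 1-NN Jaccard imputation of missing
stages, Kendall's W scoring concordance, CAR-score (sphered-correlation)
feature ranking, Monte Carlo cross-validation, and an additive linear
surrogate for explaining individual estimates.

## Worked example

```python
import osteoage as oa

obs, truth = oa.generate(oa.GeneratorConfig(seed=0))   # 500 × 64, ~9.5% missing
full = oa.impute_nn1_jaccard(obs)
res = oa.DRNN.from_observations(full).fit(seed=1)
print(res.summary())
```

```
Deep Randomized Neural Network — age-at-death regression
============================================================
n individuals:        500
n traits:             64
architecture:         8 layers x 32 units (256 total)
age range (train):    19.0 - 100.8 years
seed:                 1
...
Cross-validated (LOO) ensemble diagnostics
------------------------------------------------------------
MAE:                  6.156 years
bias slope:           0.085
coverage (alpha=0.05): 0.944
interval truncation:  [19.0, inf] years
```

The leave-one-out MAE of ~6.2 years and near-zero bias slope say the
network tracks age across the whole adult span without the usual
over-young/under-old drift; 94.4% of known ages fall inside the nominal
95% intervals. Per-individual predictions with intervals:

```python
print(res.predict(full, alpha=0.05).head(3))
```

```
           point        sd      lower      upper
I0001  84.569707  7.470092  69.928596  99.210819
I0002  35.069735  7.735300  21.835560  50.294111
I0003  27.963688  7.582449  19.814217  43.232600
```

Note the heteroskedastic, truncated intervals: the youngest estimate's
lower bound is pinned near the training minimum. The same pipeline is
available from the shell:

```sh
osteoage simulate --n 500 --seed 0 --out data.csv --schema-out schema.yaml
osteoage fit --data data.csv --schema schema.yaml --seed 1 --out model.npz
osteoage predict --model model.npz --data data.csv --out estimates.csv
osteoage evaluate --data data.csv --schema schema.yaml -B 50 --out report
osteoage rank-features --data data.csv --schema schema.yaml --out features.csv
```

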