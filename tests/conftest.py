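import numpy as np
import pandas as pd
import pytest

from osteoage import (
    GeneratorConfig,
    ObservationMatrix,
    Trait,
    TraitSchema,
    TraitSpec,
    generate,
    impute_nn1_jaccard,
)


@pytest.fixture(scope="session")
def default_dataset():
    """Default-condition synthetic dataset: n=500, 64 traits, 9.5% MCAR."""
    obs, truth = generate(GeneratorConfig(seed=7))
    return obs, truth


@pytest.fixture(scope="session")
def complete_dataset(default_dataset):
    obs, truth = default_dataset
    return impute_nn1_jaccard(obs), truth


@pytest.fixture(scope="session")
def small_dataset():
    """Quick-to-fit dataset: n=80, 10 informative traits, complete."""
    specs = [
        TraitSpec(f"T{i:02d}", n_stages=3 if i % 2 else 2,
                  informativeness=lam, bilateral=False, block="axial")
        for i, lam in enumerate(np.linspace(1.5, 3.0, 10))
    ]
    cfg = GeneratorConfig(n=80, traits=specs, missing_rate=0.0, seed=11)
    obs, truth = generate(cfg)
    return obs, truth


@pytest.fixture
def binary_schema():
    return TraitSchema(
        [Trait(f"B{i}", 2, False, "axial") for i in range(3)]
    )


def make_obs(values, schema, ages=None, ids=None):
    """Build an ObservationMatrix from a nested list (None = missing)."""
    arr = np.array(
        [[np.nan if v is None else float(v) for v in row] for row in values]
    )
    idx = ids if ids is not None else [f"I{i}" for i in range(len(arr))]
    stages = pd.DataFrame(arr, index=idx, columns=schema.trait_ids)
    ages_s = pd.Series(ages, index=idx, dtype=float) if ages is not None else None
    return ObservationMatrix(stages, schema, ages_s)
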