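"""Trait container, laterality collapse, one-hot coding, 1-NN Jaccard
imputation and Kendall's W concordance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from osteoage import (
    ObservationMatrix,
    Trait,
    TraitSchema,
    collapse_laterality,
    generate,
    impute_nn1_jaccard,
    kendalls_w,
    one_hot_decode,
    one_hot_encode,
)
from osteoage.schema import SchemaError
from osteoage.simulate import GeneratorConfig
from osteoage.traits import ImputationError, ValidationError

from conftest import make_obs


# ---------------------------------------------------------------------
# container validation
# ---------------------------------------------------------------------

class TestObservationMatrix:
    def test_rejects_out_of_range_stage(self, binary_schema):
        with pytest.raises(ValidationError, match="stage codes outside"):
            make_obs([[0, 1, 2]], binary_schema)

    def test_rejects_non_integer_stage(self, binary_schema):
        with pytest.raises(ValidationError, match="non-integer"):
            make_obs([[0.5, 1, 0]], binary_schema)

    def test_rejects_negative_age(self, binary_schema):
        with pytest.raises(ValidationError, match="non-negative"):
            make_obs([[0, 1, 0]], binary_schema, ages=[-3.0])

    def test_csv_round_trip(self, tmp_path, binary_schema):
        obs = make_obs([[0, None, 1], [1, 1, 0]], binary_schema,
                       ages=[30.0, 71.5])
        path = tmp_path / "obs.csv"
        obs.to_csv(path)
        back = ObservationMatrix.from_csv(path, binary_schema)
        assert back == obs


# ---------------------------------------------------------------------
# laterality collapse
# ---------------------------------------------------------------------

class TestCollapseLaterality:
    @pytest.fixture
    def bilateral_schema(self):
        return TraitSchema([
            Trait("P", 3, True, "pubic_symphysis"),
            Trait("U", 2, False, "axial"),
        ])

    @pytest.mark.parametrize(
        "left,right,expected",
        [
            (2, 1, 2),          # left preferred
            (None, 1, 1),       # right is the surrogate
            (None, None, None), # nothing to collapse
        ],
    )
    def test_side_preference(self, bilateral_schema, left, right, expected):
        raw = pd.DataFrame(
            {"P.L": [left], "P.R": [right], "U": [1]},
            index=["a"], dtype=float,
        )
        obs = collapse_laterality(raw, bilateral_schema)
        got = obs.stages.loc["a", "P"]
        if expected is None:
            assert np.isnan(got)
        else:
            assert got == expected

    def test_never_invents_values(self, bilateral_schema):
        rng = np.random.default_rng(0)
        left = rng.choice([0.0, 1.0, 2.0, np.nan], size=40)
        right = rng.choice([0.0, 1.0, 2.0, np.nan], size=40)
        raw = pd.DataFrame({"P.L": left, "P.R": right,
                            "U": np.zeros(40)})
        obs = collapse_laterality(raw, bilateral_schema)
        for val, l, r in zip(obs.stages["P"], left, right):
            if np.isnan(val):
                assert np.isnan(l) and np.isnan(r)
            else:
                assert val in {x for x in (l, r) if not np.isnan(x)}

    def test_extra_side_column_rejected(self, bilateral_schema):
        raw = pd.DataFrame({"P.L": [1.0], "P.R": [1.0], "P": [1.0],
                            "U": [0.0]})
        with pytest.raises(SchemaError):
            collapse_laterality(raw, bilateral_schema)

    def test_full_panel_column_reduction(self):
        """35 bilateral + 29 unilateral traits: 99 raw → 64 collapsed."""
        raw, schema, ages, _ = generate(GeneratorConfig(seed=3), collapse=False)
        assert raw.shape[1] == 99
        assert schema.n_raw_columns == 99
        obs = collapse_laterality(raw, schema, ages=ages)
        assert len(obs.trait_ids) == 64


# ---------------------------------------------------------------------
# one-hot encoding
# ---------------------------------------------------------------------

class TestOneHot:
    def test_indicator_coding(self, binary_schema):
        schema = TraitSchema([Trait("T", 3, False, "axial")])
        enc = one_hot_encode(make_obs([[1]], schema))
        assert enc.indicators.tolist() == [[0.0, 1.0, 0.0]]

    def test_missing_yields_zero_group_and_mask(self, binary_schema):
        enc = one_hot_encode(make_obs([[None, 1, 0]], binary_schema))
        assert enc.indicators[0, :2].tolist() == [0.0, 0.0]
        assert enc.missing[0].tolist() == [True, False, False]

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_round_trip_bijection(self, seed):
        rng = np.random.default_rng(seed)
        schema = TraitSchema(
            [Trait(f"T{i}", int(rng.integers(2, 4)), False, "axial")
             for i in range(5)]
        )
        values = [
            [int(rng.integers(0, schema[t].n_stages)) for t in schema.trait_ids]
            for _ in range(8)
        ]
        obs = make_obs(values, schema)
        back = one_hot_decode(one_hot_encode(obs), schema, index=obs.individuals)
        assert back == obs


# ---------------------------------------------------------------------
# 1-NN Jaccard imputation
# ---------------------------------------------------------------------

def brute_force_impute(obs):
    """Independent oracle: exhaustive donor search with explicit Jaccard."""
    stages = obs.stages.to_numpy()
    schema = obs.schema
    tids = obs.trait_ids
    out = stages.copy()
    n = len(stages)
    for i in range(n):
        miss = np.isnan(stages[i])
        if not miss.any():
            continue
        best = (-1.0, -1)
        for j in range(n):
            if j == i or np.isnan(stages[j][miss]).any():
                continue
            inter = union = 0
            for t, tid in enumerate(tids):
                if np.isnan(stages[i, t]) or np.isnan(stages[j, t]):
                    continue
                for s in range(schema[tid].n_stages):
                    a = stages[i, t] == s
                    b = stages[j, t] == s
                    inter += a and b
                    union += a or b
            if union == 0:
                continue
            sim = inter / union
            if sim > best[0]:
                best = (sim, j)
        if best[1] < 0:
            raise ImputationError("no donor")
        out[i, miss] = stages[best[1], miss]
    return out


class TestImputation:
    def test_forced_donor(self, binary_schema):
        obs = make_obs(
            [[1, 0, 1], [1, 0, None], [0, 1, 0]], binary_schema,
            ids=["A", "B", "C"],
        )
        filled = impute_nn1_jaccard(obs)
        assert filled.stages.loc["B"].tolist() == [1.0, 0.0, 1.0]

    def test_complete_matrix_unchanged(self, binary_schema):
        obs = make_obs([[1, 0, 1], [0, 1, 0]], binary_schema)
        assert impute_nn1_jaccard(obs) == obs

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        schema = TraitSchema(
            [Trait(f"T{i}", int(rng.integers(2, 4)), False, "axial")
             for i in range(10)]
        )
        values = np.array([
            [float(rng.integers(0, schema[t].n_stages))
             for t in schema.trait_ids]
            for _ in range(20)
        ])
        holes = rng.random(values.shape) < 0.1
        values[holes] = np.nan
        obs = make_obs(values.tolist(), schema)
        expected = brute_force_impute(obs)
        got = impute_nn1_jaccard(obs).stages.to_numpy()
        np.testing.assert_array_equal(got, expected)

    def test_all_missing_individual_rejected(self, binary_schema):
        obs = make_obs([[None, None, None], [1, 0, 1]], binary_schema)
        with pytest.raises(ImputationError, match="cannot match"):
            impute_nn1_jaccard(obs)

    def test_idempotent(self, default_dataset):
        obs, _ = default_dataset
        once = impute_nn1_jaccard(obs)
        assert impute_nn1_jaccard(once) == once

    def test_observed_values_untouched(self, default_dataset):
        obs, _ = default_dataset
        filled = impute_nn1_jaccard(obs)
        seen = ~obs.missing_mask.to_numpy()
        np.testing.assert_array_equal(
            filled.stages.to_numpy()[seen], obs.stages.to_numpy()[seen]
        )


# ---------------------------------------------------------------------
# Kendall's W
# ---------------------------------------------------------------------

def kendalls_w_oracle(a, b):
    """From-scratch tie-corrected rank-sum computation for two raters."""
    from scipy.stats import rankdata

    n = len(a)
    ra, rb = rankdata(a), rankdata(b)
    totals = ra + rb
    s = np.sum((totals - totals.mean()) ** 2)
    t_corr = 0.0
    for r in (ra, rb):
        for _, cnt in zip(*np.unique(r, return_counts=True)):
            t_corr += cnt**3 - cnt
    return 12 * s / (4 * (n**3 - n) - 2 * t_corr)


class TestKendallsW:
    def test_identical_sessions_perfect_agreement(self):
        s = pd.DataFrame({"t": [0, 1, 2, 1, 0, 2, 1]})
        rep = kendalls_w(s, s.copy())
        assert rep.table.loc["t", "W"] == pytest.approx(1.0)
        assert rep.mean_w == pytest.approx(1.0)

    def test_reversed_rankings_zero(self):
        a = pd.DataFrame({"t": [1, 2, 3, 4, 5]})
        b = pd.DataFrame({"t": [5, 4, 3, 2, 1]})
        assert kendalls_w(a, b).table.loc["t", "W"] == pytest.approx(0.0)

    def test_matches_rank_sum_oracle(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 3, size=50).astype(float)
        b = np.where(rng.random(50) < 0.8, a, rng.integers(0, 3, 50))
        rep = kendalls_w(pd.DataFrame({"t": a}), pd.DataFrame({"t": b}))
        assert rep.table.loc["t", "W"] == pytest.approx(
            kendalls_w_oracle(a, b), abs=1e-12
        )

    def test_chi_square_statistic(self):
        rng = np.random.default_rng(9)
        a = rng.integers(0, 3, 30).astype(float)
        b = rng.integers(0, 3, 30).astype(float)
        rep = kendalls_w(pd.DataFrame({"t": a}), pd.DataFrame({"t": b}))
        w = rep.table.loc["t", "W"]
        assert rep.table.loc["t", "chi2"] == pytest.approx(2 * 29 * w)

    def test_too_few_subjects_rejected(self):
        s = pd.DataFrame({"t": [0, 1]})
        with pytest.raises(ValidationError, match="at least 3"):
            kendalls_w(s, s)

    def test_constant_ratings_undefined(self):
        s = pd.DataFrame({"t": [1, 1, 1, 1]})
        assert np.isnan(kendalls_w(s, s.copy()).table.loc["t", "W"])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_w_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 3, 12).astype(float)
        b = rng.integers(0, 3, 12).astype(float)
        w = kendalls_w(pd.DataFrame({"t": a}), pd.DataFrame({"t": b})).table[
            "W"].iloc[0]
        assert np.isnan(w) or 0.0 <= w <= 1.0
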