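"""Deep randomized network: architecture heuristic, random layers,
forward pass, end-to-end fit/predict and serialization."""

import numpy as np
import pandas as pd
import pytest

from osteoage import DRNN, DRNNConfig, architecture_heuristic
from osteoage.drnn import DRNNResults, RandomLayer, forward, init_layers, stacked_designs
from osteoage.traits import ValidationError


class TestArchitectureHeuristic:
    @pytest.mark.parametrize(
        "n,depth,width,total",
        [
            (500, 8, 32, 256),   # the reference instantiation
            (4, 2, 8, 16),
            (256, 8, 32, 256),
        ],
    )
    def test_known_instantiations(self, n, depth, width, total):
        arch = architecture_heuristic(n)
        assert (arch.depth, arch.width, arch.total_units) == (depth, width, total)

    def test_powers_of_two(self):
        for n in (10, 47, 123, 999, 5000):
            arch = architecture_heuristic(n)
            assert arch.total_units & (arch.total_units - 1) == 0
            assert arch.depth & (arch.depth - 1) == 0
            assert arch.depth * arch.width == arch.total_units

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            architecture_heuristic(3)


class TestRandomLayers:
    def test_reproducible_from_seed(self):
        arch = architecture_heuristic(500)
        a = init_layers(arch, 64, np.random.default_rng(5))
        b = init_layers(arch, 64, np.random.default_rng(5))
        for la, lb in zip(a, b):
            np.testing.assert_array_equal(la.w, lb.w)

    def test_layer_shapes_with_skip_connections(self):
        arch = architecture_heuristic(500)
        layers = init_layers(arch, 64, np.random.default_rng(0))
        assert layers[0].w.shape == (64 + 1, 32)        # traits + bias
        assert layers[2].w.shape == (32 + 64 + 1, 32)   # width + traits + bias

    def test_unknown_distribution_rejected(self):
        arch = architecture_heuristic(500)
        with pytest.raises(ValueError, match="distribution"):
            init_layers(arch, 4, np.random.default_rng(0), "cauchy")


class TestForward:
    def test_relu_zero_at_zero_preactivation(self):
        layer = RandomLayer(w=np.zeros((4, 3)))
        hs = forward([layer], np.random.default_rng(0).standard_normal((5, 3)),
                     train=True, standardize_pre=False, standardize_post=False)
        np.testing.assert_array_equal(hs[0], np.zeros((5, 3)))

    def test_design_column_counts(self):
        arch = architecture_heuristic(500)
        layers = init_layers(arch, 64, np.random.default_rng(1))
        xs = np.random.default_rng(2).standard_normal((500, 64))
        designs = stacked_designs(forward(layers, xs, train=True), xs)
        assert designs[0].shape[1] == 32 + 64
        assert designs[-1].shape[1] == 8 * 32 + 64   # 320 for the full depth

    def test_prediction_pass_reproduces_training_designs(self):
        arch = architecture_heuristic(64)
        layers = init_layers(arch, 6, np.random.default_rng(3))
        xs = np.random.default_rng(4).standard_normal((64, 6))
        train_h = forward(layers, xs, train=True)
        apply_h = forward(layers, xs, train=False)
        for a, b in zip(train_h, apply_h):
            np.testing.assert_array_equal(a, b)


class TestFit:
    def test_noise_free_linear_target_recovered(self):
        rng = np.random.default_rng(20)
        stage = rng.integers(0, 3, 200).astype(float)
        y = 25.0 + 20.0 * stage
        model = DRNN(y, pd.DataFrame({"t": stage}))
        res = model.fit(seed=0)
        assert res.cv_mae <= 0.5

    def test_same_seed_identical_predictions(self, small_dataset):
        obs, _ = small_dataset
        a = DRNN.from_observations(obs).fit(seed=3)
        b = DRNN.from_observations(obs).fit(seed=3)
        pd.testing.assert_series_equal(a.loo_predictions, b.loo_predictions)
        pd.testing.assert_series_equal(a.predict(obs), b.predict(obs))

    def test_depth_one_is_shallow_rvfl(self, small_dataset):
        obs, _ = small_dataset
        res = DRNN.from_observations(
            obs, config=DRNNConfig(depth=1)
        ).fit(seed=0)
        assert len(res.solutions) == 1
        # ensemble of one = that single shallow solution
        np.testing.assert_allclose(
            res.fitted.to_numpy(), res.solutions[0].fitted
        )

    def test_constant_ages_rejected(self):
        x = pd.DataFrame({"t": [0.0, 1.0, 0.0, 1.0, 0.0, 1.0]})
        with pytest.raises(ValidationError, match="constant"):
            DRNN(np.full(6, 50.0), x)

    def test_missing_values_rejected(self):
        x = pd.DataFrame({"t": [0.0, np.nan, 1.0, 1.0]})
        with pytest.raises(ValidationError, match="impute"):
            DRNN(np.array([20.0, 40.0, 60.0, 80.0]), x)

    def test_analytic_loo_matches_explicit_refits_every_depth(self):
        """Module-central oracle: per-depth analytic LOO equals explicit
        leave-one-out ridge refits on the frozen network designs."""
        rng = np.random.default_rng(30)
        n = 24
        x = pd.DataFrame({
            "a": rng.integers(0, 3, n).astype(float),
            "b": rng.integers(0, 2, n).astype(float),
            "c": rng.integers(0, 3, n).astype(float),
            "d": rng.integers(0, 2, n).astype(float),
        })
        y = 20 + 15 * x["a"].to_numpy() + 5 * x["b"].to_numpy() + rng.normal(
            0, 3, n)
        res = DRNN(y, x).fit(seed=1)

        xs = (x.to_numpy() - res.x_mean) / res.x_scale
        designs = stacked_designs(
            forward(res.layers, xs, train=False), xs
        )
        for sol, d in zip(res.solutions, designs):
            z = (d - sol.col_mean) / sol.col_scale
            yc = y - sol.y_mean
            for i in range(n):
                keep = np.arange(n) != i
                beta = np.linalg.solve(
                    z[keep].T @ z[keep] + np.eye(z.shape[1]) / sol.c,
                    z[keep].T @ yc[keep],
                )
                assert sol.loo[i] == pytest.approx(
                    z[i] @ beta + sol.y_mean, rel=1e-8, abs=1e-8
                )


class TestPredict:
    def test_training_rows_reproduce_fitted(self, small_dataset):
        obs, _ = small_dataset
        res = DRNN.from_observations(obs).fit(seed=0)
        np.testing.assert_allclose(
            res.predict(obs).to_numpy(), res.fitted.to_numpy(), atol=1e-10
        )

    def test_column_permutation_invariant(self, small_dataset):
        obs, _ = small_dataset
        res = DRNN.from_observations(obs).fit(seed=0)
        shuffled = obs.stages[obs.stages.columns[::-1]]
        np.testing.assert_allclose(
            res.predict(shuffled).to_numpy(), res.fitted.to_numpy(),
            atol=1e-10,
        )

    def test_constant_row_within_training_range(self, small_dataset):
        obs, _ = small_dataset
        res = DRNN.from_observations(obs).fit(seed=0)
        row = pd.DataFrame(
            [np.zeros(len(obs.trait_ids))], columns=obs.trait_ids
        )
        pred = float(res.predict(row).iloc[0])
        lo, hi = obs.ages.min(), obs.ages.max()
        assert lo - 25 < pred < hi + 25

    def test_unseen_stage_code_rejected(self, small_dataset):
        obs, _ = small_dataset
        res = DRNN.from_observations(obs).fit(seed=0)
        bad = obs.stages.copy()
        bad.iloc[0, 0] = 9.0
        with pytest.raises(ValidationError, match="stage codes"):
            res.predict(bad)

    def test_interval_output_shape(self, small_dataset):
        obs, _ = small_dataset
        res = DRNN.from_observations(obs).fit(seed=0)
        table = res.predict(obs, alpha=0.05)
        assert list(table.columns) == ["point", "sd", "lower", "upper"]
        assert (table["lower"] <= table["upper"]).all()


class TestSerialization:
    def test_round_trip_predictions_identical(self, small_dataset, tmp_path):
        obs, _ = small_dataset
        res = DRNN.from_observations(obs).fit(seed=9)
        path = tmp_path / "model.npz"
        res.save(path)
        back = DRNNResults.load(path)
        pd.testing.assert_series_equal(
            back.loo_predictions, res.loo_predictions, check_index_type=False
        )
        a = res.predict(obs, alpha=0.05)
        b = back.predict(obs.stages.reset_index(drop=True), alpha=0.05)
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-12)

    def test_version_mismatch_rejected(self, small_dataset, tmp_path):
        import json

        obs, _ = small_dataset
        res = DRNN.from_observations(obs).fit(seed=0)
        path = tmp_path / "model.npz"
        res.save(path)
        with np.load(path) as z:
            arrays = {k: z[k] for k in z.files}
        meta = json.loads(bytes(arrays.pop("meta")).decode())
        meta["version"] = 99
        np.savez(path, meta=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)
        with pytest.raises(ValidationError, match="version"):
            DRNNResults.load(path)

    def test_summary_mentions_architecture(self, small_dataset):
        obs, _ = small_dataset
        res = DRNN.from_observations(obs).fit(seed=0)
        text = res.summary()
        arch = res.architecture
        assert f"{arch.depth} layers x {arch.width} units" in text
        assert "MAE" in text
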