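"""Metrics, permutation importance, management summaries, rasters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn import metrics as skm

import wheatyield as wy
from wheatyield.config import BaselineConfig
from wheatyield.models import FittedModel
from wheatyield.synth import ManagementTable, YieldGrid

import pandas as pd


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0])
        rep = wy.compute_metrics(y, y)
        assert rep.mae == 0 and rep.rmse == 0 and rep.r2 == 1

    def test_hand_arithmetic_example(self):
        rep = wy.compute_metrics([2.0, 4.0], [3.0, 3.0])
        assert rep.mae == pytest.approx(1.0)
        assert rep.rmse == pytest.approx(1.0)
        assert rep.r2 == pytest.approx(0.0)

    def test_null_model_r2_zero(self, rng):
        y = rng.uniform(1, 6, 30)
        rep = wy.compute_metrics(y, np.full(30, y.mean()))
        assert rep.r2 == pytest.approx(0.0, abs=1e-12)

    def test_matches_sklearn_oracle(self, rng):
        y = rng.uniform(1, 7, 50)
        p = y + rng.normal(0, 0.5, 50)
        rep = wy.compute_metrics(y, p)
        assert rep.mae == pytest.approx(skm.mean_absolute_error(y, p))
        assert rep.rmse == pytest.approx(np.sqrt(skm.mean_squared_error(y, p)))
        assert rep.r2 == pytest.approx(skm.r2_score(y, p))

    def test_zero_variance_flagged(self):
        with pytest.warns(UserWarning):
            rep = wy.compute_metrics([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
        assert np.isnan(rep.r2)

    @settings(max_examples=200, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(st.floats(-10, 10), st.floats(-10, 10)),
            min_size=2,
            max_size=30,
        )
    )
    def test_rmse_at_least_mae(self, data):
        y = np.array([a for a, _ in data])
        p = np.array([b for _, b in data])
        rep = wy.compute_metrics(y, p)
        assert rep.rmse >= rep.mae - 1e-12

    def test_r2_identity_with_rmse(self, rng):
        y = rng.uniform(1, 7, 40)
        p = y + rng.normal(0, 0.3, 40)
        rep = wy.compute_metrics(y, p)
        identity = 1 - rep.m * rep.rmse**2 / np.sum((y - y.mean()) ** 2)
        assert rep.r2 == pytest.approx(identity, abs=1e-10)


class _LinearSeqModel:
    """Predicts from feature 0's mean over time; ignores the rest."""

    def __init__(self, copy_feature=0):
        self.k = copy_feature

    def predict(self, X):
        return X[:, :, self.k].mean(axis=1)


def _seq_model(k=0, n_feat=3, T=4):
    return FittedModel(
        kind="toy",
        estimator=_LinearSeqModel(k),
        schema=("sequence", T, n_feat),
        feature_names=[f"f{j}" for j in range(n_feat)],
    )


class TestPermutationImportance:
    def test_ignored_feature_keeps_baseline_loss(self, rng):
        X = rng.uniform(size=(50, 4, 3))
        y = X[:, :, 0].mean(axis=1)
        imp = wy.permutation_feature_importance(_seq_model(0), X, y, seed=0)
        assert imp.shuffled_loss["f1"] == pytest.approx(imp.baseline_loss, abs=1e-12)
        assert imp.shuffled_loss["f2"] == pytest.approx(imp.baseline_loss, abs=1e-12)
        assert imp.shuffled_loss["f0"] > imp.baseline_loss

    def test_copy_feature_matches_direct_recomputation(self, rng):
        X = rng.uniform(size=(40, 4, 2))
        y = X[:, :, 0].mean(axis=1)  # model copies feature 0 exactly
        model = _seq_model(0, n_feat=2)
        imp = wy.permutation_feature_importance(
            model, X, y, n_repeats=3, seed=123
        )
        # brute-force recomputation with the same rng stream
        rng2 = np.random.default_rng(123)
        losses = []
        for k in range(2):
            for _ in range(3):
                perm = rng2.permutation(40)
                Xp = X.copy()
                Xp[:, :, k] = X[perm][:, :, k]
                pred = Xp[:, :, 0].mean(axis=1)
                losses.append(np.mean((pred - y) ** 2))
            if k == 0:
                assert imp.shuffled_loss["f0"] == pytest.approx(np.mean(losses))

    def test_ranks_are_a_permutation(self, rng):
        X = rng.uniform(size=(30, 4, 3))
        y = X[:, :, 1].mean(axis=1)
        imp = wy.permutation_feature_importance(_seq_model(1), X, y, seed=0)
        assert sorted(imp.rank.values()) == [1, 2, 3]
        assert imp.ranking[0] == "f1"

    def test_flat_schema_group_shuffle(self, rng):
        X = rng.uniform(size=(40, 6))
        y = X[:, :3].mean(axis=1)

        class FlatModel:
            def predict(self, X):
                return X[:, :3].mean(axis=1)

        model = FittedModel(
            kind="toy",
            estimator=FlatModel(),
            schema=("flat", 6),
            feature_names=["a", "b"],
            feature_groups={"a": np.arange(3), "b": np.arange(3, 6)},
        )
        imp = wy.permutation_feature_importance(model, X, y, seed=0)
        assert imp.shuffled_loss["b"] == pytest.approx(imp.baseline_loss)
        assert imp.shuffled_loss["a"] > imp.baseline_loss

    def test_single_sample_rejected(self, rng):
        X = rng.uniform(size=(1, 4, 3))
        with pytest.raises(ValueError):
            wy.permutation_feature_importance(_seq_model(), X, np.array([1.0]))

    def test_repeat_averaging_stabilizes(self, rng):
        X = rng.uniform(size=(60, 4, 2))
        y = X[:, :, 0].mean(axis=1)
        model = _seq_model(0, n_feat=2)
        spreads = []
        for n_rep in (2, 40):
            vals = [
                wy.permutation_feature_importance(
                    model, X, y, n_repeats=n_rep, seed=s
                ).shuffled_loss["f0"]
                for s in range(8)
            ]
            spreads.append(np.var(vals))
        assert spreads[1] < spreads[0]


class TestManagementSummary:
    def test_group_means_match_direct_computation(self):
        cfg = wy.SceneConfig(seed=9)
        table = wy.generate_management_table(cfg, n_samples=200)
        summary = wy.summarize_management_effects(table)
        row = summary[
            (summary.factor == "seeding_rate_kg_ha") & (summary.level == 225.0)
        ].iloc[0]
        direct = table.data[table.data.seeding_rate_kg_ha == 225.0][
            "yield_t_ha"
        ].mean()
        assert row["mean"] == pytest.approx(direct)

    def test_constant_yield_equal_means(self):
        df = pd.DataFrame(
            {
                "seeding_rate_kg_ha": [180.0, 180.0, 225.0, 225.0],
                "tillage": ["conventional"] * 4,
                "fertilizer": ["fixed"] * 4,
                "irrigation_mm": [0.0, 20.0, 0.0, 20.0],
                "yield_t_ha": [4.0] * 4,
            }
        )
        summary = wy.summarize_management_effects(ManagementTable(df))
        assert np.allclose(summary["mean"], 4.0)

    def test_underpopulated_level_omitted_with_warning(self):
        df = pd.DataFrame(
            {
                "seeding_rate_kg_ha": [180.0, 180.0, 225.0],
                "tillage": ["conventional"] * 3,
                "fertilizer": ["fixed"] * 3,
                "irrigation_mm": [0.0, 0.0, 0.0],
                "yield_t_ha": [4.0, 4.2, 5.0],
            }
        )
        with pytest.warns(UserWarning):
            summary = wy.summarize_management_effects(ManagementTable(df))
        levels = summary[summary.factor == "seeding_rate_kg_ha"]["level"].tolist()
        assert 225.0 not in levels


class TestYieldMap:
    def test_write_read_round_trip(self, tmp_path):
        cfg = wy.SceneConfig(n_rows=6, n_cols=5, seed=0)
        grid = wy.generate_yield_grid(cfg)
        path = wy.write_yield_map(grid, grid.values, tmp_path / "map.tif")
        values, geo = wy.read_yield_map(path)
        assert np.allclose(values, grid.values, atol=1e-5)
        assert geo["cell_size_m"] == pytest.approx(5.0)

    def test_masked_cells_become_nodata(self, tmp_path):
        mask = np.ones((4, 4), bool)
        mask[0, 0] = False
        grid = YieldGrid(np.full((4, 4), 3.0), mask=mask)
        path = wy.write_yield_map(grid, grid.values, tmp_path / "map.tif")
        values, _ = wy.read_yield_map(path)
        assert np.isnan(values[0, 0])
        assert np.isfinite(values[1:, :]).all()

    def test_cell_count_matches_grid(self, tmp_path):
        cfg = wy.SceneConfig(n_rows=7, n_cols=3, seed=1)
        grid = wy.generate_yield_grid(cfg)
        path = wy.write_yield_map(grid, grid.yields, tmp_path / "map.tif")
        values, _ = wy.read_yield_map(path)
        assert np.isfinite(values).sum() == grid.n_samples
        assert values.size == grid.values.size

    def test_shape_mismatch_rejected(self, tmp_path):
        grid = YieldGrid(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            wy.write_yield_map(grid, np.zeros(5), tmp_path / "map.tif")
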