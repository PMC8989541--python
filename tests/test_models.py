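"""Per-position gradient-boosted model set: fitting, evaluation, curves."""

import numpy as np
import pandas as pd
import pytest

from bescreen.features import N_FEATURES, feature_names
from bescreen.models import (
    DEFAULT_HYPERPARAMS,
    PositionEditingModel,
    downsample_experiment,
    evaluate,
    train_model_set,
)


def _random_features(n, seed):
    """Valid one-hot + Tm feature rows (random spacers)."""
    rng = np.random.default_rng(seed)
    X = np.zeros((n, N_FEATURES))
    for i in range(n):
        for slot in range(20):
            X[i, 4 * slot + rng.integers(4)] = 1.0
        X[i, -1] = rng.normal(60, 5)
    return X


def _linear_target(X, slot=4, noise=0.0, seed=0):
    """Deterministic target from one slot's one-hot channels plus Tm."""
    rng = np.random.default_rng(seed)
    w = np.array([0.0, 1.0, -1.0, 2.0])
    y = X[:, 4 * slot : 4 * slot + 4] @ w + 0.02 * (X[:, -1] - 60.0)
    if noise:
        y = y + rng.normal(0, noise, len(y))
    return y


class TestFit:
    def test_deterministic_under_seed(self):
        X = _random_features(200, 1)
        Y = pd.DataFrame({6: _linear_target(X, noise=0.3)})
        a = PositionEditingModel(random_state=5).fit(X, Y).predict(X)
        b = PositionEditingModel(random_state=5).fit(X, Y).predict(X)
        assert np.array_equal(a.to_numpy(), b.to_numpy())

    def test_noiseless_signal_learnable(self):
        X = _random_features(600, 2)
        y = _linear_target(X)
        Y = pd.DataFrame({6: y})
        model = PositionEditingModel(random_state=0).fit(X[:500], Y.iloc[:500])
        pred = model.predict(X[500:])[6].to_numpy()
        r = np.corrcoef(y[500:], pred)[0, 1]
        assert r >= 0.95

    def test_constant_target_surfaced(self):
        X = _random_features(100, 3)
        with pytest.raises(ValueError, match="zero-variance"):
            PositionEditingModel().fit(X, pd.DataFrame({6: np.full(100, 0.5)}))

    def test_too_few_rows_surfaced(self):
        X = _random_features(100, 3)
        y = np.full(100, np.nan)
        y[:10] = np.random.default_rng(0).random(10)
        with pytest.raises(ValueError, match="training rows"):
            PositionEditingModel().fit(X, pd.DataFrame({6: y}))

    def test_nan_masking_per_position(self):
        X = _random_features(200, 4)
        y1 = _linear_target(X, slot=2, noise=0.1)
        y2 = _linear_target(X, slot=7, noise=0.1)
        y2[:80] = np.nan
        model = PositionEditingModel(min_training_rows=50, random_state=0).fit(
            X, pd.DataFrame({5: y1, 6: y2})
        )
        assert model.n_training_rows_[5] == 200
        assert model.n_training_rows_[6] == 120


class TestPredict:
    def test_batch_equals_single_row(self):
        X = _random_features(60, 5)
        Y = pd.DataFrame({6: _linear_target(X, noise=0.2)})
        model = PositionEditingModel(random_state=0).fit(X, Y)
        batch = model.predict(X[:5])
        singles = np.concatenate([model.predict(X[i]).to_numpy() for i in range(5)])
        assert np.allclose(batch.to_numpy().ravel(), singles.ravel(), atol=1e-12)

    def test_schema_mismatch_rejected(self):
        X = _random_features(60, 5)
        model = PositionEditingModel(random_state=0).fit(
            X, pd.DataFrame({6: _linear_target(X, noise=0.2)})
        )
        with pytest.raises(ValueError, match="schema"):
            model.predict(np.zeros((2, 10)))

    def test_output_per_position(self):
        X = _random_features(120, 6)
        Y = pd.DataFrame(
            {p: _linear_target(X, slot=p, noise=0.2, seed=p) for p in range(3, 11)}
            | {"overall": _linear_target(X, slot=12, noise=0.2, seed=99)}
        )
        model = PositionEditingModel(random_state=0).fit(X, Y)
        pred = model.predict(X[:3])
        assert list(pred.columns) == list(Y.columns)
        assert pred.shape == (3, 9)
        assert np.isfinite(pred.to_numpy()).all()


class TestEvaluate:
    @staticmethod
    def _dataset_with_predictable_targets(n=150, seed=7):
        X = _random_features(n, seed)
        df = pd.DataFrame(X, columns=feature_names())
        df.insert(0, "guide_id", [f"g{i}" for i in range(n)])
        df.insert(1, "dataset", "sim")
        df.insert(2, "split", ["train"] * (n - 30) + ["test"] * 30)
        df["z_6"] = _linear_target(X, noise=0.05, seed=seed)
        return df

    def test_perfect_predictions_r_one_mse_zero(self):
        df = self._dataset_with_predictable_targets()

        class Oracle:
            positions_ = [6]

            def predict(self, X):
                return pd.DataFrame({6: _linear_target(np.asarray(X), noise=0.05, seed=7)[-len(X):]})

        # hand the evaluator the measured targets as predictions
        df_test = df[df["split"] == "test"]

        class Identity:
            positions_ = [6]

            def predict(self, X):
                return pd.DataFrame({6: df_test["z_6"].to_numpy()})

        out = evaluate(Identity(), df, split="test")
        row = out[out["position"] == "6"].iloc[0]
        assert row["pearson_r"] == pytest.approx(1.0)
        assert row["mse"] == pytest.approx(0.0, abs=1e-15)

    def test_constant_offset_keeps_r_one(self):
        df = self._dataset_with_predictable_targets()
        df_test = df[df["split"] == "test"]

        class Offset:
            positions_ = [6]

            def predict(self, X):
                return pd.DataFrame({6: df_test["z_6"].to_numpy() + 0.5})

        out = evaluate(Offset(), df, split="test")
        row = out[out["position"] == "6"].iloc[0]
        assert row["pearson_r"] == pytest.approx(1.0)
        assert row["mse"] == pytest.approx(0.25)

    def test_pure_noise_target_near_zero_r(self):
        rng = np.random.default_rng(11)
        X = _random_features(800, 11)
        y = rng.standard_normal(800)  # no relation to features
        df = pd.DataFrame(X, columns=feature_names())
        df.insert(0, "guide_id", [f"g{i}" for i in range(800)])
        df.insert(1, "dataset", "sim")
        df.insert(2, "split", ["train"] * 400 + ["test"] * 400)
        df["z_6"] = y
        model = train_model_set(df, positions=(6,), seed=0)
        out = evaluate(model, df, split="test")
        r = out[out["position"] == "6"].iloc[0]["pearson_r"]
        assert abs(r) < 3 / np.sqrt(400)


class TestImportances:
    def test_sum_to_one_and_planted_channel_ranks_first(self):
        X = _random_features(500, 8)
        Y = pd.DataFrame({6: _linear_target(X, slot=4)})
        model = PositionEditingModel(random_state=0).fit(X, Y)
        imp = model.feature_importances_[6]
        assert imp.sum() == pytest.approx(1.0)
        table = model.feature_importance_table()
        top = table[table["rank"] == 1].iloc[0]["feature"]
        assert top.startswith("pos5_")  # slot 4 is spacer position 5

    def test_irrelevant_features_near_zero(self):
        X = _random_features(500, 9)
        Y = pd.DataFrame({6: _linear_target(X, slot=4)})
        model = PositionEditingModel(random_state=0).fit(X, Y)
        imp = model.feature_importances_[6]
        # channels of a distant slot carry no signal
        assert imp[4 * 15 : 4 * 16].sum() < 0.02


class TestDownsampling:
    @staticmethod
    def _dataset(n=400, seed=13):
        X = _random_features(n, seed)
        df = pd.DataFrame(X, columns=feature_names())
        df.insert(0, "guide_id", [f"g{i}" for i in range(n)])
        df.insert(1, "dataset", "sim")
        df.insert(2, "split", ["train"] * (n - 80) + ["test"] * 80)
        df["z_6"] = _linear_target(X, noise=0.8, seed=seed)
        return df

    def test_full_fraction_single_rep_reproduces_baseline(self):
        df = self._dataset()
        curves = downsample_experiment(df, 6, fractions=(1.0,), n_reps=1, seed=0)
        model = train_model_set(df, positions=(6,), seed=0)
        base = evaluate(model, df, split="test")
        r_base = base[base["position"] == "6"].iloc[0]["pearson_r"]
        assert curves.iloc[0]["pearson_r"] == pytest.approx(r_base, abs=1e-12)

    def test_same_seed_identical_curves(self):
        df = self._dataset()
        a = downsample_experiment(df, 6, fractions=(0.5, 0.25), n_reps=2, seed=3)
        b = downsample_experiment(df, 6, fractions=(0.5, 0.25), n_reps=2, seed=3)
        assert a.equals(b)

    def test_tiny_fraction_skipped_with_warning(self, caplog):
        df = self._dataset(n=120)
        curves = downsample_experiment(
            df, 6, fractions=(0.1,), n_reps=1, seed=0, min_training_rows=50
        )
        assert curves.empty


class TestHyperparameters:
    def test_published_defaults(self):
        model = PositionEditingModel()
        for k, v in DEFAULT_HYPERPARAMS.items():
            assert getattr(model, k) == v
        assert model.get_params()["n_estimators"] == 100

    def test_sklearn_param_interface(self):
        model = PositionEditingModel().set_params(max_depth=2)
        assert model.max_depth == 2

    def test_search_returns_grid_point(self):
        X = _random_features(120, 14)
        y = _linear_target(X, noise=0.3, seed=14)
        best = PositionEditingModel().search_hyperparameters(
            X, y, grid={"n_estimators": [10, 50], "max_depth": [2, 4]}, cv=3
        )
        assert best["n_estimators"] in (10, 50)
        assert best["max_depth"] in (2, 4)


class TestPersistence:
    def test_save_load_roundtrip(self, tmp_path):
        X = _random_features(100, 15)
        Y = pd.DataFrame({6: _linear_target(X, noise=0.2, seed=15)})
        model = PositionEditingModel(random_state=0).fit(X, Y)
        path = tmp_path / "model.joblib"
        model.save(path)
        loaded = PositionEditingModel.load(path)
        assert np.array_equal(
            loaded.predict(X).to_numpy(), model.predict(X).to_numpy()
        )
        assert path.with_suffix(".joblib.json").exists()
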