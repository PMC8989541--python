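"""Per-position gradient-boosted regression of standardized editing rates.

One squared-error gradient-boosted tree regressor is trained per
protospacer position 3-10 plus an "overall" model for the total fraction
of edited reads.  Inputs are the 81 guide features (one-hot spacer +
melting temperature); targets are per-dataset standardized rates.  The
published configuration — 100 trees of depth 4, minimum 2 samples per
leaf, learning rate 0.1, no stochastic subsampling — is the default and
the fit is deterministic under a fixed random_state.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.model_selection import GridSearchCV
from sklearn.utils.validation import check_is_fitted

from .features import MODEL_POSITIONS, N_FEATURES, feature_names

logger = logging.getLogger(__name__)

DEFAULT_HYPERPARAMS = {
    "n_estimators": 100,
    "max_depth": 4,
    "min_samples_leaf": 2,
    "learning_rate": 0.1,
}

#: cross-validation grid spanning the values the defaults were selected from
DEFAULT_SEARCH_GRID = {
    "n_estimators": [10, 100, 1000],
    "max_depth": [1, 4, 10],
    "min_samples_leaf": [1, 2, 50],
    "learning_rate": [0.001, 0.1, 1.0],
}


def _target_columns(Y) -> list:
    if isinstance(Y, pd.DataFrame):
        return list(Y.columns)
    Y = np.asarray(Y)
    if Y.ndim == 1:
        return ["overall"]
    return list(range(Y.shape[1]))


class PositionEditingModel(BaseEstimator, RegressorMixin):
    """Set of per-position gradient-boosted regressors.

    Parameters
    ----------
    n_estimators, max_depth, min_samples_leaf, learning_rate:
        Boosting hyperparameters (defaults are the published
        configuration).
    random_state:
        Seed for the boosting fits; with no subsampling the fit and its
        predictions are deterministic.
    min_training_rows:
        Minimum usable rows per position; positions with fewer raise.

    Fitted attributes
    -----------------
    models_ : dict mapping position -> fitted GradientBoostingRegressor
    positions_ : the target columns trained
    feature_importances_ : dict mapping position -> importance vector
        (impurity-based, normalized to sum 1)
    """

    def __init__(
        self,
        n_estimators: int = 100,
        max_depth: int = 4,
        min_samples_leaf: int = 2,
        learning_rate: float = 0.1,
        random_state: int | None = 0,
        min_training_rows: int = 50,
    ):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.learning_rate = learning_rate
        self.random_state = random_state
        self.min_training_rows = min_training_rows

    def _make_regressor(self) -> GradientBoostingRegressor:
        return GradientBoostingRegressor(
            loss="squared_error",
            n_estimators=self.n_estimators,
            max_depth=self.max_depth,
            min_samples_leaf=self.min_samples_leaf,
            learning_rate=self.learning_rate,
            random_state=self.random_state,
        )

    def _validate_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(1, -1)
        if X.shape[1] != getattr(self, "n_features_in_", N_FEATURES):
            raise ValueError(
                f"feature schema mismatch: expected "
                f"{getattr(self, 'n_features_in_', N_FEATURES)} columns, "
                f"got {X.shape[1]}"
            )
        return X

    def fit(self, X, Y):
        """Fit one regressor per target column.

        ``Y`` is a DataFrame (or 2D array) of standardized targets, one
        column per position; NaN rows are dropped per position, so each
        model sees only guides with an editable base there.
        """
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2D")
        self.n_features_in_ = X.shape[1]
        cols = _target_columns(Y)
        Ymat = Y.to_numpy(dtype=float) if isinstance(Y, pd.DataFrame) else np.asarray(
            Y, dtype=float
        ).reshape(len(X), -1)
        self.models_ = {}
        self.n_training_rows_ = {}
        for j, col in enumerate(cols):
            y = Ymat[:, j]
            mask = ~np.isnan(y)
            if mask.sum() < self.min_training_rows:
                raise ValueError(
                    f"position {col}: only {int(mask.sum())} training rows "
                    f"(minimum {self.min_training_rows})"
                )
            if np.std(y[mask]) == 0:
                raise ValueError(f"position {col}: degenerate (zero-variance) target")
            reg = self._make_regressor()
            reg.fit(X[mask], y[mask])
            self.models_[col] = reg
            self.n_training_rows_[col] = int(mask.sum())
        self.positions_ = cols
        return self

    def predict(self, X) -> pd.DataFrame:
        """Standardized-rate predictions, one column per trained position."""
        check_is_fitted(self, "models_")
        X = self._validate_X(X)
        out = {col: reg.predict(X) for col, reg in self.models_.items()}
        return pd.DataFrame(out)

    @property
    def feature_importances_(self) -> dict:
        check_is_fitted(self, "models_")
        return {col: reg.feature_importances_ for col, reg in self.models_.items()}

    def feature_importance_table(self) -> pd.DataFrame:
        """Ranked impurity-based importances per position (sum to 1)."""
        check_is_fitted(self, "models_")
        names = (
            feature_names()
            if self.n_features_in_ == N_FEATURES
            else [f"f{i}" for i in range(self.n_features_in_)]
        )
        rows = []
        for col, imp in self.feature_importances_.items():
            order = np.argsort(imp)[::-1]
            for rank, i in enumerate(order, start=1):
                rows.append((str(col), rank, names[i], float(imp[i])))
        return pd.DataFrame(rows, columns=["position", "rank", "feature", "importance"])

    def save(self, path: str | Path, metadata: dict | None = None) -> None:
        """Persist the fitted model set with JSON metadata alongside."""
        check_is_fitted(self, "models_")
        path = Path(path)
        joblib.dump(self, path)
        meta = {
            "hyperparameters": {k: getattr(self, k) for k in DEFAULT_HYPERPARAMS},
            "random_state": self.random_state,
            "n_features": int(self.n_features_in_),
            "positions": [str(p) for p in self.positions_],
            "n_training_rows": {str(k): v for k, v in self.n_training_rows_.items()},
        }
        if metadata:
            meta.update(metadata)
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(meta, indent=2, sort_keys=True)
        )

    @staticmethod
    def load(path: str | Path) -> "PositionEditingModel":
        model = joblib.load(path)
        meta_path = Path(path).with_suffix(Path(path).suffix + ".json")
        if meta_path.exists():
            meta = json.loads(meta_path.read_text())
            if meta.get("n_features") != int(model.n_features_in_):
                raise ValueError("model bundle metadata does not match fitted schema")
        return model

    def search_hyperparameters(
        self,
        X,
        y,
        grid: dict | None = None,
        cv: int = 5,
        n_jobs: int = 1,
    ) -> dict:
        """Optional 5-fold CV re-search of the boosting hyperparameters.

        Runs on a single target vector; returns the best parameter dict
        (the published defaults are used when this is skipped).
        """
        grid = grid or DEFAULT_SEARCH_GRID
        y = np.asarray(y, dtype=float)
        mask = ~np.isnan(y)
        search = GridSearchCV(
            self._make_regressor(), grid, cv=cv, n_jobs=n_jobs,
            scoring="neg_mean_squared_error",
        )
        search.fit(np.asarray(X, dtype=float)[mask], y[mask])
        return dict(search.best_params_)


def train_model_set(
    dataset: pd.DataFrame,
    positions: tuple = MODEL_POSITIONS,
    hyperparams: dict | None = None,
    seed: int = 0,
    min_training_rows: int = 50,
) -> PositionEditingModel:
    """Train the per-position model set from a combined PositionDataset table.

    Uses only rows tagged split == "train".  Positions whose target
    column is absent or has too few usable rows are skipped with a log
    message (e.g. no editable bases upstream in a small cohort).
    """
    hp = dict(DEFAULT_HYPERPARAMS)
    if hyperparams:
        hp.update(hyperparams)
    train = dataset[dataset["split"] == "train"]
    X = train[feature_names()].to_numpy(dtype=float)
    cols = {}
    for p in positions:
        col = f"z_{p}"
        if col not in train.columns:
            continue
        y = train[col].to_numpy(dtype=float)
        if (~np.isnan(y)).sum() >= min_training_rows:
            cols[p] = y
        else:
            logger.info("position %s skipped: too few training rows", p)
    if not cols:
        raise ValueError("no position has enough training rows")
    Y = pd.DataFrame(cols)
    model = PositionEditingModel(
        random_state=seed, min_training_rows=min_training_rows, **hp
    )
    model.fit(X, Y)
    return model


def evaluate(
    model: PositionEditingModel,
    dataset: pd.DataFrame,
    split: str = "test",
    by_dataset: bool = False,
) -> pd.DataFrame:
    """Pearson R and MSE between predicted and measured standardized rates.

    One row per position (plus a mean-across-positions row), computed on
    the rows with the given split tag; with ``by_dataset`` the breakdown
    is repeated per provenance dataset.  Positions with fewer than 3
    usable test rows are undefined and omitted.
    """
    sub = dataset[dataset["split"] == split] if split else dataset
    groups = sub.groupby("dataset") if by_dataset else [("all", sub)]
    rows = []
    for ds_id, grp in groups:
        X = grp[feature_names()].to_numpy(dtype=float)
        if len(grp) == 0:
            continue
        pred = model.predict(X)
        rs = []
        for p in model.positions_:
            col = f"z_{p}"
            if col not in grp.columns:
                continue
            y = grp[col].to_numpy(dtype=float)
            mask = ~np.isnan(y)
            if mask.sum() < 3:
                continue
            yhat = pred[p].to_numpy()[mask]
            r = float(sps.pearsonr(y[mask], yhat).statistic)
            mse = float(np.mean((y[mask] - yhat) ** 2))
            rows.append((ds_id, str(p), int(mask.sum()), r, mse))
            rs.append((r, mse))
        if rs:
            rows.append(
                (
                    ds_id,
                    "mean_across_positions",
                    0,
                    float(np.mean([x[0] for x in rs])),
                    float(np.mean([x[1] for x in rs])),
                )
            )
    return pd.DataFrame(rows, columns=["dataset", "position", "n", "pearson_r", "mse"])


def downsample_experiment(
    dataset: pd.DataFrame,
    position,
    fractions: tuple[float, ...] = (0.8, 0.5, 0.25, 0.1),
    n_reps: int = 100,
    seed: int = 0,
    hyperparams: dict | None = None,
    min_training_rows: int = 50,
) -> pd.DataFrame:
    """Learning-curve experiment for one position model.

    For each fraction, draws ``n_reps`` training subsets without
    replacement, refits, and records the test-set Pearson R (always
    evaluated on the full test set).  Fractions yielding fewer than
    ``min_training_rows`` rows are skipped with a warning.
    """
    hp = dict(DEFAULT_HYPERPARAMS)
    if hyperparams:
        hp.update(hyperparams)
    col = f"z_{position}"
    train = dataset[(dataset["split"] == "train") & dataset[col].notna()]
    test = dataset[(dataset["split"] == "test") & dataset[col].notna()]
    Xtr = train[feature_names()].to_numpy(dtype=float)
    ytr = train[col].to_numpy(dtype=float)
    Xte = test[feature_names()].to_numpy(dtype=float)
    yte = test[col].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for frac in fractions:
        n_sub = int(round(frac * len(ytr)))
        if n_sub < min_training_rows:
            logger.warning("fraction %.2f gives %d rows; skipped", frac, n_sub)
            continue
        for rep in range(n_reps):
            idx = rng.choice(len(ytr), size=n_sub, replace=False)
            reg = GradientBoostingRegressor(
                loss="squared_error", random_state=seed, **hp
            )
            reg.fit(Xtr[idx], ytr[idx])
            yhat = reg.predict(Xte)
            r = float(sps.pearsonr(yte, yhat).statistic)
            rows.append((frac, rep, n_sub, r))
    return pd.DataFrame(rows, columns=["fraction", "rep", "n_train", "pearson_r"])
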