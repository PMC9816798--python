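"""Train/test splitting and the four yield regressors.

The sequence model is the two-layer LSTM of :mod:`wheatyield.lstm`,
consuming the 4-index x 9-month matrix time-major.  The baselines --
random forest, gradient-boosted trees, and RBF support-vector
regression -- cannot consume sequences and take the flattened vector
instead; they are delegated to scikit-learn with the study's tuned
hyperparameters (RF: 150 trees, random state 200, out-of-bag scoring;
GBDT: 1250 trees, subsample 0.6, learning rate 0.1; SVR: RBF kernel,
C = 1e5, gamma = 0.5).  Features are z-scored for the LSTM and the
SVR, which are scale-sensitive; the tree models see raw features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .config import BaselineConfig, LSTMConfig, SplitSpec
from .lstm import LSTMRegressor

__all__ = [
    "split_train_test",
    "FittedModel",
    "train_lstm_regressor",
    "train_baseline_regressor",
    "predict_yield",
]


def split_train_test(n_samples: int, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray]:
    """Random disjoint-exhaustive index partition (default 9:1).

    Returns (train_idx, test_idx); reproducible given ``spec.seed``.
    """
    if n_samples < 10:
        raise ValueError("need at least 10 samples to split")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(n_samples)
    n_train = int(round(spec.train_fraction * n_samples))
    n_train = min(max(n_train, 1), n_samples - 1)
    return np.sort(order[:n_train]), np.sort(order[n_train:])


@dataclass
class FittedModel:
    """A trained regressor plus its feature schema.

    ``schema`` is ("sequence", T, F) for the LSTM or ("flat", d) for
    the baselines; predictions are refused on mismatched input.
    ``feature_names`` names the F (or the d-column groups') features
    for importance analysis; ``feature_groups`` maps each name to the
    flat columns it owns (flat schema only).
    """

    kind: str
    estimator: Any
    schema: tuple
    feature_names: list[str] = field(default_factory=list)
    feature_groups: dict[str, np.ndarray] = field(default_factory=dict)
    training_log: list = field(default_factory=list)
    oob_r2: float | None = None
    clip_range: tuple[float, float] | None = None

    def check_schema(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        if self.schema[0] == "sequence":
            if X.ndim != 3 or X.shape[1:] != tuple(self.schema[1:]):
                raise ValueError(
                    f"{self.kind} expects sequences of shape {self.schema[1:]}, "
                    f"got {X.shape[1:]}"
                )
        else:
            if X.ndim != 2 or X.shape[1] != self.schema[1]:
                raise ValueError(
                    f"{self.kind} expects {self.schema[1]} flat features, "
                    f"got {X.shape}"
                )
        return X


def train_lstm_regressor(
    X: np.ndarray,
    y: np.ndarray,
    config: LSTMConfig,
    feature_names: list[str] | None = None,
) -> FittedModel:
    """Fit the stacked-LSTM regressor on sequences (n, T, F)."""
    X = np.asarray(X, float)
    if X.ndim != 3:
        raise ValueError("LSTM input must be (n_samples, n_steps, n_features)")
    n, T, F = X.shape
    est = LSTMRegressor(
        n_features=F,
        hidden_units=config.hidden_units,
        n_layers=config.n_layers,
        dropout=config.dropout,
        l2_lambda=config.l2_lambda,
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        epochs=config.epochs,
        seed=config.seed,
    )
    est.fit(X, y)
    return FittedModel(
        kind="LSTM",
        estimator=est,
        schema=("sequence", T, F),
        feature_names=feature_names or [f"f{k}" for k in range(F)],
        training_log=list(est.training_log),
        clip_range=config.clip_range,
    )


def train_baseline_regressor(
    X: np.ndarray,
    y: np.ndarray,
    config: BaselineConfig,
    feature_names: list[str] | None = None,
    feature_groups: dict[str, np.ndarray] | None = None,
) -> FittedModel:
    """Fit one of the RF / GBDT / SVR baselines on flat features (n, d)."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if X.ndim != 2:
        raise ValueError("baseline input must be flat (n_samples, n_features)")
    oob = None
    if config.model == "RF":
        est = RandomForestRegressor(
            n_estimators=config.rf_n_trees,
            random_state=config.rf_random_state,
            oob_score=True,
        )
        est.fit(X, y)
        oob = float(est.oob_score_)
    elif config.model == "GBDT":
        est = GradientBoostingRegressor(
            n_estimators=config.gbdt_n_trees,
            subsample=config.gbdt_subsample,
            learning_rate=config.gbdt_learning_rate,
            random_state=config.seed,
        )
        est.fit(X, y)
    else:  # SVR
        est = Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "svr",
                    SVR(kernel=config.svr_kernel, C=config.svr_c, gamma=config.svr_gamma),
                ),
            ]
        )
        est.fit(X, y)
    return FittedModel(
        kind=config.model,
        estimator=est,
        schema=("flat", X.shape[1]),
        feature_names=feature_names or [f"f{k}" for k in range(X.shape[1])],
        feature_groups=feature_groups or {},
        oob_r2=oob,
    )


def predict_yield(model: FittedModel, X: np.ndarray) -> np.ndarray:
    """Predict yields in t/ha, optionally clipped to the plausible range."""
    X = model.check_schema(X)
    pred = np.asarray(model.estimator.predict(X), float)
    if not np.all(np.isfinite(pred)):
        raise RuntimeError(f"{model.kind} produced non-finite predictions")
    if model.clip_range is not None:
        pred = np.clip(pred, *model.clip_range)
    return pred
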