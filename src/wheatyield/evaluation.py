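"""Accuracy metrics, permutation feature importance, and summaries.

Metrics follow the standard definitions

    MAE  = (1/m) sum |h(x_i) - y_i|
    RMSE = sqrt((1/m) sum (h(x_i) - y_i)^2)
    R^2  = 1 - sum (h(x_i) - y_i)^2 / sum (y_i - ybar)^2

Permutation feature importance (PFI) shuffles one feature at a time
across samples -- the whole monthly trajectory of that vegetation
index, keeping within-sample temporal structure intact -- and records
the prediction loss of the already-trained model on the shuffled
data.  A larger shuffled loss means the model leaned harder on that
feature.  No retraining is involved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import FittedModel, predict_yield
from .synth import ManagementTable

__all__ = [
    "EvaluationReport",
    "compute_metrics",
    "ImportanceReport",
    "permutation_feature_importance",
    "summarize_management_effects",
]


@dataclass
class EvaluationReport:
    """MAE/RMSE (t/ha), R^2 and sample count for one evaluation."""

    mae: float
    rmse: float
    r2: float
    m: int
    split: str = ""

    def to_dict(self) -> dict:
        return {"mae": self.mae, "rmse": self.rmse, "r2": self.r2, "m": self.m,
                "split": self.split}


def compute_metrics(y_true, y_pred, split: str = "") -> EvaluationReport:
    """MAE, RMSE and R^2 of predictions against observed yields.

    R^2 is NaN (flagged with a warning) when the observed yields have
    zero variance.
    """
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be equal-length vectors")
    if y_true.size < 2:
        raise ValueError("need at least two samples")
    if not (np.all(np.isfinite(y_true)) and np.all(np.isfinite(y_pred))):
        raise ValueError("inputs must be finite")
    err = y_pred - y_true
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("R^2 undefined: zero variance in y_true", stacklevel=2)
        r2 = float("nan")
    else:
        r2 = 1.0 - float(np.sum(err**2)) / ss_tot
    return EvaluationReport(mae=mae, rmse=rmse, r2=r2, m=y_true.size, split=split)


@dataclass
class ImportanceReport:
    """Per-feature shuffled loss, baseline loss and ranks.

    ``ranking`` lists feature names by descending shuffled loss (most
    important first); ``rank[f]`` is that feature's 1-based rank.
    """

    feature_names: list[str]
    shuffled_loss: dict[str, float]
    baseline_loss: float
    n_repeats: int
    seed: int
    loss: str = "mse"

    @property
    def ranking(self) -> list[str]:
        return sorted(
            self.feature_names, key=lambda f: (-self.shuffled_loss[f], f)
        )

    @property
    def rank(self) -> dict[str, int]:
        return {f: k + 1 for k, f in enumerate(self.ranking)}

    def to_dict(self) -> dict:
        return {
            "baseline_loss": self.baseline_loss,
            "shuffled_loss": self.shuffled_loss,
            "ranking": self.ranking,
            "n_repeats": self.n_repeats,
            "seed": self.seed,
            "loss": self.loss,
        }


def _loss(y_true, y_pred, kind: str) -> float:
    if kind == "mse":
        return float(np.mean((y_pred - y_true) ** 2))
    if kind == "rmse":
        return float(np.sqrt(np.mean((y_pred - y_true) ** 2)))
    if kind == "mae":
        return float(np.mean(np.abs(y_pred - y_true)))
    raise ValueError(f"unknown loss {kind!r}")


def permutation_feature_importance(
    model: FittedModel,
    X: np.ndarray,
    y_true: np.ndarray,
    n_repeats: int = 10,
    seed: int = 0,
    loss: str = "mse",
) -> ImportanceReport:
    """Shuffle one feature at a time and record the prediction loss.

    For sequence input (n, T, F) the permutation reorders feature k's
    whole trajectory across samples; for flat input the columns of the
    feature's group (its months) are moved together with a single
    permutation.  The mean loss over ``n_repeats`` independent
    shuffles is reported per feature, and features are ranked by
    descending loss.
    """
    X = model.check_schema(X)
    y_true = np.asarray(y_true, float)
    if X.shape[0] < 2:
        raise ValueError("need at least two samples to permute")
    rng = np.random.default_rng(seed)
    baseline = _loss(y_true, predict_yield(model, X), loss)

    names = model.feature_names
    shuffled: dict[str, float] = {}
    for k, name in enumerate(names):
        losses = []
        for _ in range(n_repeats):
            perm = rng.permutation(X.shape[0])
            Xp = X.copy()
            if model.schema[0] == "sequence":
                Xp[:, :, k] = X[perm][:, :, k]
            else:
                cols = model.feature_groups.get(name)
                if cols is None:
                    cols = np.array([k])
                Xp[:, cols] = X[perm][:, cols]
            losses.append(_loss(y_true, predict_yield(model, Xp), loss))
        shuffled[name] = float(np.mean(losses))
    return ImportanceReport(
        feature_names=list(names),
        shuffled_loss=shuffled,
        baseline_loss=baseline,
        n_repeats=n_repeats,
        seed=seed,
        loss=loss,
    )


def summarize_management_effects(table: ManagementTable) -> pd.DataFrame:
    """Group mean, SD and count of yield per management-factor level.

    Returns a tidy frame (factor, level, mean, sd, n), levels in their
    observed sorted order.  Levels with fewer than two samples are
    omitted with a warning.
    """
    df = table.data
    rows = []
    for factor in ManagementTable.FACTORS:
        for level, grp in df.groupby(factor, sort=True):
            if len(grp) < 2:
                warnings.warn(
                    f"factor {factor!r} level {level!r} has <2 samples; omitted",
                    stacklevel=2,
                )
                continue
            rows.append(
                {
                    "factor": factor,
                    "level": level,
                    "mean": float(grp["yield_t_ha"].mean()),
                    "sd": float(grp["yield_t_ha"].std(ddof=1)),
                    "n": int(len(grp)),
                }
            )
    return pd.DataFrame(rows, columns=["factor", "level", "mean", "sd", "n"])
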