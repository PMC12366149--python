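"""Type-specific gradient-boosted tree classifiers for consensus SV calls.

One model per SV type maps a harmonized feature vector to the probability
that the consensus call is a true positive. Training uses the exact greedy
split finder with the gbtree booster and a binary logistic objective;
hyperparameters are chosen by seeded stratified cross-validation over a
grid, and features whose gain importance is zero are iteratively discarded
with the search re-run until a fixpoint.
"""

from __future__ import annotations

import itertools
import json
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import xgboost as xgb
from sklearn.model_selection import StratifiedKFold

from .bench import roc_auc
from .features import FeatureMatrix
from .types import SVType

#: default hyperparameter grid (configuration; recorded in the artifact)
DEFAULT_GRID: dict[str, list] = {
    "max_depth": [3, 5, 7],
    "learning_rate": [0.05, 0.1, 0.3],
    "n_estimators": [100, 300],
    "min_child_weight": [1, 5],
}

#: reduced grid for quick desk-scale runs
SMALL_GRID: dict[str, list] = {
    "max_depth": [3, 5],
    "learning_rate": [0.1, 0.3],
    "n_estimators": [100],
    "min_child_weight": [1],
}


class TrainingError(RuntimeError):
    pass


@dataclass
class TrainingConfig:
    objective: str = "binary:logistic"
    tree_method: str = "exact"
    booster: str = "gbtree"
    hyperparameter_grid: dict[str, list] = field(default_factory=lambda: dict(DEFAULT_GRID))
    cv_folds: int = 5
    seed: int = 0
    decision_threshold: float = 0.5
    max_prune_iterations: int = 5

    def __post_init__(self) -> None:
        if not (0.0 < self.decision_threshold < 1.0):
            raise ValueError("decision_threshold must lie in (0, 1)")
        if not self.hyperparameter_grid:
            raise ValueError("hyperparameter grid must be non-empty")


@dataclass
class TrainedMetaModel:
    svtype: SVType
    booster: xgb.Booster
    feature_names: list[str]
    importances: dict[str, float]
    hyperparameters: dict
    cv_auc: float
    decision_threshold: float
    registry_hash: str = ""
    seed: int = 0

    def save(self, directory: str | os.PathLike) -> None:
        os.makedirs(directory, exist_ok=True)
        self.booster.save_model(os.path.join(directory, "model.json"))
        meta = {
            "svtype": self.svtype.value,
            "feature_names": self.feature_names,
            "importances": self.importances,
            "hyperparameters": self.hyperparameters,
            "cv_auc": self.cv_auc,
            "decision_threshold": self.decision_threshold,
            "registry_hash": self.registry_hash,
            "seed": self.seed,
        }
        with open(os.path.join(directory, "meta.json"), "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, directory: str | os.PathLike) -> "TrainedMetaModel":
        with open(os.path.join(directory, "meta.json")) as fh:
            meta = json.load(fh)
        booster = xgb.Booster()
        booster.load_model(os.path.join(directory, "model.json"))
        return cls(
            svtype=SVType(meta["svtype"]),
            booster=booster,
            feature_names=meta["feature_names"],
            importances=meta["importances"],
            hyperparameters=meta["hyperparameters"],
            cv_auc=meta["cv_auc"],
            decision_threshold=meta["decision_threshold"],
            registry_hash=meta.get("registry_hash", ""),
            seed=meta.get("seed", 0),
        )


def _make_estimator(config: TrainingConfig, params: dict) -> xgb.XGBClassifier:
    return xgb.XGBClassifier(
        objective=config.objective,
        tree_method=config.tree_method,
        booster=config.booster,
        random_state=config.seed,
        n_jobs=1,
        eval_metric="logloss",
        **params,
    )


def _gain_importances(booster: xgb.Booster, feature_names: Sequence[str]) -> dict[str, float]:
    """Relative (normalized) gain contribution per feature; unused -> 0."""
    raw = booster.get_score(importance_type="gain")
    gains = np.array([raw.get(name, 0.0) for name in feature_names], dtype=float)
    total = gains.sum()
    if total > 0:
        gains = gains / total
    return dict(zip(feature_names, gains.tolist()))


def _prepared(matrix: FeatureMatrix, feature_names: Optional[Sequence[str]] = None):
    names = list(feature_names) if feature_names is not None else list(matrix.df.columns)
    missing = [n for n in names if n not in matrix.df.columns]
    if missing:
        raise ValueError(f"feature matrix lacks required columns: {missing}")
    return matrix.df[names].astype(float)


def grid_search_train(
    matrix: FeatureMatrix,
    config: TrainingConfig,
    feature_names: Optional[Sequence[str]] = None,
) -> TrainedMetaModel:
    """Select hyperparameters by mean cross-validated AUC and refit.

    Grid points are scored with stratified ``cv_folds``-fold CV under the
    config seed; ties keep the earlier grid point, so the result is fully
    deterministic. The winning configuration is refit on all rows.
    """
    if matrix.labels is None:
        raise TrainingError("training requires labels")
    y = matrix.labels.to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise TrainingError("both classes must be represented in the labels")
    X = _prepared(matrix, feature_names)

    skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    folds = list(skf.split(X, y))

    keys = list(config.hyperparameter_grid)
    best_auc, best_params = -np.inf, None
    for combo in itertools.product(*(config.hyperparameter_grid[k] for k in keys)):
        params = dict(zip(keys, combo))
        aucs = []
        for train_idx, test_idx in folds:
            est = _make_estimator(config, params)
            est.fit(X.iloc[train_idx], y[train_idx])
            scores = est.predict_proba(X.iloc[test_idx])[:, 1]
            aucs.append(roc_auc(scores, y[test_idx].astype(bool)))
        mean_auc = float(np.mean(aucs))
        if mean_auc > best_auc:
            best_auc, best_params = mean_auc, params

    final = _make_estimator(config, best_params)
    final.fit(X, y)
    booster = final.get_booster()
    return TrainedMetaModel(
        svtype=_svtype_of(matrix),
        booster=booster,
        feature_names=list(X.columns),
        importances=_gain_importances(booster, X.columns),
        hyperparameters=best_params,
        cv_auc=best_auc,
        decision_threshold=config.decision_threshold,
        registry_hash=matrix.registry_hash,
        seed=config.seed,
    )


def _svtype_of(matrix: FeatureMatrix) -> SVType:
    return matrix.svtype if matrix.svtype is not None else SVType.DEL


def prune_zero_importance(
    model: TrainedMetaModel,
    matrix: FeatureMatrix,
    config: TrainingConfig,
) -> TrainedMetaModel:
    """Drop zero-gain features and re-run the grid search until none remain.

    Stops at a fixpoint or after ``config.max_prune_iterations`` rounds; a
    feature with positive gain is never removed.
    """
    current = model
    for _ in range(config.max_prune_iterations):
        zero = [f for f in current.feature_names if current.importances[f] == 0.0]
        if not zero:
            break
        retained = [f for f in current.feature_names if f not in zero]
        if not retained:
            raise TrainingError("pruning removed every feature")
        svtype = current.svtype
        current = grid_search_train(matrix, config, feature_names=retained)
        current.svtype = svtype
    return current


def predict_probabilities(model: TrainedMetaModel, matrix: FeatureMatrix) -> np.ndarray:
    """TP probability per row, in the row order of ``matrix``."""
    if model.registry_hash and matrix.registry_hash and model.registry_hash != matrix.registry_hash:
        raise ValueError(
            "feature-registry mismatch: the model was trained on features "
            f"built under registry {model.registry_hash}, got {matrix.registry_hash}"
        )
    X = _prepared(matrix, model.feature_names)
    dmat = xgb.DMatrix(X, missing=np.nan, feature_names=model.feature_names)
    probs = model.booster.predict(dmat).astype(float)
    return np.clip(probs, 0.0, 1.0)


def classify(probabilities: Sequence[float], threshold: float = 0.5) -> np.ndarray:
    """Positive iff probability >= threshold (inclusive bound)."""
    return np.asarray(probabilities, dtype=float) >= threshold
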