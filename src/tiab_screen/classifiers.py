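"""The four candidate learners and their grid-search tuning.

Methods: a kernel method (SVM with RBF kernel), a linear model (logistic
regression, no hyperparameters), and two tree ensembles — bagging (random
forest, probability = fraction of trees voting include) and boosting
(histogram gradient-boosted trees, the LightGBM-style algorithm available
in scikit-learn).

Hyperparameters are chosen by exhaustive grid search with stratified 5-fold
cross-validation on the training set scored by AUC; ties break toward the
first grid point in declared order.  No resampling or class weighting is
applied — class imbalance is handled downstream at the cutoff stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import ParameterGrid, StratifiedKFold
from sklearn.svm import SVC

from .corpus_io import Label
from .features import DocumentTermMatrix, labels_to_binary

logger = logging.getLogger(__name__)

__all__ = [
    "METHODS",
    "ClassifierSpec",
    "TrainedClassifier",
    "default_grid",
    "tune_and_fit",
    "predict_inclusion_probability",
]

METHODS = ("svm", "logistic_regression", "random_forest", "gradient_boosted_trees")

_DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "svm": {"C": [0.1, 1.0, 10.0], "gamma_factor": [0.5, 1.0, 2.0]},
    "logistic_regression": {},
    "random_forest": {"n_estimators": [500], "max_features_factor": [0.5, 1.0, 2.0]},
    "gradient_boosted_trees": {
        "learning_rate": [0.05, 0.1],
        "max_leaf_nodes": [15, 31],
        "max_iter": [200],
    },
}


def default_grid(method: str) -> dict[str, list]:
    return {k: list(v) for k, v in _DEFAULT_GRIDS[method].items()}


@dataclass(frozen=True)
class ClassifierSpec:
    """Which learner to train and how to tune it."""

    method: str
    hyperparameter_grid: Mapping[str, Sequence] | None = None
    tuning_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")
        grid = self.hyperparameter_grid
        if grid is None:
            grid = default_grid(self.method)
            object.__setattr__(self, "hyperparameter_grid", grid)
        if self.method != "logistic_regression" and not grid:
            raise ValueError(f"method {self.method!r} requires a non-empty grid")

    def grid_points(self) -> list[dict]:
        if not self.hyperparameter_grid:
            return [{}]
        # ParameterGrid sorts keys but preserves candidate order per key;
        # iteration order is deterministic, so "first grid point" is defined
        return list(ParameterGrid(dict(self.hyperparameter_grid)))


def _build_estimator(method: str, params: Mapping, n_features: int, seed: int):
    if method == "svm":
        gamma = params.get("gamma_factor", 1.0) / max(n_features, 1)
        # probability=True fits a monotone (Platt sigmoid) mapping of
        # decision values by internal cross-validation on the training folds
        return SVC(
            kernel=params.get("kernel", "rbf"),
            C=params.get("C", 1.0),
            gamma=gamma,
            probability=True,
            random_state=seed,
        )
    if method == "logistic_regression":
        # near-unpenalized; the tiny l2 term keeps separable fits finite
        return LogisticRegression(C=1e4, max_iter=2000, solver="lbfgs")
    if method == "random_forest":
        max_features = max(
            1,
            min(
                n_features,
                int(round(params.get("max_features_factor", 1.0) * np.sqrt(n_features))),
            ),
        )
        return RandomForestClassifier(
            n_estimators=params.get("n_estimators", 500),
            max_features=max_features,
            random_state=seed,
            n_jobs=1,
        )
    if method == "gradient_boosted_trees":
        return HistGradientBoostingClassifier(
            learning_rate=params.get("learning_rate", 0.1),
            max_leaf_nodes=params.get("max_leaf_nodes", 31),
            max_iter=params.get("max_iter", 200),
            early_stopping=False,
            random_state=seed,
        )
    raise ValueError(method)


def _proba(method: str, estimator, X: np.ndarray) -> np.ndarray:
    if method == "random_forest":
        # majority-vote semantics: probability = share of trees voting include
        votes = np.stack([tree.predict(X) for tree in estimator.estimators_])
        return votes.mean(axis=0)
    pos = list(estimator.classes_).index(1)
    return estimator.predict_proba(X)[:, pos]


@dataclass(frozen=True)
class TrainedClassifier:
    """A tuned, fitted model exposing inclusion probabilities."""

    spec: ClassifierSpec
    chosen_hyperparameters: dict
    fit_state: object = field(repr=False)
    training_vocabulary: tuple[str, ...] = ()
    cv_auc_by_grid_point: tuple[float, ...] = ()

    def save_metadata(self, path: str | Path, training_ids: Sequence[str] = ()) -> None:
        vocab_hash = hashlib.sha256(
            "\n".join(self.training_vocabulary).encode()
        ).hexdigest()[:16]
        Path(path).write_text(
            json.dumps(
                {
                    "method": self.spec.method,
                    "chosen_hyperparameters": self.chosen_hyperparameters,
                    "seed": self.spec.seed,
                    "tuning_folds": self.spec.tuning_folds,
                    "n_training_ids": len(training_ids),
                    "training_ids": list(training_ids),
                    "vocabulary_hash": vocab_hash,
                },
                indent=2,
            )
            + "\n"
        )


def tune_and_fit(
    spec: ClassifierSpec,
    dtm: DocumentTermMatrix,
    labels: Sequence[Label] | np.ndarray,
) -> TrainedClassifier:
    """Grid search with stratified K-fold CV on AUC, then refit on all rows.

    Every grid point is evaluated on the same folds; the best mean AUC wins
    and ties break toward the earlier grid point.  The DTM must already be
    reduced to the selected features.
    """
    y = labels if isinstance(labels, np.ndarray) else labels_to_binary(labels)
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present to fit a classifier")
    if len(y) != dtm.n:
        raise ValueError("labels length does not match number of documents")

    X = dtm.counts.toarray().astype(np.float64)
    points = spec.grid_points()

    if len(points) == 1:
        best_params, cv_aucs = points[0], ()
    else:
        skf = StratifiedKFold(
            n_splits=spec.tuning_folds, shuffle=True, random_state=spec.seed
        )
        folds = list(skf.split(X, y))
        mean_aucs = []
        for params in points:
            fold_aucs = []
            for train_idx, val_idx in folds:
                est = _build_estimator(spec.method, params, dtm.p, spec.seed)
                est.fit(X[train_idx], y[train_idx])
                probs = _proba(spec.method, est, X[val_idx])
                fold_aucs.append(roc_auc_score(y[val_idx], probs))
            mean_aucs.append(float(np.mean(fold_aucs)))
        best_idx = int(np.argmax(mean_aucs))  # argmax returns the first maximum
        best_params = points[best_idx]
        cv_aucs = tuple(mean_aucs)
        logger.info(
            "%s grid search: chose %s (CV AUC %.4f)",
            spec.method, best_params, mean_aucs[best_idx],
        )

    estimator = _build_estimator(spec.method, best_params, dtm.p, spec.seed)
    estimator.fit(X, y)
    return TrainedClassifier(
        spec=spec,
        chosen_hyperparameters=dict(best_params),
        fit_state=estimator,
        training_vocabulary=dtm.vocabulary,
        cv_auc_by_grid_point=cv_aucs,
    )


def predict_inclusion_probability(
    model: TrainedClassifier, dtm: DocumentTermMatrix
) -> np.ndarray:
    """Inclusion probability in [0, 1] for every row of *dtm*.

    The DTM vocabulary must equal the model's training vocabulary; project
    test bags through the features module first.
    """
    if dtm.vocabulary != model.training_vocabulary:
        raise ValueError(
            "vocabulary mismatch: project the test matrix onto the model's "
            "training vocabulary before predicting"
        )
    X = dtm.counts.toarray().astype(np.float64)
    probs = _proba(model.spec.method, model.fit_state, X)
    return np.clip(probs, 0.0, 1.0)
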