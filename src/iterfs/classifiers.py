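"""Registry of the five classifier families used by the framework.

The framework is model-agnostic; this module supplies its default mixture
of experts — random forest, (unpenalised) logistic regression, k-nearest
neighbours, an information-gain decision tree standing in for the C5.0
family, and an RBF support-vector machine. Each family carries a small
tuning grid; grid search with stratified internal CV runs once per
(subset, classifier) on the training partition, not per Monte-Carlo
iteration. Distance- and margin-based models (knn, svm_rbf) get centring
and scaling inside their pipeline, so scaling parameters are always
estimated on the training portion only.

Additional families can be registered without touching framework logic::

    register_classifier("my_model", ClassifierSpec(...))
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Callable

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

if TYPE_CHECKING:
    from .config import RunConfig

__all__ = [
    "ClassifierSpec",
    "register_classifier",
    "classifier_registry",
    "build_classifier",
    "tune_classifier",
    "fit_predict",
]


@dataclass(frozen=True)
class ClassifierSpec:
    """One classifier family: a builder, a grid factory and a scaling flag."""

    classifier_id: str
    builder: Callable[[dict, int, "RunConfig"], BaseEstimator]
    grid: Callable[[np.ndarray, np.ndarray, "RunConfig"], dict[str, list]]
    needs_scaling: bool


def _wrap_scaled(estimator: BaseEstimator) -> Pipeline:
    return Pipeline([("scale", StandardScaler()), ("model", estimator)])


# -- builders -----------------------------------------------------------


def _build_rf(params: dict, seed: int, config: "RunConfig") -> BaseEstimator:
    return RandomForestClassifier(
        n_estimators=config.rf_trees, random_state=seed, n_jobs=1, **params
    )


def _grid_rf(X: np.ndarray, y: np.ndarray, config: "RunConfig") -> dict[str, list]:
    p = X.shape[1]
    candidates = sorted({max(1, int(np.sqrt(p))), max(1, p // 3), p})
    return {"max_features": candidates}


def _build_logistic(params: dict, seed: int, config: "RunConfig") -> BaseEstimator:
    return LogisticRegression(C=np.inf, max_iter=2000, **params)


def _grid_logistic(X: np.ndarray, y: np.ndarray, config: "RunConfig") -> dict[str, list]:
    return {}


def _build_knn(params: dict, seed: int, config: "RunConfig") -> BaseEstimator:
    return _wrap_scaled(KNeighborsClassifier(**{k.removeprefix("model__"): v for k, v in params.items()}))


def _grid_knn(X: np.ndarray, y: np.ndarray, config: "RunConfig") -> dict[str, list]:
    n = X.shape[0]
    ks = [k for k in (3, 5, 7, 9, 11) if k < n]
    return {"model__n_neighbors": ks or [1]}


def _build_tree(params: dict, seed: int, config: "RunConfig") -> BaseEstimator:
    return DecisionTreeClassifier(criterion="entropy", random_state=seed, **params)


def _grid_tree(X: np.ndarray, y: np.ndarray, config: "RunConfig") -> dict[str, list]:
    # pruning strength plays the role of the C5.0 confidence factor
    return {"ccp_alpha": [0.0, 0.01, 0.05], "min_samples_leaf": [1, 5]}


def _build_svm(params: dict, seed: int, config: "RunConfig") -> BaseEstimator:
    return _wrap_scaled(SVC(random_state=seed, **{k.removeprefix("model__"): v for k, v in params.items()}))


def _median_heuristic_gamma(X: np.ndarray) -> float:
    """1 / median squared pairwise distance on standardised features."""
    Xs = StandardScaler().fit_transform(X)
    if Xs.shape[0] > 200:  # a subsample is plenty for a median
        rng = np.random.default_rng(0)
        Xs = Xs[rng.choice(Xs.shape[0], 200, replace=False)]
    sq = np.sum((Xs[:, None, :] - Xs[None, :, :]) ** 2, axis=-1)
    med = float(np.median(sq[np.triu_indices_from(sq, k=1)]))
    if med <= 0:
        return 1.0 / max(1, X.shape[1])
    return 1.0 / med


def _grid_svm(X: np.ndarray, y: np.ndarray, config: "RunConfig") -> dict[str, list]:
    g0 = _median_heuristic_gamma(X)
    return {
        "model__C": [0.25, 0.5, 1.0, 2.0, 4.0],
        "model__gamma": [g0 / 2, g0, 2 * g0],
    }


_REGISTRY: dict[str, ClassifierSpec] = {}


def register_classifier(classifier_id: str, spec: ClassifierSpec) -> None:
    _REGISTRY[classifier_id] = spec


def classifier_registry() -> dict[str, ClassifierSpec]:
    return dict(_REGISTRY)


for _spec in (
    ClassifierSpec("random_forest", _build_rf, _grid_rf, needs_scaling=False),
    ClassifierSpec("logistic", _build_logistic, _grid_logistic, needs_scaling=False),
    ClassifierSpec("knn", _build_knn, _grid_knn, needs_scaling=True),
    ClassifierSpec("tree", _build_tree, _grid_tree, needs_scaling=False),
    ClassifierSpec("svm_rbf", _build_svm, _grid_svm, needs_scaling=True),
):
    register_classifier(_spec.classifier_id, _spec)


def _get_spec(classifier_id: str) -> ClassifierSpec:
    try:
        return _REGISTRY[classifier_id]
    except KeyError:
        raise KeyError(
            f"unregistered classifier {classifier_id!r}; known: {sorted(_REGISTRY)}"
        ) from None


def tune_classifier(
    classifier_id: str,
    X: np.ndarray,
    y: np.ndarray,
    seed: int,
    config: "RunConfig",
) -> dict:
    """Grid-search hyperparameters by stratified internal CV on training data."""
    spec = _get_spec(classifier_id)
    grid = dict(spec.grid(X, y, config))
    grid.update(config.grids.get(classifier_id, {}))
    if not grid:
        return {}
    min_class = int(min(np.bincount(np.asarray(y, dtype=int), minlength=2)))
    n_splits = max(2, min(5, min_class))
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    search = GridSearchCV(
        spec.builder({}, seed, config),
        grid,
        scoring="balanced_accuracy",
        cv=cv,
        refit=False,
        n_jobs=1,
    )
    search.fit(X, y)
    return dict(search.best_params_)


def build_classifier(
    classifier_id: str, params: dict, seed: int, config: "RunConfig"
) -> BaseEstimator:
    return _get_spec(classifier_id).builder(params, seed, config)


def fit_predict(
    classifier_id: str,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    seed: int,
    config: "RunConfig",
    params: dict | None = None,
) -> np.ndarray:
    """Tune (unless given), fit on train, predict the test cases."""
    if params is None:
        params = tune_classifier(classifier_id, X_train, y_train, seed, config)
    model = build_classifier(classifier_id, params, seed, config)
    model.fit(X_train, y_train)
    return model.predict(X_test)
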