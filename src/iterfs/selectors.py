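"""The two feature-selection experts.

``BorutaSelector`` re-implements the all-relevant shadow-feature scheme:
each run appends one permuted ("shadow") copy of every still-undecided
feature, fits a random forest on the augmented matrix, and records a *hit*
for every undecided feature whose importance exceeds the maximum shadow
importance. After each run a two-sided binomial test against
Binomial(runs, 0.5), Bonferroni-corrected across the undecided features,
confirms features with significantly more hits and rejects those with
significantly fewer; whatever is still undecided at ``max_runs`` is
tentative. Only confirmed features count as selected.

``SparseLogisticSelector`` fits an l1-penalised binomial model over a
data-driven regularisation path (100 values, glmnet-style maximum) and
keeps the penalty strength minimising 5-fold cross-validated deviance
(the lambda-min rule); features with non-zero coefficients there are
selected. Its tentative set is empty by construction.

Both estimators canonicalise the internal column order by a content hash
before fitting, so a column permutation of the input (with the same seed)
reproduces the same partition after inverse mapping.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import binomtest
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import SelectorMixin
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted, validate_data

from ._seeds import derive_seed
from .config import RunConfig
from .data import LabeledDataset

__all__ = [
    "SelectionResult",
    "BorutaSelector",
    "SparseLogisticSelector",
    "shadow_forest_select",
    "sparse_logistic_select",
    "run_selector",
    "selector_registry",
]


@dataclass(frozen=True)
class SelectionResult:
    """One selector's partition of the input features.

    ``selected``, ``tentative`` and ``rejected`` partition the feature
    set; ``scores`` holds the importance (shadow-forest) or absolute
    coefficient (sparse-logistic) per feature.
    """

    selector_id: str
    selected: tuple[str, ...]
    tentative: tuple[str, ...]
    rejected: tuple[str, ...]
    scores: dict[str, float]

    def __post_init__(self) -> None:
        parts = [set(self.selected), set(self.tentative), set(self.rejected)]
        if sum(len(s) for s in parts) != len(set().union(*parts)):
            raise ValueError("selected/tentative/rejected must be disjoint")

    def to_table(self):
        import pandas as pd

        rows = [
            (name, status, self.scores.get(name, float("nan")))
            for status, names in (
                ("selected", self.selected),
                ("tentative", self.tentative),
                ("rejected", self.rejected),
            )
            for name in names
        ]
        return pd.DataFrame(rows, columns=["feature", "status", "score"])


def _content_order(X: np.ndarray) -> np.ndarray:
    """Canonical column order by content hash (permutation-invariant)."""
    keys = [hashlib.sha256(np.ascontiguousarray(X[:, j]).tobytes()).hexdigest() for j in range(X.shape[1])]
    return np.array(sorted(range(X.shape[1]), key=lambda j: (keys[j], j)))


class BorutaSelector(SelectorMixin, BaseEstimator):
    """All-relevant feature selection with shadow features and a random forest.

    Parameters
    ----------
    n_estimators : int, default 500
        Trees per forest.
    max_runs : int, default 100
        Importance-estimation runs before undecided features become tentative.
    alpha : float, default 0.01
        Level of the per-feature binomial test, Bonferroni-corrected across
        the undecided features.
    importance : {"permutation", "impurity"}, default "permutation"
        Permutation importance (mean accuracy decrease) or impurity decrease.
    n_repeats : int, default 5
        Permutation-importance repeats per run.

    Attributes
    ----------
    support_ : bool array — confirmed features only.
    confirmed_, tentative_, rejected_ : index arrays partitioning the columns.
    importances_ : mean importance per original feature across runs.
    n_runs_ : runs actually performed.
    """

    def __init__(
        self,
        n_estimators: int = 500,
        max_runs: int = 100,
        alpha: float = 0.01,
        importance: str = "permutation",
        n_repeats: int = 5,
        random_state: int | None = None,
    ):
        self.n_estimators = n_estimators
        self.max_runs = max_runs
        self.alpha = alpha
        self.importance = importance
        self.n_repeats = n_repeats
        self.random_state = random_state

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        if self.importance not in ("permutation", "impurity"):
            raise ValueError(f"unknown importance type {self.importance!r}")
        seed = 0 if self.random_state is None else int(self.random_state)
        order = _content_order(X)
        Xc = X[:, order]
        n, p = Xc.shape

        UNDECIDED, CONFIRMED, REJECTED = 0, 1, -1
        status = np.full(p, UNDECIDED)
        hits = np.zeros(p, dtype=int)
        imp_sum = np.zeros(p)
        imp_count = np.zeros(p, dtype=int)
        runs = 0

        while runs < self.max_runs and np.any(status == UNDECIDED):
            undecided = np.flatnonzero(status == UNDECIDED)
            active = np.flatnonzero(status != REJECTED)  # confirmed + undecided
            rng_run = np.random.default_rng(derive_seed(seed, "boruta-run", runs))
            shadows = Xc[:, undecided].copy()
            for k in range(shadows.shape[1]):
                rng_run.shuffle(shadows[:, k])
            X_aug = np.hstack([Xc[:, active], shadows])

            forest = RandomForestClassifier(
                n_estimators=self.n_estimators,
                random_state=derive_seed(seed, "boruta-forest", runs),
                n_jobs=1,
            )
            forest.fit(X_aug, y)
            if self.importance == "permutation":
                imp = permutation_importance(
                    forest,
                    X_aug,
                    y,
                    n_repeats=self.n_repeats,
                    random_state=derive_seed(seed, "boruta-perm", runs),
                    scoring="accuracy",
                    n_jobs=1,
                ).importances_mean
            else:
                imp = forest.feature_importances_
            real_imp = imp[: active.size]
            shadow_max = float(np.max(imp[active.size:]))
            imp_sum[active] += real_imp
            imp_count[active] += 1
            pos_of = {feat: i for i, feat in enumerate(active)}
            for feat in undecided:
                if real_imp[pos_of[feat]] > shadow_max:
                    hits[feat] += 1
            runs += 1

            m = undecided.size  # Bonferroni across currently undecided features
            for feat in undecided:
                if binomtest(int(hits[feat]), runs, 0.5, alternative="greater").pvalue < self.alpha / m:
                    status[feat] = CONFIRMED
                elif binomtest(int(hits[feat]), runs, 0.5, alternative="less").pvalue < self.alpha / m:
                    status[feat] = REJECTED

        inv = np.empty(p, dtype=int)
        inv[order] = np.arange(p)
        status = status[inv]
        mean_imp = np.divide(imp_sum, np.maximum(imp_count, 1))[inv]
        self.support_ = status == CONFIRMED
        self.confirmed_ = np.flatnonzero(status == CONFIRMED)
        self.tentative_ = np.flatnonzero(status == UNDECIDED)
        self.rejected_ = np.flatnonzero(status == REJECTED)
        self.importances_ = mean_imp
        self.n_runs_ = runs
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.support_


class SparseLogisticSelector(SelectorMixin, BaseEstimator):
    """Embedded selection by l1-penalised logistic regression at lambda-min.

    Features are standardised internally (coefficients live on that scale);
    the penalty path has ``n_lambdas`` values from a data-driven maximum
    down by the usual ratio (1e-4 when n > p, 1e-2 otherwise), and the CV
    criterion is the binomial deviance.
    """

    def __init__(self, cv: int = 5, n_lambdas: int = 100, random_state: int | None = None):
        self.cv = cv
        self.n_lambdas = n_lambdas
        self.random_state = random_state

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        seed = 0 if self.random_state is None else int(self.random_state)
        order = _content_order(X)
        Xc = X[:, order]
        n, p = Xc.shape

        mean = Xc.mean(axis=0)
        sd = Xc.std(axis=0)
        keep = sd > 0
        Xs = np.zeros_like(Xc)
        Xs[:, keep] = (Xc[:, keep] - mean[keep]) / sd[keep]

        resid = y - y.mean()
        lambda_max = float(np.max(np.abs(Xs.T @ resid)) / n) if keep.any() else 0.0
        coef = np.zeros(p)
        if lambda_max > 0:
            ratio = 1e-4 if n > p else 1e-2
            lambdas = np.geomspace(lambda_max, lambda_max * ratio, self.n_lambdas)
            Cs = 1.0 / (n * lambdas)  # sklearn's C versus glmnet's per-case lambda
            folds = StratifiedKFold(n_splits=self.cv, shuffle=True, random_state=seed)
            model = LogisticRegressionCV(
                Cs=Cs,
                cv=folds,
                penalty="l1",
                solver="liblinear",
                scoring="neg_log_loss",
                max_iter=2000,
                random_state=seed,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", FutureWarning)
                model.fit(Xs, y)
            coef = model.coef_.ravel().copy()
            self.lambda_min_ = float(1.0 / (n * model.C_[0]))
            self.intercept_ = float(model.intercept_[0])
        else:
            self.lambda_min_ = 0.0
            self.intercept_ = float(np.log(y.mean() / (1 - y.mean()))) if 0 < y.mean() < 1 else 0.0

        inv = np.empty(p, dtype=int)
        inv[order] = np.arange(p)
        self.coef_ = coef[inv]
        self.support_ = np.abs(self.coef_) > 0
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.support_


# -- LabeledDataset-facing wrappers ------------------------------------


def _result_from_masks(
    selector_id: str,
    names: tuple[str, ...],
    selected_mask: np.ndarray,
    tentative_mask: np.ndarray,
    scores: np.ndarray,
) -> SelectionResult:
    selected = tuple(n for n, s in zip(names, selected_mask) if s)
    tentative = tuple(n for n, t in zip(names, tentative_mask) if t)
    decided = set(selected) | set(tentative)
    rejected = tuple(n for n in names if n not in decided)
    return SelectionResult(
        selector_id=selector_id,
        selected=selected,
        tentative=tentative,
        rejected=rejected,
        scores={n: float(s) for n, s in zip(names, scores)},
    )


def shadow_forest_select(train: LabeledDataset, config: RunConfig) -> SelectionResult:
    """Run the shadow-feature random-forest selector on a training partition."""
    est = BorutaSelector(
        n_estimators=config.boruta_trees,
        max_runs=config.boruta_max_runs,
        alpha=config.boruta_alpha,
        importance=config.boruta_importance,
        n_repeats=config.boruta_n_repeats,
        random_state=config.derived_seed("selector", "boruta", ",".join(sorted(train.feature_names))),
    )
    est.fit(train.features, train.y01)
    tentative_mask = np.zeros(train.n_features, dtype=bool)
    tentative_mask[est.tentative_] = True
    return _result_from_masks(
        "boruta", train.feature_names, est.support_, tentative_mask, est.importances_
    )


def sparse_logistic_select(train: LabeledDataset, config: RunConfig) -> SelectionResult:
    """Run the sparse CV-logistic selector on a training partition."""
    est = SparseLogisticSelector(
        cv=config.lasso_cv_folds,
        n_lambdas=config.lasso_path_length,
        random_state=config.derived_seed("selector", "lasso", ",".join(sorted(train.feature_names))),
    )
    est.fit(train.features, train.y01)
    no_tentative = np.zeros(train.n_features, dtype=bool)
    return _result_from_masks(
        "lasso", train.feature_names, est.support_, no_tentative, np.abs(est.coef_)
    )


_SELECTORS = {"boruta": shadow_forest_select, "lasso": sparse_logistic_select}


def selector_registry() -> dict:
    return dict(_SELECTORS)


def run_selector(selector_id: str, train: LabeledDataset, config: RunConfig) -> SelectionResult:
    try:
        fn = _SELECTORS[selector_id]
    except KeyError:
        raise KeyError(f"unknown selector {selector_id!r}; known: {sorted(_SELECTORS)}") from None
    return fn(train, config)
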