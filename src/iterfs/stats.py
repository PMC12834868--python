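"""Comparative classical-statistics battery.

Everything a reviewer would run next to the machine-learning framework:
per-feature standardised effect sizes with bootstrap CIs and two-sample
tests, the clustered absolute-correlation structure, multicollinearity
diagnostics (VIF with explicit aliasing detection), the all-subsets
logistic-regression stability scan, and penalised logistic regression
under ridge / lasso / elastic-net penalties with their respective
selection rules (non-zero at lambda-min; |coef| > 0.05 on the
standardised scale for ridge).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import chain, combinations
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import statsmodels.api as sm
from scipy.spatial.distance import squareform
from scipy.stats import ttest_ind
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

from .data import LabeledDataset

__all__ = [
    "EffectSizeResult",
    "CollinearityReport",
    "ScanStatusMatrix",
    "PenalisedSelection",
    "cohens_d_with_ci",
    "effect_size_table",
    "correlation_structure",
    "vif_report",
    "subset_regression_scan",
    "penalised_logistic_select",
]

_ALIAS_TOL = 1e-8
RIDGE_COEF_THRESHOLD = 0.05  # standardised-predictor scale


@dataclass(frozen=True)
class EffectSizeResult:
    feature: str
    d: float
    ci_low: float
    ci_high: float
    t_statistic: float
    p_value: float


def cohens_d_with_ci(
    x: np.ndarray,
    y: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    feature: str = "",
    test: str = "welch",
) -> EffectSizeResult:
    """Cohen's d (group1 - group2, pooled SD) with a percentile bootstrap CI.

    The two-sample test is Welch's by default (``test="student"`` switches
    to the equal-variance variant). Sign convention: positive d means the
    first group's mean is larger; the estimate is antisymmetric under
    group swap.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")

    def _d(a: np.ndarray, b: np.ndarray) -> float:
        na, nb = a.size, b.size
        pooled = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        if pooled <= 0:
            raise ValueError("zero pooled variance: effect size undefined")
        return float((a.mean() - b.mean()) / np.sqrt(pooled))

    d = _d(x, y)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        xb = x[rng.integers(0, x.size, x.size)]
        yb = y[rng.integers(0, y.size, y.size)]
        try:
            boots[b] = _d(xb, yb)
        except ValueError:
            boots[b] = d  # degenerate resample: fall back to the point estimate
    lo, hi = np.quantile(boots, [0.025, 0.975])
    t_res = ttest_ind(x, y, equal_var=(test == "student"))
    return EffectSizeResult(feature, d, float(lo), float(hi), float(t_res.statistic), float(t_res.pvalue))


def effect_size_table(dataset: LabeledDataset, n_boot: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Per-feature Cohen's d (positive minus negative class) with CI and test."""
    y = dataset.y01
    rows = []
    for j, name in enumerate(dataset.feature_names):
        col = dataset.features[:, j]
        res = cohens_d_with_ci(col[y == 1], col[y == 0], n_boot=n_boot, seed=seed + j, feature=name)
        rows.append(
            (name, res.d, res.ci_low, res.ci_high, res.t_statistic, res.p_value)
        )
    return pd.DataFrame(rows, columns=["feature", "d", "ci_low", "ci_high", "t", "p"])


def correlation_structure(dataset: LabeledDataset) -> pd.DataFrame:
    """Absolute Pearson correlations, rows/columns ordered by Ward clustering.

    Clustering runs on the distance 1 - |r|. Zero-variance features have
    undefined correlations; they are excluded from the ordering and
    reported in the frame's ``attrs['excluded']``.
    """
    X = dataset.features
    sd = X.std(axis=0)
    keep = np.flatnonzero(sd > 0)
    excluded = [dataset.feature_names[j] for j in np.flatnonzero(sd == 0)]
    names = [dataset.feature_names[j] for j in keep]
    if len(keep) < 2:
        raise ValueError("need at least 2 non-constant features")
    corr = np.abs(np.corrcoef(X[:, keep], rowvar=False))
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    linkage = sch.linkage(squareform(dist, checks=False), method="ward")
    order = sch.leaves_list(linkage)
    frame = pd.DataFrame(corr[np.ix_(order, order)],
                         index=[names[i] for i in order],
                         columns=[names[i] for i in order])
    frame.attrs["excluded"] = excluded
    return frame


# -- multicollinearity --------------------------------------------------


@dataclass(frozen=True)
class CollinearityReport:
    vif: dict[str, float]          # finite VIFs for non-aliased features
    aliased: tuple[str, ...]       # features in exact linear dependencies
    aliased_sets: tuple[tuple[str, ...], ...]
    flagged: tuple[str, ...]       # VIF > 10
    degenerate: bool               # n <= p: VIFs not meaningful

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, value in self.vif.items():
            rows.append((name, value, name in self.flagged, False))
        for name in self.aliased:
            rows.append((name, np.nan, True, True))
        return pd.DataFrame(rows, columns=["feature", "vif", "flagged", "aliased"])


def _aliased_groups(X: np.ndarray, names: Sequence[str]) -> list[tuple[str, ...]]:
    """Groups of features in exact linear dependence (from the null space)."""
    Xc = X - X.mean(axis=0)
    scale = np.linalg.norm(Xc, axis=0)
    scale[scale == 0] = 1.0
    _, s, vt = np.linalg.svd(Xc / scale, full_matrices=True)
    p = Xc.shape[1]
    tol = _ALIAS_TOL * max(1.0, s.max(initial=1.0))
    null_mask = np.array([(s[i] < tol) if i < s.size else True for i in range(p)])
    groups: list[tuple[str, ...]] = []
    for vec in vt[null_mask]:
        members = tuple(names[j] for j in np.flatnonzero(np.abs(vec) > 1e-6))
        if members and members not in groups:
            groups.append(members)
    return groups


def vif_report(dataset: LabeledDataset, threshold: float = 10.0) -> CollinearityReport:
    """Variance inflation factors with explicit aliasing detection.

    VIF_j = 1/(1 - R^2_j) from regressing feature j on all other features
    (with intercept). Exact dependencies are found by rank analysis first;
    members of such groups get no numeric VIF. With n <= p the whole
    design is flagged degenerate instead of reporting numbers.
    """
    X = dataset.features
    names = dataset.feature_names
    n, p = X.shape
    if p < 2:
        raise ValueError("VIF needs at least 2 features")
    if n <= p:
        return CollinearityReport({}, (), (), (), degenerate=True)
    groups = _aliased_groups(X, names)
    aliased = tuple(sorted(set(chain.from_iterable(groups))))
    keep = [j for j, name in enumerate(names) if name not in aliased]
    vifs: dict[str, float] = {}
    for j in keep:
        others = [k for k in keep if k != j]
        target = X[:, j]
        if not others:
            vifs[names[j]] = 1.0
            continue
        design = np.column_stack([np.ones(n), X[:, others]])
        beta, *_ = np.linalg.lstsq(design, target, rcond=None)
        resid = target - design @ beta
        tss = float(np.sum((target - target.mean()) ** 2))
        if tss == 0:
            vifs[names[j]] = 1.0
            continue
        r2 = 1.0 - float(np.sum(resid**2)) / tss
        vifs[names[j]] = float(1.0 / max(1.0 - r2, 1e-12))
    flagged = tuple(name for name, v in vifs.items() if v > threshold)
    return CollinearityReport(vifs, aliased, tuple(groups), flagged, degenerate=False)


# -- all-subsets regression stability scan ------------------------------


@dataclass(frozen=True)
class ScanStatusMatrix:
    """Per-model x per-feature status codes for the stability scan.

    Cell values: ``removed`` (feature excluded from that model), ``ok``
    (Wald significance at 0.05 agrees with the reference), ``wrong``
    (disagrees), ``aliased_na`` (coefficient undefined: aliasing or
    non-convergence). The last row is the full model.
    """

    matrix: pd.DataFrame  # rows: removal scenarios; columns: features

    def to_long(self) -> pd.DataFrame:
        long = self.matrix.stack().rename_axis(["model", "feature"]).reset_index(name="status")
        return long


def _independent_columns(X: np.ndarray) -> np.ndarray:
    """Greedy left-to-right choice of columns that keep the design full rank."""
    n = X.shape[0]
    kept: list[int] = []
    basis = np.ones((n, 1)) / np.sqrt(n)  # intercept
    for j in range(X.shape[1]):
        col = X[:, j].astype(float)
        resid = col - basis @ (basis.T @ col)
        norm = np.linalg.norm(resid)
        if norm > _ALIAS_TOL * max(1.0, np.linalg.norm(col)):
            basis = np.column_stack([basis, resid / norm])
            kept.append(j)
    return np.array(kept, dtype=int)


def subset_regression_scan(
    dataset: LabeledDataset,
    candidate_removals: Sequence[str],
    reference_significant: Sequence[str],
    alpha: float = 0.05,
) -> ScanStatusMatrix:
    """Logistic-regression stability across all removal subsets.

    For every subset of ``candidate_removals`` (the suspected collinear or
    redundant variables) a binomial model is fitted on the remaining
    features. Each remaining feature is ``ok`` when its Wald significance
    at ``alpha`` agrees with its membership in ``reference_significant``
    (the user-supplied ground truth), ``wrong`` when it disagrees and
    ``aliased_na`` when its coefficient is undefined.
    """
    candidate_removals = dataset.check_subset(candidate_removals)
    reference = set(dataset.check_subset(reference_significant))
    names = dataset.feature_names
    y = dataset.y01

    scenarios: list[tuple[str, frozenset]] = []
    for k in range(len(candidate_removals), 0, -1):
        for combo in combinations(candidate_removals, k):
            scenarios.append(("-" + "-".join(combo), frozenset(combo)))
    scenarios.append(("full_model", frozenset()))

    rows = {}
    for label, removed in scenarios:
        statuses = {name: "removed" if name in removed else "aliased_na" for name in names}
        kept_names = [n for n in names if n not in removed]
        X = dataset.columns(kept_names)
        indep = _independent_columns(X)
        model_names = [kept_names[j] for j in indep]
        design = sm.add_constant(X[:, indep], has_constant="add")
        try:
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
            converged = bool(fit.mle_retvals.get("converged", True))
            pvalues = fit.pvalues[1:]
        except Exception:
            converged = False
            pvalues = None
        if converged and pvalues is not None and np.all(np.isfinite(pvalues)):
            for name, p in zip(model_names, pvalues):
                significant = p < alpha
                statuses[name] = "ok" if significant == (name in reference) else "wrong"
        rows[label] = statuses
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=list(names))
    return ScanStatusMatrix(matrix)


# -- penalised logistic regression -------------------------------------


@dataclass(frozen=True)
class PenalisedSelection:
    penalty: str  # ridge | lasso | elastic
    coef: dict[str, float]      # standardised-scale coefficients at lambda-min
    selected: dict[str, bool]
    lambda_min: float


def penalised_logistic_select(
    dataset: LabeledDataset,
    penalty: str,
    alpha: float = 0.5,
    folds: int = 5,
    seed: int = 0,
    n_lambdas: int = 100,
) -> PenalisedSelection:
    """Ridge / lasso / elastic-net logistic regression at lambda-min.

    The path is fitted on standardised predictors; the penalty strength is
    the deviance-minimising value under stratified ``folds``-fold CV.
    Selection rule: non-zero coefficient for lasso and elastic net,
    |coefficient| > 0.05 (standardised scale) for ridge.
    """
    if penalty not in ("ridge", "lasso", "elastic"):
        raise ValueError(f"penalty must be ridge, lasso or elastic, got {penalty!r}")
    if folds < 3:
        raise ValueError("folds must be >= 3")
    X = dataset.features
    y = dataset.y01
    n, p = X.shape
    mean, sd = X.mean(axis=0), X.std(axis=0)
    live = sd > 0
    Xs = np.zeros_like(X)
    Xs[:, live] = (X[:, live] - mean[live]) / sd[live]

    l1_ratio = {"ridge": 0.0, "lasso": 1.0, "elastic": alpha}[penalty]
    resid = y - y.mean()
    grad_max = float(np.max(np.abs(Xs.T @ resid)) / n) if live.any() else 1e-3
    # glmnet-style maximum: the l1 component bounds the start of the path;
    # for ridge (no l1 component) extend well beyond the lasso maximum.
    lambda_top = grad_max / max(l1_ratio, 1e-3)
    ratio = 1e-4 if n > p else 1e-2
    lambdas = np.geomspace(max(lambda_top, 1e-8), max(lambda_top, 1e-8) * ratio, n_lambdas)
    Cs = 1.0 / (n * lambdas)

    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    kwargs: dict = {"scoring": "neg_log_loss", "max_iter": 5000, "random_state": seed, "cv": cv, "Cs": Cs}
    if penalty == "ridge":
        model = LogisticRegressionCV(penalty="l2", solver="lbfgs", **kwargs)
    elif penalty == "lasso":
        model = LogisticRegressionCV(penalty="l1", solver="liblinear", **kwargs)
    else:
        model = LogisticRegressionCV(penalty="elasticnet", solver="saga", l1_ratios=[alpha], **kwargs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        model.fit(Xs, y)
    coef = model.coef_.ravel()
    lambda_min = float(1.0 / (n * model.C_[0]))
    if penalty == "ridge":
        selected = np.abs(coef) > RIDGE_COEF_THRESHOLD
    else:
        selected = np.abs(coef) > 0
    return PenalisedSelection(
        penalty,
        {name: float(c) for name, c in zip(dataset.feature_names, coef)},
        {name: bool(s) for name, s in zip(dataset.feature_names, selected)},
        lambda_min,
    )
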