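"""Monte-Carlo cross-validation, balanced accuracy and the success criterion.

The evaluation protocol has two stages. A single stratified split sets
aside a fixed validation partition (default 20%) before any feature
selection. Then, for every (feature subset, classifier) pair, a fresh
stratified 80% subsample of the training partition is used to fit the
classifier and a fresh stratified 80% subsample of the validation
partition to score it, repeated ``n_iterations`` times. The balanced
accuracies of those iterations yield a median and a non-parametric
confidence interval; classification *succeeds* when at least one
classifier's CI lower bound strictly exceeds the chance level (0.5).

Quantile convention: linear interpolation between order statistics (the
default of mainstream statistical environments), used for every CI here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .classifiers import build_classifier, tune_classifier
from .config import RunConfig
from .data import LabeledDataset

__all__ = [
    "ConfusionCounts",
    "PerformanceEstimate",
    "SubsetEvaluation",
    "UndefinedMetricError",
    "balanced_accuracy",
    "percentile_ci",
    "round_half_up",
    "SplitPlan",
    "stratified_split",
    "stratified_subsample",
    "mc_evaluate",
    "subset_success",
    "Evaluator",
]


class UndefinedMetricError(ValueError):
    """A class is absent from the evaluated cases."""


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts with the positive level fixed by the dataset."""

    tp: int
    fp: int
    tn: int
    fn: int

    @classmethod
    def from_labels(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        )


def balanced_accuracy(counts: ConfusionCounts) -> float:
    """Mean of sensitivity and specificity; 0.5 is chance at any imbalance."""
    pos = counts.tp + counts.fn
    neg = counts.tn + counts.fp
    if pos == 0 or neg == 0:
        raise UndefinedMetricError("balanced accuracy undefined: a class is absent")
    return 0.5 * (counts.tp / pos + counts.tn / neg)


def percentile_ci(samples: Sequence[float], level: float) -> tuple[float, float]:
    """Empirical two-sided CI by linearly interpolated quantiles."""
    samples = np.asarray(samples, dtype=float)
    if samples.size < 2:
        raise ValueError("percentile_ci needs at least 2 samples")
    if not 0 < level < 1:
        raise ValueError(f"level must lie in (0, 1), got {level}")
    tail = (1.0 - level) / 2.0
    low, high = np.quantile(samples, [tail, 1.0 - tail], method="linear")
    return float(low), float(high)


def round_half_up(x: float) -> int:
    """0.5 always rounds away from zero toward +inf (13.8 -> 14, 11.2 -> 11)."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class PerformanceEstimate:
    """Per-iteration balanced-accuracy sample with median and CI."""

    ba_samples: tuple[float, ...]
    median_ba: float
    ci_low: float
    ci_high: float

    @classmethod
    def from_samples(cls, samples: Sequence[float], ci_level: float) -> "PerformanceEstimate":
        samples = tuple(float(s) for s in samples)
        low, high = percentile_ci(samples, ci_level)
        return cls(samples, float(np.median(samples)), low, high)

    def __str__(self) -> str:  # report cell, table style "median [low, high]"
        return f"{self.median_ba:.3f} [{self.ci_low:.3f}, {self.ci_high:.3f}]"


@dataclass(frozen=True)
class SubsetEvaluation:
    """One subset's estimates across classifiers and the success verdict."""

    subset: tuple[str, ...]
    per_classifier: dict[str, PerformanceEstimate]
    success: bool


@dataclass(frozen=True)
class SplitPlan:
    """A fixed train/validation partition of case indices."""

    train_indices: tuple[int, ...]
    validation_indices: tuple[int, ...]
    seed: int


def _stratified_pick(y01: np.ndarray, counts: Mapping[int, int], rng: np.random.Generator) -> np.ndarray:
    picked = []
    for cls_value, k in counts.items():
        members = np.flatnonzero(y01 == cls_value)
        picked.append(rng.choice(members, size=k, replace=False))
    return np.sort(np.concatenate(picked))


def stratified_split(dataset: LabeledDataset, fraction: float, seed: int) -> SplitPlan:
    """Partition cases, giving each class round-half-up(fraction * size) to validation.

    With class sizes 69/56 and fraction 0.2 the validation partition holds
    exactly 14 and 11 cases for every seed; only the membership varies.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    y = dataset.y01
    rng = np.random.default_rng(seed)
    counts: dict[int, int] = {}
    for cls_value in (0, 1):
        size = int(np.sum(y == cls_value))
        if size < 2:
            raise ValueError(f"class {cls_value} has fewer than 2 cases")
        k = round_half_up(fraction * size)
        if k == 0 or k == size:
            raise ValueError(
                f"fraction {fraction} leaves class {cls_value} with an empty "
                "training or validation side"
            )
        counts[cls_value] = k
    val = _stratified_pick(y, counts, rng)
    train = np.setdiff1d(np.arange(dataset.n_cases), val)
    return SplitPlan(tuple(int(i) for i in train), tuple(int(i) for i in val), seed)


def stratified_subsample(y01: np.ndarray, fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Indices of a stratified fraction of cases (round half up per class, >= 1)."""
    counts = {}
    for cls_value in (0, 1):
        size = int(np.sum(y01 == cls_value))
        counts[cls_value] = max(1, min(size, round_half_up(fraction * size)))
    return _stratified_pick(y01, counts, rng)


def mc_evaluate(
    train: LabeledDataset,
    validation: LabeledDataset,
    subset: Sequence[str],
    classifier_id: str,
    config: RunConfig,
    log: Callable[[dict], None] | None = None,
) -> PerformanceEstimate:
    """Monte-Carlo CV estimate of a classifier on one feature subset.

    Hyperparameters are tuned once per subset/classifier on the full
    training partition; each of the ``n_iterations`` iterations refits the
    tuned model on a fresh stratified 80% subsample of the training
    partition and scores it on a fresh stratified 80% subsample of the
    fixed validation partition. Degenerate subsamples (a class absent in
    an 80% draw cannot arise under stratification, but predictions
    collapsing a class can) are guarded by the confusion-count check.
    """
    subset = train.check_subset(subset)
    if not subset:
        raise ValueError("cannot evaluate an empty feature subset")
    key = ",".join(sorted(subset))
    X_train = train.columns(subset)
    y_train = train.y01
    X_val = validation.columns(subset)
    y_val = validation.y01

    tune_seed = config.derived_seed("tune", key, classifier_id)
    params = tune_classifier(classifier_id, X_train, y_train, tune_seed, config)

    samples: list[float] = []
    for i in range(config.n_iterations):
        seed_i = config.derived_seed("mc", key, classifier_id, i)
        rng = np.random.default_rng(seed_i)
        ba = None
        for _attempt in range(5):  # bounded redraws keep ba_samples full length
            tr_idx = stratified_subsample(y_train, config.inner_subsample_fraction, rng)
            va_idx = stratified_subsample(y_val, config.inner_subsample_fraction, rng)
            model = build_classifier(classifier_id, params, seed_i, config)
            model.fit(X_train[tr_idx], y_train[tr_idx])
            pred = model.predict(X_val[va_idx])
            counts = ConfusionCounts.from_labels(y_val[va_idx], pred)
            try:
                ba = balanced_accuracy(counts)
                break
            except UndefinedMetricError:
                if log is not None:
                    log({"event": "degenerate_subsample", "iteration": i, "classifier": classifier_id})
                continue
        if ba is None:
            raise RuntimeError(f"iteration {i} degenerate after bounded redraws")
        samples.append(ba)
    return PerformanceEstimate.from_samples(samples, config.ci_level)


def subset_success(evaluation: SubsetEvaluation | Mapping[str, PerformanceEstimate], chance_level: float = 0.5) -> bool:
    """True iff any classifier's CI lower bound strictly exceeds chance."""
    estimates = (
        evaluation.per_classifier if isinstance(evaluation, SubsetEvaluation) else evaluation
    )
    if not estimates:
        raise ValueError("no classifier estimates present")
    return any(est.ci_low > chance_level for est in estimates.values())


@dataclass
class Evaluator:
    """Caching evaluation engine bound to one train/validation partition.

    The cache key is (sorted subset, classifier): the derived seed stream
    depends only on that pair, so a cached estimate is identical to a
    fresh recomputation.
    """

    train: LabeledDataset
    validation: LabeledDataset
    config: RunConfig
    cache: dict[tuple[tuple[str, ...], str], PerformanceEstimate] = field(default_factory=dict)
    log_records: list[dict] = field(default_factory=list)

    def evaluate(self, subset: Sequence[str], phase: str = "") -> SubsetEvaluation:
        subset = tuple(subset)
        per_classifier: dict[str, PerformanceEstimate] = {}
        for classifier_id in self.config.classifier_ids:
            cache_key = (tuple(sorted(subset)), classifier_id)
            estimate = self.cache.get(cache_key)
            if estimate is None:
                estimate = mc_evaluate(
                    self.train, self.validation, subset, classifier_id, self.config,
                    log=self.log_records.append,
                )
                self.cache[cache_key] = estimate
                self.log_records.append(
                    {
                        "event": "evaluation",
                        "phase": phase,
                        "subset": ";".join(sorted(subset)),
                        "classifier": classifier_id,
                        "median": estimate.median_ba,
                        "ci_low": estimate.ci_low,
                        "ci_high": estimate.ci_high,
                    }
                )
            per_classifier[classifier_id] = estimate
        success = subset_success(per_classifier, self.config.chance_level)
        return SubsetEvaluation(subset, per_classifier, success)
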