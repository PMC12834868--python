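"""The iterative feature selection and rejection algorithm.

Given a labelled feature table, the framework partitions the features into
a *selected* set sufficient for classification and a *rejected* set
verified to classify at chance level, under a model-agnostic success
criterion (any classifier's balanced-accuracy CI lower bound > 0.5 under
Monte-Carlo CV). The outer loop runs four phases on the current feature
set F_cur, initially all features:

* Phase 0 — run every feature-selection expert on the training partition
  restricted to F_cur; evaluate all candidate subsets (F_cur itself, each
  expert's selected set, and all unions/intersections of those); stop with
  ``not_classifiable`` if nothing succeeds on the first pass, or with
  ``all_features_necessary`` if the smallest successful subset is F_cur.
* Phase 1 — backward elimination on the smallest successful subset:
  repeatedly drop the first single feature whose removal preserves
  success, restarting after every committed removal, until 1-minimal.
* Phase 2 — rescue: every feature discarded from F_cur is evaluated alone;
  individually successful features re-enter the selected set (redundancy
  masking must not discard independently predictive features).
* Phase 3 — verification: the selected set must still succeed (hard error
  otherwise); the rejected set is attacked the same way (selectors re-run
  on it, all subset combinations evaluated). If nothing succeeds, the
  partition is final. If something succeeds but no rejected feature was
  expert-chosen in Phase 0 nor individually successful in Phase 2, the
  run ends with an interaction warning; otherwise F_cur becomes the
  rejected set and the loop repeats.

Selector-rejected sets and the complement of the union of selected sets
are evaluated for reporting only; they never enter the smallest-subset
candidate pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .config import RunConfig, validate_config
from .data import LabeledDataset
from .evaluation import Evaluator, SplitPlan, SubsetEvaluation, stratified_split
from .selectors import SelectionResult, run_selector

__all__ = [
    "SubsetEntry",
    "PhaseRecord",
    "FrameworkResult",
    "FrameworkError",
    "generate_subsets",
    "backward_eliminate",
    "rescue_individual",
    "run_framework",
    "IterativeFeatureSelector",
]

_DISPLAY = {"boruta": "Boruta", "lasso": "LASSO"}


def _display(selector_id: str) -> str:
    return _DISPLAY.get(selector_id, selector_id.title())


class FrameworkError(RuntimeError):
    """Internal-consistency failure (e.g., no subset of selected classifies)."""


@dataclass(frozen=True)
class SubsetEntry:
    """A labelled candidate subset; report-only entries are never minimised."""

    label: str
    features: tuple[str, ...]
    report_only: bool = False


@dataclass
class PhaseRecord:
    """Trace of one phase: what was evaluated and what was decided."""

    phase_id: str
    outer_iteration: int
    evaluated: list[tuple[SubsetEntry, SubsetEvaluation]] = field(default_factory=list)
    decisions: list[tuple[str, str]] = field(default_factory=list)  # (feature/subset, action)
    selections: list[SelectionResult] = field(default_factory=list)


@dataclass
class FrameworkResult:
    """Final partition with its guarantee status and full phase trace."""

    selected: tuple[str, ...]
    rejected: tuple[str, ...]
    warning: bool
    status: str  # ok | not_classifiable | all_features_necessary
    trace: list[PhaseRecord]
    split: SplitPlan
    evaluator: Evaluator

    def report(self) -> pd.DataFrame:
        from .report import build_report

        return build_report(self)


def generate_subsets(
    selections: Sequence[SelectionResult],
    universe: Sequence[str],
    include_report_only: bool = True,
) -> list[SubsetEntry]:
    """Candidate subsets from selector outputs over a feature universe.

    Candidates: the universe, each selector's selected set, and the unions
    and intersections of every combination of two or more selected sets.
    Report-only extras: each selector's rejected set and the complement of
    the union of all selected sets. Duplicates (as sets) and empty sets
    are dropped, first label wins.
    """
    universe = tuple(universe)
    entries: list[SubsetEntry] = [SubsetEntry("All_Features", universe)]
    selected_sets = [
        (_display(s.selector_id), tuple(n for n in universe if n in set(s.selected)))
        for s in selections
    ]
    for name, sel in selected_sets:
        if sel:
            entries.append(SubsetEntry(f"{name}_Selected", sel))
    nonempty = [(name, set(sel)) for name, sel in selected_sets if sel]
    for k in range(2, len(nonempty) + 1):
        for combo in combinations(nonempty, k):
            tag = "_".join(name for name, _ in combo)
            union = set().union(*(s for _, s in combo))
            inter = set.intersection(*(s for _, s in combo))
            entries.append(SubsetEntry(f"{tag}_Selected", tuple(n for n in universe if n in union)))
            if inter:
                entries.append(
                    SubsetEntry(f"{tag}_Intersection", tuple(n for n in universe if n in inter))
                )
    if include_report_only:
        for s in selections:
            rej = tuple(n for n in universe if n in set(s.rejected))
            if rej:
                entries.append(SubsetEntry(f"{_display(s.selector_id)}_Rejected", rej, report_only=True))
        if nonempty:
            tag = "_".join(name for name, _ in nonempty)
            union_all = set().union(*(s for _, s in nonempty))
            comp = tuple(n for n in universe if n not in union_all)
            if comp:
                entries.append(SubsetEntry(f"{tag}_Rejected", comp, report_only=True))

    seen: dict[frozenset, int] = {}
    unique: list[SubsetEntry] = []
    for entry in entries:
        if not entry.features:
            continue
        key = frozenset(entry.features)
        if key in seen:
            # a candidate subsumes an identical report-only set
            idx = seen[key]
            if unique[idx].report_only and not entry.report_only:
                unique[idx] = entry
            continue
        seen[key] = len(unique)
        unique.append(entry)
    return unique


def _pick_smallest(
    evaluated: list[tuple[SubsetEntry, SubsetEvaluation]]
) -> tuple[SubsetEntry, SubsetEvaluation] | None:
    """Smallest successful candidate; ties by highest best median BA, then names."""
    successes = [
        (entry, ev)
        for entry, ev in evaluated
        if ev.success and not entry.report_only
    ]
    if not successes:
        return None
    return min(
        successes,
        key=lambda pair: (
            len(pair[0].features),
            -max(est.median_ba for est in pair[1].per_classifier.values()),
            tuple(sorted(pair[0].features)),
        ),
    )


def backward_eliminate(
    start: Sequence[str],
    evaluator: Evaluator,
    order_scores: dict[str, float] | None = None,
    record: PhaseRecord | None = None,
) -> tuple[str, ...]:
    """Shrink a successful subset until no single removal preserves success.

    Features are tried in ascending importance (least important first,
    lexicographic fallback); after every committed removal the scan
    restarts. The result is successful and 1-minimal.
    """
    scores = order_scores or {}
    minimal = tuple(start)
    changed = True
    while changed and len(minimal) > 1:
        changed = False
        order = sorted(minimal, key=lambda n: (scores.get(n, 0.0), n))
        for feature in order:
            candidate = tuple(n for n in minimal if n != feature)
            ev = evaluator.evaluate(candidate, phase="phase1")
            if record is not None:
                record.evaluated.append(
                    (SubsetEntry("Backward_Elimination", candidate), ev)
                )
            if ev.success:
                minimal = candidate
                changed = True
                if record is not None:
                    record.decisions.append((feature, "removed"))
                break
    return minimal


def rescue_individual(
    candidates: Sequence[str],
    evaluator: Evaluator,
    record: PhaseRecord | None = None,
) -> tuple[str, ...]:
    """Features among ``candidates`` that classify successfully alone."""
    rescued: list[str] = []
    for feature in sorted(candidates):
        ev = evaluator.evaluate((feature,), phase="phase2")
        if record is not None:
            record.evaluated.append((SubsetEntry("Individual", (feature,)), ev))
            record.decisions.append((feature, "rescued" if ev.success else "confirmed-rejected"))
        if ev.success:
            rescued.append(feature)
    return tuple(rescued)


def _evaluate_entries(
    entries: Sequence[SubsetEntry], evaluator: Evaluator, record: PhaseRecord, phase: str
) -> list[tuple[SubsetEntry, SubsetEvaluation]]:
    out = []
    for entry in entries:
        ev = evaluator.evaluate(entry.features, phase=phase)
        record.evaluated.append((entry, ev))
        out.append((entry, ev))
    return out


def run_framework(dataset: LabeledDataset, config: RunConfig) -> FrameworkResult:
    """Execute the full phase 0-3 loop on a labelled dataset.

    The stratified validation partition is drawn once (before any feature
    selection) and reused by every phase and outer iteration. All subset
    evaluations share one cache keyed by (subset, classifier).
    """
    config = validate_config(config)
    split = stratified_split(dataset, config.validation_fraction, config.derived_seed("split"))
    train = dataset.take(split.train_indices)
    validation = dataset.take(split.validation_indices)
    evaluator = Evaluator(train, validation, config)

    all_features = dataset.feature_names
    selected: set[str] = set()
    current: tuple[str, ...] = all_features
    trace: list[PhaseRecord] = []

    def result(status: str, warning: bool = False) -> FrameworkResult:
        sel = tuple(n for n in all_features if n in selected)
        rej = tuple(n for n in all_features if n not in selected)
        return FrameworkResult(sel, rej, warning, status, trace, split, evaluator)

    for outer in range(1, len(all_features) + 2):
        # ---- Phase 0 -------------------------------------------------
        rec0 = PhaseRecord("phase0", outer)
        trace.append(rec0)
        train_cur = train.restrict(current)
        selections = [run_selector(sid, train_cur, config) for sid in config.selector_ids]
        rec0.selections = selections
        entries = generate_subsets(selections, current)
        if outer == 1:
            for label, feats in config.custom_subsets.items():
                entries.append(SubsetEntry(label, dataset.check_subset(feats), report_only=True))
        evaluated = _evaluate_entries(entries, evaluator, rec0, "phase0")
        smallest = _pick_smallest(evaluated)
        if smallest is None:
            if outer == 1:
                rec0.decisions.append(("all", "not_classifiable"))
                return result("not_classifiable")
            return result("ok")
        rec0.decisions.append((";".join(smallest[0].features), "kept"))
        if set(smallest[0].features) == set(current):
            selected.update(current)
            rec0.decisions.append((";".join(current), "all-features-necessary"))
            return result("all_features_necessary")
        phase0_chosen = set().union(*(set(s.selected) for s in selections))

        # ---- Phase 1 -------------------------------------------------
        rec1 = PhaseRecord("phase1", outer)
        trace.append(rec1)
        order_scores: dict[str, float] = {}
        for s in selections:
            if s.selector_id == "boruta":
                order_scores = dict(s.scores)
                break
        else:
            if selections:
                order_scores = dict(selections[0].scores)
        minimal = backward_eliminate(smallest[0].features, evaluator, order_scores, rec1)
        rec1.decisions.append((";".join(minimal), "kept"))

        # ---- Phase 2 -------------------------------------------------
        rec2 = PhaseRecord("phase2", outer)
        trace.append(rec2)
        rejected_cur = tuple(n for n in current if n not in set(minimal))
        rescued = rescue_individual(rejected_cur, evaluator, rec2)
        selected.update(minimal)
        selected.update(rescued)
        rejected = tuple(n for n in all_features if n not in selected)

        # ---- Phase 3 -------------------------------------------------
        rec3 = PhaseRecord("phase3", outer)
        trace.append(rec3)
        sel_tuple = tuple(n for n in all_features if n in selected)
        sel_selections = [
            run_selector(sid, train.restrict(sel_tuple), config) for sid in config.selector_ids
        ]
        rec3.selections = list(sel_selections)
        sel_entries = [
            SubsetEntry(f"Selected::{e.label}", e.features, e.report_only)
            for e in generate_subsets(sel_selections, sel_tuple)
        ]
        sel_evaluated = _evaluate_entries(sel_entries, evaluator, rec3, "phase3")
        if not any(ev.success for entry, ev in sel_evaluated if not entry.report_only):
            raise FrameworkError(
                "internal consistency failure: no subset of the selected features "
                f"{sel_tuple} achieves classification success"
            )
        if not rejected:
            rec3.decisions.append(("", "confirmed-rejected"))
            return result("ok")

        rej_selections = [
            run_selector(sid, train.restrict(rejected), config) for sid in config.selector_ids
        ]
        rec3.selections.extend(rej_selections)
        rej_entries = [
            SubsetEntry(f"Rejected::{e.label}", e.features, e.report_only)
            for e in generate_subsets(rej_selections, rejected)
        ]
        rej_evaluated = _evaluate_entries(rej_entries, evaluator, rec3, "phase3")
        rejected_succeeds = any(ev.success for entry, ev in rej_evaluated if not entry.report_only)
        if not rejected_succeeds:
            rec3.decisions.append((";".join(rejected), "confirmed-rejected"))
            return result("ok")
        if not (set(rejected) & phase0_chosen) and not (set(rejected) & set(rescued)):
            rec3.decisions.append((";".join(rejected), "interaction-warning"))
            return result("ok", warning=True)
        rec3.decisions.append((";".join(rejected), "re-entered"))
        current = rejected

    raise FrameworkError("outer loop failed to terminate")  # pragma: no cover


class IterativeFeatureSelector(SelectorMixin, BaseEstimator):
    """Scikit-learn interface to the iterative selection/rejection framework.

    ``fit(X, y)`` runs the whole phase 0-3 loop; ``get_support()`` /
    ``transform`` expose the selected set. A boolean ``warning_`` flags
    rejected features that classify only through interactions invisible
    to every selector, and ``status_`` distinguishes a normal run from
    ``not_classifiable`` and ``all_features_necessary`` terminations.

    Parameters mirror :class:`~iterfs.config.RunConfig`; see there for the
    protocol semantics. ``random_state`` is the master seed.
    """

    def __init__(
        self,
        validation_fraction: float = 0.20,
        n_iterations: int = 100,
        inner_subsample_fraction: float = 0.80,
        ci_level: float = 0.95,
        chance_level: float = 0.5,
        selector_ids: tuple[str, ...] = ("boruta", "lasso"),
        classifier_ids: tuple[str, ...] = ("random_forest", "logistic", "knn", "tree", "svm_rbf"),
        grids: dict | None = None,
        boruta_max_runs: int = 100,
        boruta_trees: int = 500,
        boruta_alpha: float = 0.01,
        boruta_importance: str = "permutation",
        boruta_n_repeats: int = 5,
        lasso_cv_folds: int = 5,
        rf_trees: int = 500,
        random_state: int | None = None,
    ):
        self.validation_fraction = validation_fraction
        self.n_iterations = n_iterations
        self.inner_subsample_fraction = inner_subsample_fraction
        self.ci_level = ci_level
        self.chance_level = chance_level
        self.selector_ids = selector_ids
        self.classifier_ids = classifier_ids
        self.grids = grids
        self.boruta_max_runs = boruta_max_runs
        self.boruta_trees = boruta_trees
        self.boruta_alpha = boruta_alpha
        self.boruta_importance = boruta_importance
        self.boruta_n_repeats = boruta_n_repeats
        self.lasso_cv_folds = lasso_cv_folds
        self.rf_trees = rf_trees
        self.random_state = random_state

    def _config(self) -> RunConfig:
        return validate_config(
            validation_fraction=self.validation_fraction,
            n_iterations=self.n_iterations,
            inner_subsample_fraction=self.inner_subsample_fraction,
            ci_level=self.ci_level,
            chance_level=self.chance_level,
            selector_ids=tuple(self.selector_ids),
            classifier_ids=tuple(self.classifier_ids),
            grids=dict(self.grids or {}),
            boruta_max_runs=self.boruta_max_runs,
            boruta_trees=self.boruta_trees,
            boruta_alpha=self.boruta_alpha,
            boruta_importance=self.boruta_importance,
            boruta_n_repeats=self.boruta_n_repeats,
            lasso_cv_folds=self.lasso_cv_folds,
            rf_trees=self.rf_trees,
            master_seed=0 if self.random_state is None else int(self.random_state),
        )

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            names = tuple(str(c) for c in X.columns)
        else:
            names = None
        X, y = validate_data(self, X, y)
        if names is None:
            names = tuple(f"x{j}" for j in range(X.shape[1]))
        labels = np.asarray(y).astype(str)
        levels = sorted(set(labels))
        if len(levels) != 2:
            raise ValueError(f"need a binary target, found levels {levels}")
        dataset = LabeledDataset(X, names, labels, (levels[0], levels[1]))
        result = run_framework(dataset, self._config())
        self.result_ = result
        self.selected_ = result.selected
        self.rejected_ = result.rejected
        self.status_ = result.status
        self.warning_ = result.warning
        self.trace_ = result.trace
        self.support_ = np.array([n in set(result.selected) for n in names])
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.support_

    def report(self) -> pd.DataFrame:
        check_is_fitted(self)
        return self.result_.report()
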