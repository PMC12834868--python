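"""Run configuration: the contract shared by every stage of the pipeline.

``RunConfig`` collects the resampling protocol (validation fraction,
Monte-Carlo iterations, inner subsample fraction, CI level), the chance
level of the success criterion, the selector and classifier rosters, and
the tuning knobs of both selectors. A configuration can come from keyword
arguments or a YAML file; unknown keys are an error in both cases.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import yaml

from ._seeds import derive_seed

__all__ = ["RunConfig", "ConfigError", "validate_config", "load_config"]

DEFAULT_SELECTORS = ("boruta", "lasso")
DEFAULT_CLASSIFIERS = ("random_forest", "logistic", "knn", "tree", "svm_rbf")


class ConfigError(ValueError):
    """Raised when a configuration field is missing, unknown or invalid."""


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for a framework run.

    Parameters
    ----------
    validation_fraction : float
        Fraction of cases set aside once, before any selection, as the
        fixed validation partition (default 0.20).
    n_iterations : int
        Monte-Carlo cross-validation iterations per subset/classifier
        (default 100).
    inner_subsample_fraction : float
        Fraction of the training and validation partitions drawn afresh
        in every Monte-Carlo iteration (default 0.80).
    ci_level : float
        Level of the non-parametric confidence interval on balanced
        accuracy (default 0.95).
    chance_level : float
        Guessing-level balanced accuracy; classification succeeds only if
        some classifier's CI lower bound strictly exceeds it (default 0.5).
    master_seed : int
        Root of every derived random stream.
    selector_ids, classifier_ids : sequences of str
        Feature-selection experts and classifier families to use.
    grids : mapping classifier_id -> {hyperparameter: list of values}
        Overrides for the default tuning grids.
    """

    validation_fraction: float = 0.20
    n_iterations: int = 100
    inner_subsample_fraction: float = 0.80
    ci_level: float = 0.95
    chance_level: float = 0.5
    master_seed: int = 0
    selector_ids: tuple[str, ...] = DEFAULT_SELECTORS
    classifier_ids: tuple[str, ...] = DEFAULT_CLASSIFIERS
    grids: dict[str, dict[str, list]] = field(default_factory=dict)
    # shadow-feature random-forest selector
    boruta_max_runs: int = 100
    boruta_trees: int = 500
    boruta_alpha: float = 0.01
    boruta_importance: str = "permutation"  # or "impurity"
    boruta_n_repeats: int = 5
    # sparse CV-logistic selector
    lasso_cv_folds: int = 5
    lasso_path_length: int = 100
    # classifier zoo
    rf_trees: int = 500
    # report-only user subsets: {label: [feature, ...]}
    custom_subsets: dict[str, list[str]] = field(default_factory=dict)

    def derived_seed(self, *tokens: object) -> int:
        """Seed for a named consumer, a pure function of the master seed."""
        return derive_seed(self.master_seed, *tokens)

    def replace(self, **kwargs: Any) -> "RunConfig":
        return validate_config(dataclasses.replace(self, **kwargs))


def _check(condition: bool, message: str) -> None:
    if not condition:
        raise ConfigError(message)


def validate_config(config: RunConfig | None = None, /, **kwargs: Any) -> RunConfig:
    """Normalise and validate a configuration; errors name the field.

    Accepts either an existing ``RunConfig`` or keyword arguments (unknown
    keywords are rejected). Returns a validated, frozen configuration.
    """
    if config is None:
        known = {f.name for f in dataclasses.fields(RunConfig)}
        unknown = set(kwargs) - known
        _check(not unknown, f"unknown configuration keys: {sorted(unknown)}")
        config = RunConfig(**kwargs)
    _check(
        0 < config.validation_fraction < 1,
        f"validation_fraction must lie in (0, 1), got {config.validation_fraction}",
    )
    _check(
        0 < config.inner_subsample_fraction < 1,
        "inner_subsample_fraction must lie in (0, 1), "
        f"got {config.inner_subsample_fraction}",
    )
    _check(0 < config.ci_level < 1, f"ci_level must lie in (0, 1), got {config.ci_level}")
    _check(config.n_iterations >= 2, f"n_iterations must be >= 2, got {config.n_iterations}")
    _check(0 <= config.chance_level < 1, f"chance_level must lie in [0, 1), got {config.chance_level}")
    _check(config.boruta_max_runs >= 1, "boruta_max_runs must be >= 1")
    _check(0 < config.boruta_alpha < 1, "boruta_alpha must lie in (0, 1)")
    _check(config.boruta_importance in ("permutation", "impurity"),
           f"boruta_importance must be 'permutation' or 'impurity', got {config.boruta_importance!r}")
    _check(config.lasso_cv_folds >= 2, "lasso_cv_folds must be >= 2")
    _check(len(config.selector_ids) >= 1, "selector_ids must name at least one selector")
    _check(len(config.classifier_ids) >= 1, "classifier_ids must name at least one classifier")
    object.__setattr__(config, "selector_ids", tuple(config.selector_ids))
    object.__setattr__(config, "classifier_ids", tuple(config.classifier_ids))
    return config


def load_config(path: str, **overrides: Any) -> RunConfig:
    """Read a YAML configuration file; keyword overrides win over the file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, Mapping):
        raise ConfigError(f"configuration file {path} must contain a mapping")
    merged: dict[str, Any] = dict(raw)
    merged.update(overrides)
    for key in ("selector_ids", "classifier_ids"):
        if key in merged and isinstance(merged[key], Sequence) and not isinstance(merged[key], (str, tuple)):
            merged[key] = tuple(merged[key])
    return validate_config(**merged)
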