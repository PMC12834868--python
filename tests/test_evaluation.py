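"""Balanced accuracy, confidence intervals, splitting and the MC-CV engine."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iterfs import (
    ConfusionCounts,
    Evaluator,
    PerformanceEstimate,
    balanced_accuracy,
    mc_evaluate,
    percentile_ci,
    stratified_split,
    subset_success,
    validate_config,
)
from iterfs.evaluation import UndefinedMetricError, round_half_up


class TestBalancedAccuracy:
    def test_forced_values(self):
        assert balanced_accuracy(ConfusionCounts(tp=5, fp=0, tn=5, fn=0)) == 1.0
        # constant single-class prediction on a mixed sample sits at chance
        assert balanced_accuracy(ConfusionCounts(tp=7, fp=3, tn=0, fn=0)) == 0.5
        assert balanced_accuracy(ConfusionCounts(tp=3, fn=2, tn=4, fp=1)) == pytest.approx(0.7)

    def test_absent_class_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            balanced_accuracy(ConfusionCounts(tp=3, fp=0, tn=0, fn=2))

    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
    @settings(max_examples=200, deadline=None)
    def test_mean_of_class_recalls(self, tp, fn, tn, fp):
        """Equals the mean of per-class recalls computed from raw labels."""
        if tp + fn == 0 or tn + fp == 0:
            return
        y_true = np.array([1] * (tp + fn) + [0] * (tn + fp))
        y_pred = np.array([1] * tp + [0] * fn + [0] * tn + [1] * fp)
        counts = ConfusionCounts.from_labels(y_true, y_pred)
        recalls = [np.mean(y_pred[y_true == c] == c) for c in (0, 1)]
        assert balanced_accuracy(counts) == pytest.approx(np.mean(recalls))


class TestPercentileCI:
    def test_degenerate_and_bounds(self):
        assert percentile_ci([0.75] * 10, 0.95) == (0.75, 0.75)
        low, high = percentile_ci([0.0, 1.0], 0.95)
        assert 0.0 <= low <= high <= 1.0
        with pytest.raises(ValueError):
            percentile_ci([], 0.95)
        with pytest.raises(ValueError):
            percentile_ci([1.0, 2.0], 1.5)

    def test_matches_independent_interpolation_oracle(self):
        """1..100 at level 0.95 against a hand-coded interpolated quantile."""

        def quantile_oracle(sorted_vals, q):
            # linear interpolation between order statistics at h = (n-1) q
            h = (len(sorted_vals) - 1) * q
            lo = int(np.floor(h))
            hi = min(lo + 1, len(sorted_vals) - 1)
            return sorted_vals[lo] + (h - lo) * (sorted_vals[hi] - sorted_vals[lo])

        samples = list(range(1, 101))
        low, high = percentile_ci(samples, 0.95)
        assert low == pytest.approx(quantile_oracle(samples, 0.025))
        assert high == pytest.approx(quantile_oracle(samples, 0.975))

    def test_estimate_orders_min_ci_median_max(self):
        rng = np.random.default_rng(0)
        samples = rng.random(40)
        est = PerformanceEstimate.from_samples(samples, 0.95)
        assert min(samples) <= est.ci_low <= est.median_ba <= est.ci_high <= max(samples)


class TestStratifiedSplit:
    @pytest.mark.parametrize("seed", range(12))
    def test_clinical_class_sizes_give_exact_counts(self, seed):
        """69/56 cases at 20% always put 14/11 cases into validation."""
        rng = np.random.default_rng(1)
        from iterfs import LabeledDataset

        labels = np.array(["m"] * 69 + ["f"] * 56)
        ds = LabeledDataset(rng.standard_normal((125, 3)), ("a", "b", "c"), labels, ("f", "m"))
        plan = stratified_split(ds, 0.2, seed)
        val_labels = ds.labels[list(plan.validation_indices)]
        assert int(np.sum(val_labels == "m")) == 14
        assert int(np.sum(val_labels == "f")) == 11
        assert sorted(plan.train_indices + plan.validation_indices) == list(range(125))

    def test_exact_fractions_and_seed_variation(self):
        from iterfs import LabeledDataset

        rng = np.random.default_rng(2)
        labels = np.array(["x"] * 10 + ["y"] * 10)
        ds = LabeledDataset(rng.standard_normal((20, 2)), ("a", "b"), labels, ("x", "y"))
        plans = [stratified_split(ds, 0.2, seed) for seed in range(30)]
        for plan in plans:
            val = ds.labels[list(plan.validation_indices)]
            assert int(np.sum(val == "x")) == 2 and int(np.sum(val == "y")) == 2
        memberships = {plan.validation_indices for plan in plans}
        assert len(memberships) > 1  # same counts, different members

    def test_empty_side_rejected(self):
        from iterfs import LabeledDataset

        rng = np.random.default_rng(3)
        labels = np.array(["x"] * 2 + ["y"] * 6)
        ds = LabeledDataset(rng.standard_normal((8, 2)), ("a", "b"), labels, ("x", "y"))
        with pytest.raises(ValueError):
            stratified_split(ds, 0.05, 0)  # class x would get 0 validation cases

    def test_round_half_up(self):
        assert round_half_up(13.8) == 14
        assert round_half_up(11.2) == 11
        assert round_half_up(2.5) == 3


class TestMCEvaluate:
    def test_label_leak_reaches_perfect_median(self, leak_dataset):
        cfg = validate_config(master_seed=1, n_iterations=10, classifier_ids=("tree",))
        plan = stratified_split(leak_dataset, 0.2, 0)
        train = leak_dataset.take(plan.train_indices)
        val = leak_dataset.take(plan.validation_indices)
        est = mc_evaluate(train, val, ("leak",), "tree", cfg)
        assert est.median_ba == 1.0
        assert len(est.ba_samples) == 10

    def test_reproducible_given_master_seed(self, planted_signal, fast_config):
        plan = stratified_split(planted_signal, 0.2, fast_config.derived_seed("split"))
        train = planted_signal.take(plan.train_indices)
        val = planted_signal.take(plan.validation_indices)
        cfg = fast_config.replace(n_iterations=5)
        a = mc_evaluate(train, val, ("f00", "f01"), "knn", cfg)
        b = mc_evaluate(train, val, ("f00", "f01"), "knn", cfg)
        assert a == b

    def test_pure_noise_feature_straddles_chance(self):
        """A label-independent feature must not pass the success criterion."""
        from iterfs import PlantedSpec, generate_planted

        ds = generate_planted(PlantedSpec(n=200, p=2, informative=(), seed=9))
        cfg = validate_config(master_seed=4, n_iterations=30, classifier_ids=("logistic",))
        plan = stratified_split(ds, 0.2, cfg.derived_seed("split"))
        est = mc_evaluate(
            ds.take(plan.train_indices), ds.take(plan.validation_indices), ("f00",), "logistic", cfg
        )
        assert est.ci_low <= 0.5


class TestSuccessCriterion:
    def _estimate(self, ci_low):
        samples = (ci_low, ci_low, 1.0, 1.0)
        return PerformanceEstimate(samples, float(np.median(samples)), ci_low, 1.0)

    def test_any_classifier_above_chance_suffices(self):
        ests = {"a": self._estimate(0.45), "b": self._estimate(0.62)}
        assert subset_success(ests, 0.5) is True

    def test_strict_inequality_at_the_boundary(self):
        ests = {"a": self._estimate(0.5), "b": self._estimate(0.5)}
        assert subset_success(ests, 0.5) is False

    def test_no_estimates_is_an_error(self):
        with pytest.raises(ValueError):
            subset_success({}, 0.5)


def test_evaluator_cache_is_coherent(planted_signal, fast_config):
    """Cached and freshly computed estimates are identical objects-by-value."""
    cfg = fast_config.replace(n_iterations=5)
    plan = stratified_split(planted_signal, 0.2, cfg.derived_seed("split"))
    train = planted_signal.take(plan.train_indices)
    val = planted_signal.take(plan.validation_indices)
    evaluator = Evaluator(train, val, cfg)
    first = evaluator.evaluate(("f00", "f02"))
    cached = evaluator.evaluate(("f02", "f00"))  # order-insensitive cache key
    fresh = mc_evaluate(train, val, ("f00", "f02"), "knn", cfg)
    assert cached.per_classifier["knn"] == first.per_classifier["knn"] == fresh
    n_eval_logs = sum(1 for r in evaluator.log_records if r["event"] == "evaluation")
    assert n_eval_logs == len(cfg.classifier_ids)  # second call hit the cache
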