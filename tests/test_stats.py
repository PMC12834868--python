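"""Classical battery: effect sizes, correlation, VIF, scan, penalised fits."""

import numpy as np
import pytest

from iterfs import (
    LabeledDataset,
    PlantedSpec,
    cohens_d_with_ci,
    correlation_structure,
    effect_size_table,
    generate_planted,
    penalised_logistic_select,
    subset_regression_scan,
    vif_report,
)
from iterfs.simulate import duplicate_with_noise


class TestCohensD:
    def test_identical_groups_give_zero(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = cohens_d_with_ci(x, x.copy(), n_boot=50, seed=0)
        assert res.d == 0.0

    def test_analytically_forced_value(self):
        res = cohens_d_with_ci(np.array([0.0, 1.0]), np.array([1.0, 2.0]), n_boot=50, seed=0)
        assert res.d == pytest.approx(-1 / np.sqrt(0.5))

    def test_antisymmetric_under_group_swap(self):
        rng = np.random.default_rng(1)
        x, y = rng.standard_normal(30) + 0.6, rng.standard_normal(25)
        a = cohens_d_with_ci(x, y, n_boot=50, seed=2)
        b = cohens_d_with_ci(y, x, n_boot=50, seed=2)
        assert a.d == pytest.approx(-b.d)
        assert a.ci_low <= a.d <= a.ci_high

    def test_zero_pooled_variance_is_an_error(self):
        with pytest.raises(ValueError, match="pooled variance"):
            cohens_d_with_ci(np.ones(5), np.ones(6), n_boot=10, seed=0)

    def test_bootstrap_ci_brackets_a_known_shift(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(60) + 0.8
        y = rng.standard_normal(60)
        res = cohens_d_with_ci(x, y, n_boot=500, seed=4)
        assert res.ci_low < res.d < res.ci_high
        assert res.p_value < 0.01  # d = 0.8 at n = 60/60 is unambiguous


def test_effect_size_table_covers_all_features(planted_signal):
    table = effect_size_table(planted_signal, n_boot=100, seed=0)
    assert list(table["feature"]) == list(planted_signal.feature_names)
    assert table.loc[table["feature"] == "f00", "d"].abs().iloc[0] > 1.0


class TestCorrelationStructure:
    def test_diagonal_and_noisy_duplicate(self):
        rng = np.random.default_rng(5)
        n = 125
        base = rng.standard_normal(n)
        base = (base - base.mean()) / base.std()
        twin = duplicate_with_noise(base, 0.2, seed=6)
        X = np.column_stack([base, twin, rng.standard_normal((n, 2))])
        labels = np.array(["a", "b"] * (n // 2) + ["a"])
        ds = LabeledDataset(X, ("base", "twin", "u1", "u2"), labels, ("a", "b"))
        corr = correlation_structure(ds)
        assert np.allclose(np.diag(corr.to_numpy()), 1.0)
        assert corr.loc["base", "twin"] > 0.95
        # Ward ordering puts the correlated pair next to each other
        order = list(corr.columns)
        assert abs(order.index("base") - order.index("twin")) == 1


class TestVIF:
    def test_orthogonal_design_gives_unit_vifs(self):
        n = 16
        base = np.array([[1, 1], [1, -1], [-1, 1], [-1, -1]], dtype=float)
        X = np.tile(base, (4, 1))
        labels = np.array(["a", "b"] * 8)
        ds = LabeledDataset(X, ("c1", "c2"), labels, ("a", "b"))
        rep = vif_report(ds)
        assert rep.vif == {"c1": pytest.approx(1.0), "c2": pytest.approx(1.0)}
        assert rep.aliased == () and not rep.degenerate

    def test_exact_duplicate_pair_is_aliased(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((40, 3))
        X[:, 1] = X[:, 0]
        ds = LabeledDataset(X, ("a", "b", "c"), np.array(["x", "y"] * 20), ("x", "y"))
        rep = vif_report(ds)
        assert set(rep.aliased) == {"a", "b"}
        assert "c" in rep.vif and "a" not in rep.vif

    def test_noisy_duplicate_pair_flagged_above_ten(self):
        rng = np.random.default_rng(8)
        n = 125
        base = rng.standard_normal(n)
        base = (base - base.mean()) / base.std()
        twin = duplicate_with_noise(base, 0.2, seed=9)
        X = np.column_stack([base, twin, rng.standard_normal((n, 2))])
        ds = LabeledDataset(X, ("base", "twin", "u1", "u2"), np.array(["a", "b"] * 62 + ["a"]), ("a", "b"))
        rep = vif_report(ds)
        # r ~ 0.98 implies VIF ~ 1/(1 - r^2) ~ 25
        assert rep.vif["base"] > 10 and rep.vif["twin"] > 10
        assert set(rep.flagged) >= {"base", "twin"}

    def test_matches_statsmodels_oracle(self):
        from statsmodels.stats.outliers_influence import variance_inflation_factor
        import statsmodels.api as sm

        rng = np.random.default_rng(10)
        X = rng.standard_normal((60, 5)) @ rng.uniform(0.5, 1.5, (5, 5))
        ds = LabeledDataset(X, tuple("abcde"), np.array(["x", "y"] * 30), ("x", "y"))
        rep = vif_report(ds)
        design = sm.add_constant(X)
        for j, name in enumerate("abcde"):
            oracle = variance_inflation_factor(design, j + 1)
            assert rep.vif[name] == pytest.approx(oracle, abs=1e-8)

    def test_degenerate_when_cases_do_not_exceed_features(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((6, 8))
        ds = LabeledDataset(X, tuple(f"f{i}" for i in range(8)), np.array(["a", "b"] * 3), ("a", "b"))
        assert vif_report(ds).degenerate


class TestRegressionScan:
    @pytest.fixture
    def scan_dataset(self):
        rng = np.random.default_rng(12)
        n = 200
        y01 = np.repeat([0, 1], n // 2)
        sig = y01 * 1.6 + rng.standard_normal(n)
        dup = sig.copy()  # exact alias of the signal feature
        noise = rng.standard_normal(n)
        X = np.column_stack([sig, dup, noise])
        return LabeledDataset(
            X, ("sig", "dup", "noise"), np.where(y01 == 1, "b", "a"), ("a", "b")
        )

    def test_removal_rows_and_statuses(self, scan_dataset):
        scan = subset_regression_scan(scan_dataset, ("dup",), reference_significant=("sig",))
        matrix = scan.matrix
        assert list(matrix.index) == ["-dup", "full_model"]
        assert matrix.loc["-dup", "dup"] == "removed"
        # with the alias removed, the model is clean and agrees with the reference
        assert matrix.loc["-dup", "sig"] == "ok"
        assert matrix.loc["-dup", "noise"] == "ok"
        # in the full model the exact alias makes one of the pair undefined
        full = matrix.loc["full_model"]
        assert (full == "aliased_na").sum() >= 1
        long = scan.to_long()
        assert set(long.columns) == {"model", "feature", "status"}
        assert len(long) == matrix.size

    def test_clean_design_all_ok(self):
        rng = np.random.default_rng(13)
        n = 300
        y01 = np.repeat([0, 1], n // 2)
        X = np.column_stack([y01 * 1.5 + rng.standard_normal(n), rng.standard_normal((n, 2))])
        ds = LabeledDataset(X, ("sig", "n1", "n2"), np.where(y01 == 1, "b", "a"), ("a", "b"))
        scan = subset_regression_scan(ds, ("n1",), reference_significant=("sig",))
        assert (scan.matrix.loc["full_model"] == "ok").all()


class TestPenalisedSelection:
    def test_dominant_signal_selected_by_all_penalties(self, planted_signal):
        for penalty in ("ridge", "lasso", "elastic"):
            sel = penalised_logistic_select(planted_signal, penalty, seed=1, n_lambdas=40)
            assert sel.selected["f00"], penalty
            assert sel.coef["f00"] > 0

    def test_ridge_keeps_both_duplicates_lasso_drops_one(self):
        rng = np.random.default_rng(14)
        n = 200
        y01 = np.repeat([0, 1], n // 2)
        sig = y01 * 1.5 + rng.standard_normal(n)
        twin = duplicate_with_noise(sig, 0.2, seed=15)
        X = np.column_stack([sig, twin, rng.standard_normal((n, 3))])
        ds = LabeledDataset(
            X, ("sig", "twin", "n1", "n2", "n3"), np.where(y01 == 1, "b", "a"), ("a", "b")
        )
        ridge = penalised_logistic_select(ds, "ridge", seed=2, n_lambdas=40)
        # ridge spreads weight over the correlated pair
        assert ridge.selected["sig"] and ridge.selected["twin"]
        ratio = abs(ridge.coef["sig"]) / abs(ridge.coef["twin"])
        assert 0.3 < ratio < 3.0

    def test_lasso_rule_agrees_with_the_selector_module(self, planted_signal):
        """alpha = 1 penalised selection equals the sparse-logistic expert."""
        from iterfs.selectors import SparseLogisticSelector

        seed = 3
        sel = penalised_logistic_select(planted_signal, "lasso", folds=5, seed=seed)
        est = SparseLogisticSelector(cv=5, random_state=seed).fit(
            planted_signal.features, planted_signal.y01
        )
        mine = {n for n, s in sel.selected.items() if s}
        theirs = {n for n, s in zip(planted_signal.feature_names, est.support_) if s}
        assert mine == theirs

    def test_invalid_penalty_rejected(self, planted_signal):
        with pytest.raises(ValueError):
            penalised_logistic_select(planted_signal, "l0")
        with pytest.raises(ValueError):
            penalised_logistic_select(planted_signal, "lasso", folds=2)
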