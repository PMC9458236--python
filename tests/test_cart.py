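"""Prior-weighted CART: recovery, oracle equivalence, validity checks."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from sklearn.tree import DecisionTreeClassifier

from redplif.cart import (
    PriorDecisionTreeClassifier,
    descriptor_cross_correlation,
    extract_xy,
    grid_search_priors,
    overfit_check,
    validate_model,
    y_scramble,
)
from redplif.screening_eval import confusion, metrics
from redplif.synthetic import SyntheticTableSpec, make_table


def train_ba(clf, X, y):
    return metrics(confusion(y, clf.predict(np.asarray(X, float)))).BA


@pytest.fixture
def planted_table():
    spec = SyntheticTableSpec(n_active=60, n_decoy=600, rule=[("V29", 0.5, ">=")],
                              bit_noise=0.0, n_bits=50, seed=1)
    return make_table(spec)


@pytest.fixture
def noisy_imbalanced_table():
    # ~1.7% actives with an overlapping single-descriptor signal
    spec = SyntheticTableSpec(n_active=50, n_decoy=2900, rule=[("V8", 0.5, ">=")],
                              bit_noise=0.2, background_rate=0.4, n_bits=30, seed=1)
    return make_table(spec)


class TestFit:
    def test_recovers_planted_partition(self, planted_table):
        X, y = extract_xy(planted_table)
        clf = PriorDecisionTreeClassifier(priors=(0.5, 0.5), cp=0.001,
                                          min_split=5, min_leaf=2).fit(X, y)
        assert train_ba(clf, X, y) == 1.0
        assert clf.split_variable_names() == ["V29"]

    def test_single_class_errors(self):
        X = np.random.default_rng(0).random((20, 3))
        with pytest.raises(ValueError):
            PriorDecisionTreeClassifier().fit(X, np.ones(20, int))

    def test_invalid_priors_rejected(self, planted_table):
        X, y = extract_xy(planted_table)
        with pytest.raises(ValueError):
            PriorDecisionTreeClassifier(priors=(1.0, 0.0)).fit(X, y)

    @pytest.mark.parametrize("seed", range(5))
    def test_frequency_priors_equal_plain_cart(self, seed):
        """At empirical-frequency priors the estimator is unweighted Gini
        CART: root split identical to the reference implementation, training
        predictions in near-total agreement (deeper ties may break apart)."""
        rng = np.random.default_rng(seed)
        n, p = 300, 8
        X = rng.binomial(30, 0.3, size=(n, p)) / 30
        y = ((X[:, 3] > 0.35) & (X[:, 5] < 0.4)).astype(int)
        y = np.where(rng.random(n) < 0.1, 1 - y, y)
        mine = PriorDecisionTreeClassifier(priors=None, min_split=20,
                                           min_leaf=7, cp=0.0).fit(X, y)
        sk = DecisionTreeClassifier(criterion="gini", min_samples_split=20,
                                    min_samples_leaf=7, random_state=0).fit(X, y)
        assert mine.tree_.split_variable == sk.tree_.feature[0]
        assert mine.tree_.threshold == pytest.approx(sk.tree_.threshold[0], abs=1e-6)
        agreement = (mine.predict(X) == sk.predict(X)).mean()
        assert agreement >= 0.95

    def test_matches_rpart_with_priors(self, tmp_path):
        """Cross-check against the reference R implementation with matched
        control parameters and priors 0.9:0.1."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not available for the reference cross-check")
        tab = make_table(SyntheticTableSpec(
            n_active=50, n_decoy=1000, rule=[("V5", 0.5, ">="), ("V12", 0.4, "<")],
            bit_noise=0.1, n_bits=20, seed=7))
        csv = tmp_path / "tab.csv"
        tab.drop(columns=["name", "dg"]).to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(f"""
            library(rpart)
            d <- read.csv('{csv}')
            fit <- rpart(y ~ ., data=d, method='class', parms=list(prior=c(0.9,0.1)),
                         control=rpart.control(minsplit=20, minbucket=7, cp=0.01,
                                               maxsurrogate=0, usesurrogate=0))
            pred <- as.integer(predict(fit, type='class')) - 1L
            write.csv(data.frame(pred=pred), '{tmp_path / "pred.csv"}', row.names=FALSE)
        """)
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        rpred = pd.read_csv(tmp_path / "pred.csv")["pred"].to_numpy()
        X, y = extract_xy(tab)
        clf = PriorDecisionTreeClassifier(priors=(0.9, 0.1)).fit(X, y)
        agreement = (clf.predict(np.asarray(X, float)) == rpred).mean()
        assert agreement >= 0.98

    def test_upweighting_actives_raises_sensitivity(self, noisy_imbalanced_table):
        X, y = extract_xy(noisy_imbalanced_table)
        prop = PriorDecisionTreeClassifier(priors=None).fit(X, y)
        weighted = PriorDecisionTreeClassifier(priors=(0.9, 0.1)).fit(X, y)
        sens = lambda c: metrics(confusion(y, c.predict(np.asarray(X, float)))).sensitivity
        assert sens(weighted) > sens(prop)


class TestPredict:
    def test_sklearn_protocol(self, planted_table):
        from sklearn.base import clone
        X, y = extract_xy(planted_table)
        clf = PriorDecisionTreeClassifier(priors=(0.9, 0.1))
        clone(clf)  # get_params/set_params round trip
        clf.fit(X, y)
        assert list(clf.classes_) == [0, 1]
        proba = clf.predict_proba(np.asarray(X, float)[:5])
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)

    def test_all_zero_row_is_inactive(self, planted_table):
        X, y = extract_xy(planted_table)
        clf = PriorDecisionTreeClassifier(priors=(0.5, 0.5), cp=0.001,
                                          min_split=5, min_leaf=2).fit(X, y)
        assert clf.predict(np.zeros((1, X.shape[1])))[0] == 0

    def test_wrong_feature_count_errors(self, planted_table):
        X, y = extract_xy(planted_table)
        clf = PriorDecisionTreeClassifier().fit(X, y)
        with pytest.raises(ValueError):
            clf.predict(np.zeros((1, 3)))

    def test_agrees_with_region_enumeration_on_two_variable_tree(self):
        tab = make_table(SyntheticTableSpec(
            n_active=80, n_decoy=400, rule=[("V3", 0.5, ">="), ("V7", 0.4, "<")],
            bit_noise=0.0, n_bits=10, seed=3))
        X, y = extract_xy(tab)
        clf = PriorDecisionTreeClassifier(priors=(0.5, 0.5), cp=0.001,
                                          min_split=5, min_leaf=2).fit(X, y)

        def enumerate_regions(x):
            node = clf.tree_
            while not node.is_leaf:
                node = node.left if x[node.split_variable] < node.threshold else node.right
            return node.node_class

        Xv = np.asarray(X, float)
        brute = np.array([enumerate_regions(x) for x in Xv])
        assert np.array_equal(clf.predict(Xv), brute)
        assert np.array_equal(brute, y)  # noise-free planted rule is recovered


class TestGridSearch:
    def test_selects_max_ba_above_floor(self, noisy_imbalanced_table):
        grid = [(1 - a, a) for a in (0.05, 0.1, 0.3, 0.5)]
        res = grid_search_priors(noisy_imbalanced_table, grid, f1_floor=0.1)
        trace = res.trace
        ok = trace[trace["F1"] > 0.1]
        assert res.metrics.BA == pytest.approx(ok["BA"].max())
        assert len(trace) == len(grid)

    def test_grid_of_one(self, noisy_imbalanced_table):
        res = grid_search_priors(noisy_imbalanced_table, [(0.9, 0.1)])
        assert res.best_priors == (0.9, 0.1)

    def test_unreachable_floor_errors_with_trace(self, noisy_imbalanced_table):
        with pytest.raises(ValueError) as exc:
            grid_search_priors(noisy_imbalanced_table, [(0.9, 0.1)], f1_floor=1.1)
        assert hasattr(exc.value, "trace")


class TestScramble:
    def test_deterministic_given_seed(self, noisy_imbalanced_table):
        a = y_scramble(noisy_imbalanced_table, n_iterations=2, seed=5)
        b = y_scramble(noisy_imbalanced_table, n_iterations=2, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_signal_beats_scrambled_distribution(self, noisy_imbalanced_table):
        X, y = extract_xy(noisy_imbalanced_table)
        clf = PriorDecisionTreeClassifier(priors=(0.9, 0.1)).fit(X, y)
        real = train_ba(clf, X, y)
        scrambled = y_scramble(noisy_imbalanced_table, n_iterations=10, seed=0,
                               priors=(0.9, 0.1))
        assert real > np.quantile(scrambled, 0.95)


class TestCrossCorrelation:
    def test_exact_copy_flagged(self):
        tab = pd.DataFrame({"y": [0, 1] * 10, "V1": np.arange(20.0)})
        tab["V2"] = tab["V1"]
        _, max_r, flag = descriptor_cross_correlation(tab, ["V1", "V2"])
        assert max_r == pytest.approx(1.0) and flag

    def test_anticorrelation_flagged_by_magnitude(self):
        tab = pd.DataFrame({"V1": np.arange(20.0)})
        tab["V2"] = -tab["V1"]
        _, max_r, flag = descriptor_cross_correlation(tab, ["V1", "V2"])
        assert max_r == pytest.approx(1.0) and flag

    def test_independent_columns_uncorrelated(self, rng):
        tab = pd.DataFrame(rng.random((1000, 4)), columns=["V1", "V2", "V3", "V4"])
        _, max_r, flag = descriptor_cross_correlation(tab, ["V1", "V2", "V3", "V4"])
        assert max_r < 0.15 and not flag

    def test_zero_variance_warns_and_reports_zero(self):
        tab = pd.DataFrame({"V1": np.ones(10), "V2": np.arange(10.0)})
        with pytest.warns(UserWarning, match="zero-variance"):
            _, max_r, _ = descriptor_cross_correlation(tab, ["V1", "V2"])
        assert max_r == 0.0


class TestOverfitCheck:
    def test_planted_signal_not_flagged(self, noisy_imbalanced_table):
        train, cv, flag = overfit_check(noisy_imbalanced_table, k_folds=5, seed=0,
                                        priors=(0.9, 0.1))
        assert not flag and cv > 0.7

    def test_pure_noise_deep_tree_flagged(self):
        tab = make_table(SyntheticTableSpec(n_active=40, n_decoy=160, rule=[],
                                            n_bits=40, seed=9))
        train, cv, flag = overfit_check(tab, k_folds=4, seed=0,
                                        cp=0.0, min_split=2, min_leaf=1)
        assert flag and train - cv > 0.1

    def test_deterministic_given_seed(self, noisy_imbalanced_table):
        r1 = overfit_check(noisy_imbalanced_table, k_folds=3, seed=2, priors=(0.9, 0.1))
        r2 = overfit_check(noisy_imbalanced_table, k_folds=3, seed=2, priors=(0.9, 0.1))
        assert r1 == r2

    def test_too_many_folds_errors(self):
        tab = make_table(SyntheticTableSpec(n_active=3, n_decoy=40, rule=[],
                                            n_bits=5, seed=0))
        with pytest.raises(ValueError, match="folds"):
            overfit_check(tab, k_folds=5)


class TestValidateModel:
    def test_clean_model_raises_no_flags(self, noisy_imbalanced_table):
        X, y = extract_xy(noisy_imbalanced_table)
        clf = PriorDecisionTreeClassifier(priors=(0.9, 0.1)).fit(X, y)
        report = validate_model(noisy_imbalanced_table, clf, n_scramble=8, seed=0)
        assert not report.overfitting
        assert not report.chance_correlated
        assert not report.cross_correlated
        assert "BA" in report.summary()
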