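"""Cross-validation, forward selection, the metric suite and the ANOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stopplv import (
    confusion_metrics,
    forward_select,
    loocv_accuracy,
    loocv_predict,
    one_way_anova,
    split_validate,
)
from stopplv.evaluate import MetricSet, truncate2


class TestConfusionMetrics:
    def test_printed_cells_nine_per_class_best_stage3_pair(self):
        """TP=8, FN=1, TN=9, FP=0 reproduces the 94.44% / 0 FPR / 1.00 PPV cell."""
        d = MetricSet(tp=8, fn=1, tn=9, fp=0).as_dict(reported=True)
        assert d["accuracy"] == 94.44
        assert d["sensitivity"] == 0.88
        assert d["specificity"] == 1.00
        assert d["fpr"] == 0.00
        assert d["ppv"] == 1.00

    def test_printed_cells_balanced_error_column(self):
        """TP=8, FN=1, TN=8, FP=1 reproduces the 88.88% / 0.12 FPR / 0.88 PPV cell."""
        d = MetricSet(tp=8, fn=1, tn=8, fp=1).as_dict(reported=True)
        assert d["accuracy"] == 88.88
        assert d["sensitivity"] == 0.88
        assert d["specificity"] == 0.88
        assert d["fpr"] == 0.12
        assert d["ppv"] == 0.88

    def test_perfect_prediction(self):
        m = confusion_metrics(["p", "n", "p"], ["p", "n", "p"], positive_class="p")
        assert m.accuracy == 100.0
        assert m.fpr == 0.0
        assert m.f_measure == 1.0

    def test_undefined_ratios_are_absent_not_zero(self):
        m = MetricSet(tp=0, fn=0, tn=5, fp=0)
        assert m.sensitivity is None
        assert m.ppv is None
        assert m.f_measure is None

    def test_none_predictions_excluded(self):
        m = confusion_metrics(["p", "n", "p"], ["p", None, "n"], positive_class="p")
        assert m.n == 2

    @given(
        tp=st.integers(0, 50), fn=st.integers(0, 50),
        tn=st.integers(0, 50), fp=st.integers(0, 50),
    )
    @settings(max_examples=200, deadline=None)
    def test_metric_identities(self, tp, fn, tn, fp):
        """FPR = 1 - specificity and F = harmonic mean of PPV and sensitivity."""
        m = MetricSet(tp, fn, tn, fp)
        if m.specificity is not None:
            assert m.fpr == pytest.approx(1.0 - m.specificity)
        if m.f_measure is not None:
            p, s = m.ppv, m.sensitivity
            assert m.f_measure == pytest.approx(2 * p * s / (p + s))
        if m.n:
            assert m.accuracy == pytest.approx(100.0 * (tp + tn) / m.n)


class TestLOOCV:
    def test_separable_data_perfect(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.3, (20, 2)), rng.normal(5, 0.3, (20, 2))])
        y = ["a"] * 20 + ["b"] * 20
        for clf in ("LDA", "QDA", "KNNC", "PARZENDC"):
            assert loocv_accuracy(X, y, clf) == 1.0

    def test_permuted_labels_at_chance_knn(self):
        """Label-permuted balanced data: mean KNNC LOOCV accuracy over 10
        permutations sits at chance (within 3 SE of 50%, n=100 each).

        A single-run binomial band would be too strict: leave-one-out
        predictions are correlated, so their variance exceeds binomial, and
        sampling labels without replacement adds a slight pessimism.
        """
        rng = np.random.default_rng(1)
        accs = []
        for _ in range(10):
            X = rng.normal(size=(100, 3))
            y = np.array(["a"] * 50 + ["b"] * 50)
            rng.shuffle(y)
            accs.append(loocv_accuracy(X, y, "KNNC"))
        sem = np.std(accs, ddof=1) / np.sqrt(len(accs))
        assert abs(np.mean(accs) - 0.5) < max(3 * sem, 0.03)

    def test_small_alternating_case_matches_hand_enumeration(self):
        """n=4 alternating 1-D labels with 1-NN: every fold's nearest other
        point has the opposite label, so every prediction is wrong."""
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = ["a", "b", "a", "b"]
        preds = loocv_predict(X, y, lambda: __import__("stopplv").KNNClassifier(k=1))
        assert list(preds) == ["b", "a", "b", "a"]

    def test_row_shuffle_invariance(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 2))
        y = np.array(["a", "b"] * 15)
        perm = rng.permutation(30)
        p1 = loocv_predict(X, y, "LDA")
        p2 = loocv_predict(X[perm], y[perm], "LDA")
        assert list(p1[perm]) == list(p2)

    def test_minimum_rows_enforced(self):
        with pytest.raises(ValueError):
            loocv_predict(np.zeros((3, 1)), ["a", "b", "a"], "KNNC")


class TestSplitValidate:
    def test_separable_data_mean_100_sd_0(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(0, 0.2, (30, 2)), rng.normal(6, 0.2, (30, 2))])
        y = ["a"] * 30 + ["b"] * 30
        mean, sd, _ = split_validate(X, y, "LDA", repeats=10, seed=0)
        assert mean == 100.0
        assert sd == 0.0

    def test_same_seed_identical_output(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 2))
        y = ["a", "b"] * 20
        out1 = split_validate(X, y, "KNNC", repeats=8, seed=5)
        out2 = split_validate(X, y, "KNNC", repeats=8, seed=5)
        assert out1[0] == out2[0] and np.array_equal(out1[2], out2[2])

    def test_many_repeats_approach_loocv_on_fixed_problem(self):
        """Repeated-split mean accuracy approaches LOOCV accuracy within 3 SE."""
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(0, 1.0, (40, 2)), rng.normal(2.0, 1.0, (40, 2))])
        y = ["a"] * 40 + ["b"] * 40
        loo = 100.0 * loocv_accuracy(X, y, "LDA")
        mean, sd, accs = split_validate(X, y, "LDA", repeats=200, seed=6)
        se = sd / np.sqrt(len(accs))
        assert abs(mean - loo) < 3 * se + 2.0


class TestForwardSelect:
    def test_planted_informative_feature_chosen_first(self):
        rng = np.random.default_rng(7)
        n = 60
        y = np.array(["a"] * 30 + ["b"] * 30)
        X = pd.DataFrame(rng.normal(size=(n, 10)), columns=[f"f{i}" for i in range(10)])
        X["f4"] = np.where(y == "a", 0.0, 4.0) + rng.normal(0, 0.5, n)
        trace = forward_select(X, y, "LDA", max_k=3)
        assert trace.chosen[0] == "f4"

    def test_identical_features_stop_after_one(self):
        X = pd.DataFrame({"a": [0.0, 1.0] * 10, "b": [0.0, 1.0] * 10})
        y = ["x", "y"] * 10
        trace = forward_select(X, y, "KNNC", max_k=2)
        assert len(trace) == 1

    def test_max_k_one_returns_best_single_feature(self):
        rng = np.random.default_rng(8)
        y = np.array(["a"] * 20 + ["b"] * 20)
        X = pd.DataFrame({
            "noise": rng.normal(size=40),
            "signal": np.where(y == "a", 0.0, 3.0) + rng.normal(0, 0.4, 40),
        })
        trace = forward_select(X, y, "LDA", max_k=1)
        assert trace.chosen == ["signal"]

    def test_trace_error_never_increases(self):
        rng = np.random.default_rng(9)
        y = np.array(["a"] * 25 + ["b"] * 25)
        X = pd.DataFrame(rng.normal(size=(50, 6)))
        X[0] = np.where(y == "a", 0.0, 1.5) + rng.normal(0, 1.0, 50)
        X[1] = np.where(y == "a", 0.0, 1.0) + rng.normal(0, 1.0, 50)
        trace = forward_select(X, y, "LDA", max_k=6)
        assert all(b <= a + 1e-12 for a, b in zip(trace.errors, trace.errors[1:]))


class TestAnova:
    def test_four_groups_of_eight_give_df_3_28(self):
        rng = np.random.default_rng(10)
        res = one_way_anova([rng.normal(size=8) for _ in range(4)])
        assert (res.df_between, res.df_within) == (3, 28)

    def test_identical_groups_give_f_zero_p_one(self):
        g = [1.0, 2.0, 3.0]
        res = one_way_anova([g, g, g])
        assert res.F == 0.0
        assert res.p == 1.0

    def test_hand_computed_sums_of_squares(self):
        """Three small groups with integer sums of squares, worked by hand.

        groups (1,2,3), (2,3,4), (6,7,8): grand mean 4; SSB = 3*(2-4)^2 +
        3*(3-4)^2 + 3*(7-4)^2 = 42; SSW = 2+2+2 = 6; F = (42/2)/(6/6) = 21.
        """
        res = one_way_anova([[1, 2, 3], [2, 3, 4], [6, 7, 8]])
        assert res.ss_between == pytest.approx(42.0)
        assert res.ss_within == pytest.approx(6.0)
        assert res.F == pytest.approx(21.0)

    def test_matches_scipy_f_oneway(self):
        from scipy.stats import f_oneway

        rng = np.random.default_rng(11)
        groups = [rng.normal(loc=i * 0.5, size=8) for i in range(4)]
        res = one_way_anova(groups)
        ref = f_oneway(*groups)
        assert res.F == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova([[1.0, 2.0]])
        with pytest.raises(ValueError):
            one_way_anova([[1.0], [2.0, 3.0]])
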