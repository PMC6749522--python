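"""The four classifiers against closed-form, brute-force and sklearn oracles."""

import numpy as np
import pytest

from stopplv import (
    KNNClassifier,
    LDAClassifier,
    ParzenClassifier,
    QDAClassifier,
    knn_predict,
    make_classifier,
)


def two_gaussians(rng, n=100, delta=3.0, d=2, cov=None):
    cov = np.eye(d) if cov is None else cov
    a = rng.multivariate_normal(np.zeros(d), cov, n)
    b = rng.multivariate_normal(np.full(d, delta), cov, n)
    X = np.vstack([a, b])
    y = np.array(["a"] * n + ["b"] * n)
    return X, y


class TestLDA:
    def test_separable_clouds_perfectly_fit(self):
        X, y = two_gaussians(np.random.default_rng(0), delta=8.0)
        clf = LDAClassifier().fit(X, y)
        assert np.all(clf.predict(X) == y)

    def test_equal_means_follow_priors(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(90, 2))
        y = np.array(["a"] * 60 + ["b"] * 30)
        clf = LDAClassifier().fit(X, y)
        preds = clf.predict(rng.normal(size=(200, 2)))
        assert np.mean(preds == "a") > 0.9  # majority prior dominates

    def test_boundary_matches_closed_form_gaussian_oracle(self):
        """Fitted direction aligns with Sigma^-1 (mu_b - mu_a) computed directly."""
        rng = np.random.default_rng(2)
        cov = np.array([[2.0, 0.6], [0.6, 1.0]])
        X, y = two_gaussians(rng, n=100, delta=2.0, cov=cov)
        clf = LDAClassifier(shrinkage=0.0).fit(X, y)
        w_fit = clf.coef_[:, 1] - clf.coef_[:, 0]
        mu_a, mu_b = X[y == "a"].mean(0), X[y == "b"].mean(0)
        Sa = np.cov(X[y == "a"], rowvar=False)
        Sb = np.cov(X[y == "b"], rowvar=False)
        pooled = ((len(X) // 2 - 1) * (Sa + Sb)) / (len(X) - 2)
        w_oracle = np.linalg.solve(pooled, mu_b - mu_a)
        assert np.allclose(w_fit, w_oracle, rtol=1e-8)

    def test_matches_sklearn_predictions(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(3)
        X, y = two_gaussians(rng, n=60, delta=1.5)
        grid = rng.normal(1.0, 2.0, size=(300, 2))
        ours = LDAClassifier(shrinkage=0.0).fit(X, y).predict(grid)
        ref = LinearDiscriminantAnalysis().fit(X, y).predict(grid)
        assert np.mean(ours == ref) > 0.99

    def test_singular_covariance_instructs_shrinkage(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [3.0, 6.0], [3.0, 6.0]])
        y = np.array(["a", "a", "b", "b"])
        with pytest.raises(ValueError, match="shrinkage"):
            LDAClassifier(shrinkage=0.0).fit(X, y)


class TestQDA:
    def test_reduces_to_lda_under_equal_covariances(self):
        rng = np.random.default_rng(4)
        X, y = two_gaussians(rng, n=400, delta=2.0)
        grid = rng.normal(1.0, 2.0, size=(400, 2))
        lda = LDAClassifier(shrinkage=0.0).fit(X, y).predict(grid)
        qda = QDAClassifier(shrinkage=0.0).fit(X, y).predict(grid)
        assert np.mean(lda == qda) > 0.97

    def test_concentric_classes_qda_beats_chance_lda_does_not(self):
        """Same mean, different variance: quadratic boundary is required."""
        rng = np.random.default_rng(5)
        inner = rng.normal(0, 1.0, (500, 2))
        outer = rng.normal(0, 3.0, (500, 2))
        X = np.vstack([inner, outer])
        y = np.array(["in"] * 500 + ["out"] * 500)
        test_in = rng.normal(0, 1.0, (250, 2))
        test_out = rng.normal(0, 3.0, (250, 2))
        Xt = np.vstack([test_in, test_out])
        yt = np.array(["in"] * 250 + ["out"] * 250)
        qda_acc = np.mean(QDAClassifier().fit(X, y).predict(Xt) == yt)
        lda_acc = np.mean(LDAClassifier().fit(X, y).predict(Xt) == yt)
        assert qda_acc > 0.65
        assert abs(lda_acc - 0.5) < 0.1

    def test_single_point_class_rejected(self):
        X = np.array([[0.0], [1.0], [2.0]])
        y = np.array(["a", "a", "b"])
        with pytest.raises(ValueError):
            QDAClassifier().fit(X, y)

    def test_matches_sklearn_predictions(self):
        from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis

        rng = np.random.default_rng(6)
        X, y = two_gaussians(rng, n=80, delta=1.0)
        grid = rng.normal(0.5, 2.0, size=(300, 2))
        ours = QDAClassifier(shrinkage=0.0).fit(X, y).predict(grid)
        ref = QuadraticDiscriminantAnalysis(store_covariance=True).fit(X, y).predict(grid)
        assert np.mean(ours == ref) > 0.99


class TestKNN:
    def test_k1_returns_exact_training_label(self):
        rng = np.random.default_rng(7)
        X, y = two_gaussians(rng, n=20)
        clf = KNNClassifier(k=1).fit(X, y)
        assert np.all(clf.predict(X) == y)

    def test_k_equals_n_returns_global_majority(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(30, 2))
        y = np.array(["a"] * 20 + ["b"] * 10)
        clf = KNNClassifier(k=30).fit(X, y)
        assert np.all(clf.predict(rng.normal(size=(50, 2))) == "a")

    def test_matches_brute_force_vote_oracle(self):
        """Predictions equal an all-pairs-distance majority vote (k=10, n=50)."""
        rng = np.random.default_rng(9)
        X = rng.normal(size=(50, 3))
        y = rng.choice(["a", "b"], size=50)
        T = rng.normal(size=(40, 3))
        preds = knn_predict(X, y, T, k=10)
        for i, t in enumerate(T):
            d = np.sqrt(((X - t) ** 2).sum(axis=1))
            nn = np.argsort(d, kind="stable")[:10]
            votes_a = np.sum(y[nn] == "a")
            if votes_a > 5:
                expected = "a"
            elif votes_a < 5:
                expected = "b"
            else:
                expected = y[nn[0]]  # tie -> nearest neighbour's class
            assert preds[i] == expected

    def test_k_exceeding_training_size_rejected(self):
        with pytest.raises(ValueError):
            KNNClassifier(k=10).fit(np.zeros((5, 1)), ["a", "a", "b", "b", "b"])


class TestParzen:
    def test_density_matches_direct_kernel_summation(self):
        """Class densities at 20 points equal the direct sum over Gaussians."""
        rng = np.random.default_rng(10)
        X, y = two_gaussians(rng, n=30)
        clf = ParzenClassifier(bandwidth=0.7).fit(X, y)
        T = rng.normal(size=(20, 2))
        h, d = 0.7, 2
        for c in ("a", "b"):
            Xc = X[y == c]
            direct = np.array(
                [
                    np.mean(
                        np.exp(-((t - Xc) ** 2).sum(1) / (2 * h * h))
                        / (2 * np.pi * h * h) ** (d / 2)
                    )
                    for t in T
                ]
            )
            assert np.allclose(clf.class_density(T, c), direct, rtol=1e-12)

    def test_density_matches_sklearn_kde(self):
        from sklearn.neighbors import KernelDensity

        rng = np.random.default_rng(11)
        X, y = two_gaussians(rng, n=40)
        clf = ParzenClassifier(bandwidth=0.5).fit(X, y)
        T = rng.normal(size=(15, 2))
        ref = np.exp(
            KernelDensity(bandwidth=0.5).fit(X[y == "a"]).score_samples(T)
        )
        assert np.allclose(clf.class_density(T, "a"), ref, rtol=1e-9)

    def test_bandwidth_grows_with_spread(self):
        rng = np.random.default_rng(12)
        X_tight, y = two_gaussians(rng, n=50, delta=2.0)
        X_wide = X_tight * 5.0
        h_tight = ParzenClassifier().fit(X_tight, y).bandwidth_
        h_wide = ParzenClassifier().fit(X_wide, y).bandwidth_
        assert h_wide > h_tight

    def test_bandwidth_is_argmax_over_its_grid(self):
        """The chosen bandwidth beats a dense brute-force LOO grid within 2x."""
        rng = np.random.default_rng(13)
        x = rng.normal(size=(100, 1))
        y = np.array(["a"] * 50 + ["b"] * 50)
        clf = ParzenClassifier()
        h = clf.fit_bandwidth(x, y)
        dense = np.geomspace(0.02, 5.0, 200)
        # brute-force LOO log-likelihood per candidate
        def loo_ll(h):
            ll = 0.0
            for c in ("a", "b"):
                xc = x[y == c][:, 0]
                D = (xc[:, None] - xc[None, :]) ** 2
                K = np.exp(-D / (2 * h * h)) / np.sqrt(2 * np.pi * h * h)
                np.fill_diagonal(K, 0.0)
                ll += np.sum(np.log(K.sum(1) / (len(xc) - 1) + 1e-300))
            return ll

        best_dense = dense[int(np.argmax([loo_ll(v) for v in dense]))]
        assert 0.5 * best_dense <= h <= 2.0 * best_dense

    def test_dense_cluster_wins(self):
        rng = np.random.default_rng(14)
        X, y = two_gaussians(rng, n=50, delta=6.0)
        clf = ParzenClassifier().fit(X, y)
        assert clf.predict(np.array([[0.0, 0.0]]))[0] == "a"
        assert clf.predict(np.array([[6.0, 6.0]]))[0] == "b"

    def test_too_few_points_per_class_rejected(self):
        X = np.array([[0.0], [0.1], [5.0], [5.1]])
        y = np.array(["a", "a", "b", "b"])
        with pytest.raises(ValueError):
            ParzenClassifier().fit(X, y)


class TestSharedProperties:
    @pytest.mark.parametrize("kind", ["LDA", "QDA", "KNNC", "PARZENDC"])
    def test_label_permutation_equivariance(self, kind):
        """Renaming the classes permutes the predictions identically."""
        rng = np.random.default_rng(15)
        X, y = two_gaussians(rng, n=30, delta=2.0)
        T = rng.normal(1.0, 2.0, size=(50, 2))
        p1 = make_classifier(kind).fit(X, y).predict(T)
        swap = {"a": "zz", "b": "aa"}
        y2 = np.array([swap[v] for v in y])
        p2 = make_classifier(kind).fit(X, y2).predict(T)
        assert np.all(np.array([swap[v] for v in p1]) == p2)

    @pytest.mark.parametrize("kind", ["LDA", "QDA", "KNNC", "PARZENDC"])
    def test_feature_column_order_invariance(self, kind):
        rng = np.random.default_rng(16)
        X, y = two_gaussians(rng, n=30, delta=2.0)
        T = rng.normal(1.0, 2.0, size=(50, 2))
        p1 = make_classifier(kind).fit(X, y).predict(T)
        p2 = make_classifier(kind).fit(X[:, ::-1], y).predict(T[:, ::-1])
        assert np.all(p1 == p2)

    @pytest.mark.parametrize("kind", ["LDA", "QDA"])
    def test_affine_invariance_of_discriminant_predictions(self, kind):
        """Invertible linear map + intercept leaves predicted labels unchanged."""
        rng = np.random.default_rng(17)
        X, y = two_gaussians(rng, n=60, delta=1.5)
        T = rng.normal(1.0, 2.0, size=(80, 2))
        A = np.array([[1.5, 0.3], [-0.2, 0.8]])
        b = np.array([2.0, -1.0])
        p1 = make_classifier(kind).fit(X, y).predict(T)
        p2 = make_classifier(kind).fit(X @ A.T + b, y).predict(T @ A.T + b)
        assert np.mean(p1 == p2) > 0.99
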