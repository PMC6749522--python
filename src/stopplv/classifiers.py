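"""From-definition implementations of the four classifiers: linear and
quadratic discriminant analysis (LDA/QDA), the k-nearest-neighbour classifier
(KNNC, k = 10) and the Parzen kernel-density classifier (PARZENDC) with
maximum-likelihood smoothing.

All four share one small API: ``fit(X, y)`` then ``predict(X)`` /
``predict_scores(X)``.  Class priors are estimated from training frequencies.
Score ties are broken deterministically: prefer the class of the single
nearest training neighbour, then the lexicographically smaller label.
Covariance estimates are shrunk towards their diagonal,
``S <- (1 - lam) S + lam diag(S)``, because per-fold class sizes in this
design are small.
"""

from __future__ import annotations

import numpy as np


def _as_2d(X) -> np.ndarray:
    X = np.asarray(getattr(X, "values", X), dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X


def _shrink(S: np.ndarray, lam: float) -> np.ndarray:
    return (1.0 - lam) * S + lam * np.diag(np.diag(S))


class BaseClassifier:
    """Shared fitting bookkeeping and deterministic tie-breaking."""

    def __init__(self) -> None:
        self.classes_: np.ndarray | None = None
        self._train_X: np.ndarray | None = None
        self._train_y: np.ndarray | None = None

    def _store(self, X: np.ndarray, y: np.ndarray) -> None:
        self.classes_ = np.array(sorted(set(map(str, y))))
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        self._train_X = X
        self._train_y = np.asarray([str(v) for v in y])

    def predict_scores(self, X) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def predict(self, X) -> np.ndarray:
        X = _as_2d(X)
        scores = self.predict_scores(X)
        labels = []
        for i in range(X.shape[0]):
            s = scores[i]
            tied = np.flatnonzero(s == s.max())
            if len(tied) == 1:
                labels.append(self.classes_[tied[0]])
                continue
            # Tie: class of the nearest training point if tied, else smallest.
            d = np.linalg.norm(self._train_X - X[i], axis=1)
            nn_class = self._train_y[np.argmin(d)]
            tied_classes = self.classes_[tied]
            labels.append(nn_class if nn_class in tied_classes else tied_classes[0])
        return np.asarray(labels)


class _GaussianDiscriminant(BaseClassifier):
    def __init__(self, shrinkage: float = 0.01) -> None:
        super().__init__()
        if not 0.0 <= shrinkage <= 1.0:
            raise ValueError("shrinkage must lie in [0, 1]")
        self.shrinkage = shrinkage
        self.priors_: np.ndarray | None = None
        self.means_: np.ndarray | None = None

    def _class_stats(self, X: np.ndarray, y: np.ndarray):
        means, covs, counts = [], [], []
        for c in self.classes_:
            Xc = X[y == c]
            if len(Xc) < 2:
                raise ValueError(f"class {c!r} needs at least 2 training rows")
            means.append(Xc.mean(axis=0))
            covs.append(np.atleast_2d(np.cov(Xc, rowvar=False)))
            counts.append(len(Xc))
        return np.asarray(means), covs, np.asarray(counts)

    @staticmethod
    def _check_pd(S: np.ndarray) -> np.ndarray:
        try:
            np.linalg.cholesky(S)
        except np.linalg.LinAlgError:
            raise ValueError(
                "singular covariance matrix; increase the shrinkage parameter"
            ) from None
        return S


class LDAClassifier(_GaussianDiscriminant):
    """Linear discriminant analysis with a pooled within-class covariance.

    The discriminant of class c at x is
    ``x' S^-1 mu_c - mu_c' S^-1 mu_c / 2 + ln pi_c`` with S the (shrunk)
    pooled covariance -- the Bayes classifier for Gaussian classes sharing
    one covariance.
    """

    def fit(self, X, y) -> "LDAClassifier":
        X = _as_2d(X)
        y = np.asarray([str(v) for v in np.asarray(y)])
        self._store(X, y)
        means, covs, counts = self._class_stats(X, y)
        pooled = sum((n - 1) * S for n, S in zip(counts, covs)) / (counts.sum() - len(counts))
        pooled = self._check_pd(_shrink(pooled, self.shrinkage))
        self.means_ = means
        self.priors_ = counts / counts.sum()
        self._inv = np.linalg.inv(pooled)
        self.coef_ = self._inv @ means.T                             # (d, C)
        self.intercept_ = (
            -0.5 * np.einsum("cd,dc->c", means, self.coef_) + np.log(self.priors_)
        )
        return self

    def predict_scores(self, X) -> np.ndarray:
        return _as_2d(X) @ self.coef_ + self.intercept_


class QDAClassifier(_GaussianDiscriminant):
    """Quadratic discriminant analysis with per-class covariances."""

    def fit(self, X, y) -> "QDAClassifier":
        X = _as_2d(X)
        y = np.asarray([str(v) for v in np.asarray(y)])
        self._store(X, y)
        means, covs, counts = self._class_stats(X, y)
        self.means_ = means
        self.priors_ = counts / counts.sum()
        self.covs_ = [self._check_pd(_shrink(S, self.shrinkage)) for S in covs]
        self._invs = [np.linalg.inv(S) for S in self.covs_]
        self._logdets = [np.linalg.slogdet(S)[1] for S in self.covs_]
        return self

    def predict_scores(self, X) -> np.ndarray:
        X = _as_2d(X)
        out = np.empty((X.shape[0], len(self.classes_)))
        for j in range(len(self.classes_)):
            diff = X - self.means_[j]
            maha = np.einsum("nd,de,ne->n", diff, self._invs[j], diff)
            out[:, j] = -0.5 * (self._logdets[j] + maha) + np.log(self.priors_[j])
        return out


class KNNClassifier(BaseClassifier):
    """k-nearest-neighbour majority vote with Euclidean distances (k = 10).

    Vote ties go to the class of the single nearest neighbour, then to the
    lexicographically smaller label.
    """

    def __init__(self, k: int = 10) -> None:
        super().__init__()
        if k < 1:
            raise ValueError("k must be at least 1")
        self.k = k

    def fit(self, X, y) -> "KNNClassifier":
        X = _as_2d(X)
        y = np.asarray([str(v) for v in np.asarray(y)])
        if self.k > len(X):
            raise ValueError(f"k={self.k} exceeds the training size {len(X)}")
        self._store(X, y)
        return self

    def predict_scores(self, X) -> np.ndarray:
        """Vote counts per class (fractions of k)."""
        X = _as_2d(X)
        d = np.linalg.norm(X[:, None, :] - self._train_X[None, :, :], axis=2)
        # stable argsort: equidistant neighbours resolve by training order
        nn = np.argsort(d, axis=1, kind="stable")[:, : self.k]
        out = np.zeros((X.shape[0], len(self.classes_)))
        for j, c in enumerate(self.classes_):
            out[:, j] = (self._train_y[nn] == c).mean(axis=1)
        return out


class ParzenClassifier(BaseClassifier):
    """Parzen kernel-density classifier with an ML-estimated bandwidth.

    Each class density is a Gaussian kernel estimate over its training
    points.  One shared bandwidth is chosen to maximise the leave-one-out
    log-likelihood of the training set (each point scored under its own
    class's density with itself held out), searched over a log-spaced grid
    with one refinement pass.  A test point goes to the class with maximal
    prior x density.
    """

    def __init__(self, bandwidth: float | None = None, grid_size: int = 16) -> None:
        super().__init__()
        self.bandwidth = bandwidth
        self.grid_size = grid_size

    # -- bandwidth selection -------------------------------------------
    @staticmethod
    def _loo_loglik(sq_dists: list[np.ndarray], d: int, h: float) -> float:
        ll = 0.0
        norm = -0.5 * d * np.log(2.0 * np.pi * h * h)
        for D in sq_dists:
            K = np.exp(-D / (2.0 * h * h))
            np.fill_diagonal(K, 0.0)
            dens = K.sum(axis=1) / (len(D) - 1)
            ll += float(np.sum(np.log(dens + 1e-300))) + len(D) * norm
        return ll

    def fit_bandwidth(self, X, y) -> float:
        """Grid-plus-refinement LOO maximum-likelihood bandwidth."""
        X = _as_2d(X)
        y = np.asarray([str(v) for v in np.asarray(y)])
        sq_dists = []
        for c in sorted(set(y)):
            Xc = X[y == c]
            if len(Xc) < 3:
                raise ValueError(f"class {c!r} needs at least 3 points for Parzen ML")
            diff = Xc[:, None, :] - Xc[None, :, :]
            sq_dists.append(np.einsum("ijd,ijd->ij", diff, diff))
        scale = float(np.mean(X.std(axis=0, ddof=1))) or 1.0
        grid = np.geomspace(0.05 * scale, 5.0 * scale, self.grid_size)
        lls = [self._loo_loglik(sq_dists, X.shape[1], h) for h in grid]
        h0 = grid[int(np.argmax(lls))]
        fine = np.geomspace(h0 / 2.0, h0 * 2.0, self.grid_size // 2)
        lls_f = [self._loo_loglik(sq_dists, X.shape[1], h) for h in fine]
        cand = np.concatenate([grid, fine])
        vals = np.concatenate([lls, lls_f])
        return float(cand[int(np.argmax(vals))])

    def fit(self, X, y) -> "ParzenClassifier":
        X = _as_2d(X)
        y = np.asarray([str(v) for v in np.asarray(y)])
        self._store(X, y)
        counts = np.array([(self._train_y == c).sum() for c in self.classes_])
        self.priors_ = counts / counts.sum()
        self.bandwidth_ = (
            float(self.bandwidth) if self.bandwidth is not None else self.fit_bandwidth(X, y)
        )
        return self

    def class_density(self, X, c: str) -> np.ndarray:
        """Gaussian kernel density of class c evaluated at the rows of X."""
        X = _as_2d(X)
        Xc = self._train_X[self._train_y == c]
        h, d = self.bandwidth_, X.shape[1]
        diff = X[:, None, :] - Xc[None, :, :]
        sq = np.einsum("njd,njd->nj", diff, diff)
        K = np.exp(-sq / (2.0 * h * h)) / (2.0 * np.pi * h * h) ** (d / 2.0)
        return K.mean(axis=1)

    def predict_scores(self, X) -> np.ndarray:
        X = _as_2d(X)
        return np.stack(
            [p * self.class_density(X, c) for p, c in zip(self.priors_, self.classes_)],
            axis=1,
        )


#: Canonical classifier names used in reports.
CLASSIFIER_NAMES = ("LDA", "QDA", "KNNC", "PARZENDC")


def make_classifier(kind: str, knn_k: int = 10, shrinkage: float = 0.01) -> BaseClassifier:
    """Instantiate a fresh classifier by its report name."""
    kind = kind.upper()
    if kind == "LDA":
        return LDAClassifier(shrinkage=shrinkage)
    if kind == "QDA":
        return QDAClassifier(shrinkage=shrinkage)
    if kind == "KNNC":
        return KNNClassifier(k=knn_k)
    if kind == "PARZENDC":
        return ParzenClassifier()
    raise ValueError(f"unknown classifier {kind!r}")


def knn_predict(train_X, train_y, test_X, k: int = 10) -> np.ndarray:
    """Functional k-NN shortcut: fit on (train_X, train_y), predict test_X."""
    return KNNClassifier(k=k).fit(train_X, train_y).predict(test_X)
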