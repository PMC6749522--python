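"""Model evaluation: leave-one-out and repeated-split cross-validation,
greedy forward feature selection, the confusion-matrix metric suite and the
one-way ANOVA used to compare classifiers.

Reported percentages and proportions are truncated (not rounded) at two
decimals -- 16/18 prints as 88.88%, 8/9 as 0.88 -- matching the convention of
the reference tables; full precision is retained internally.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classifiers import BaseClassifier, make_classifier

ClassifierSpec = Callable[[], BaseClassifier]


def _spec_factory(spec) -> ClassifierSpec:
    if callable(spec):
        return spec
    return lambda: make_classifier(str(spec))


def truncate2(x: float) -> float:
    """Truncate toward zero at two decimals (88.888... -> 88.88)."""
    return math.trunc(x * 100.0) / 100.0


@dataclass(frozen=True)
class MetricSet:
    """Confusion counts plus the derived performance quantities.

    Ratios with a zero denominator are ``None`` (absent), never coerced to 0.
    ``accuracy`` is a percentage; the other measures are proportions.
    """

    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @property
    def accuracy(self) -> float | None:
        return 100.0 * (self.tp + self.tn) / self.n if self.n else None

    @property
    def sensitivity(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def specificity(self) -> float | None:
        d = self.tn + self.fp
        return self.tn / d if d else None

    @property
    def fpr(self) -> float | None:
        s = self.specificity
        return None if s is None else 1.0 - s

    @property
    def ppv(self) -> float | None:
        d = self.tp + self.fp
        return self.tp / d if d else None

    @property
    def f_measure(self) -> float | None:
        p, s = self.ppv, self.sensitivity
        if p is None or s is None or (p + s) == 0:
            return None
        return 2.0 * p * s / (p + s)

    def as_dict(self, reported: bool = False) -> dict:
        """Full-precision values, or the report formatting when ``reported``.

        Reported values are truncated at two decimals, and the reported FPR
        is the complement of the *truncated* specificity (0.88 -> 0.12), the
        convention of the reference tables.
        """
        fmt = truncate2 if reported else (lambda v: v)
        out = {"TP": self.tp, "FN": self.fn, "TN": self.tn, "FP": self.fp}
        for name in ("accuracy", "sensitivity", "specificity", "fpr", "ppv", "f_measure"):
            v = getattr(self, name)
            out[name] = None if v is None else fmt(v)
        if reported and out["specificity"] is not None:
            out["fpr"] = round(1.0 - out["specificity"], 2)
        return out


def confusion_metrics(y_true, y_pred, positive_class) -> MetricSet:
    """Binary confusion counts and derived metrics.

    Rows whose prediction is ``None`` (e.g. skipped cross-validation folds)
    are excluded.
    """
    y_true = np.asarray([str(v) for v in y_true], dtype=object)
    y_pred = np.asarray(list(y_pred), dtype=object)
    if len(y_true) != len(y_pred):
        raise ValueError("label vectors must have equal length")
    valid = np.array([p is not None for p in y_pred])
    y_true, y_pred = y_true[valid], y_pred[valid].astype(str)
    classes = set(y_true) | set(y_pred)
    if len(classes - {str(positive_class)}) > 1:
        raise ValueError(f"confusion_metrics is binary; got classes {sorted(classes)}")
    pos = str(positive_class)
    tp = int(np.sum((y_true == pos) & (y_pred == pos)))
    fn = int(np.sum((y_true == pos) & (y_pred != pos)))
    tn = int(np.sum((y_true != pos) & (y_pred != pos)))
    fp = int(np.sum((y_true != pos) & (y_pred == pos)))
    return MetricSet(tp, fn, tn, fp)


def loocv_predict(X, y, spec) -> np.ndarray:
    """Leave-one-out predictions: row i predicted by a model trained on the rest.

    Folds whose training part lacks a class are skipped with a warning and
    yield ``None`` predictions.  Deterministic given the data and spec.
    """
    factory = _spec_factory(spec)
    Xa = np.asarray(getattr(X, "values", X), dtype=float)
    if Xa.ndim == 1:
        Xa = Xa[:, None]
    ya = np.asarray([str(v) for v in np.asarray(y)])
    n = len(ya)
    if n < 4:
        raise ValueError("leave-one-out needs at least 4 rows")
    classes = set(ya)
    preds: list = [None] * n
    skipped = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if set(ya[mask]) != classes:
            skipped += 1
            continue
        clf = factory().fit(Xa[mask], ya[mask])
        preds[i] = str(clf.predict(Xa[i : i + 1])[0])
    if skipped:
        warnings.warn(f"skipped {skipped} fold(s) missing a class in training")
    return np.asarray(preds, dtype=object)


def loocv_accuracy(X, y, spec) -> float:
    preds = loocv_predict(X, y, spec)
    ya = np.asarray([str(v) for v in np.asarray(y)])
    valid = np.array([p is not None for p in preds])
    if not valid.any():
        return float("nan")
    return float(np.mean(preds[valid].astype(str) == ya[valid]))


def split_validate(
    X,
    y,
    spec,
    train_fraction: float = 0.9,
    repeats: int = 20,
    seed: int = 0,
) -> tuple[float, float, np.ndarray]:
    """Repeated stratified train/test splits (default 90%/10%).

    Returns ``(mean, sd, per_repeat)`` accuracies in percent; the SD is the
    sample standard deviation across repeats (the "± SD" of the report
    tables).  Identical seeds give identical output.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    factory = _spec_factory(spec)
    rng = np.random.default_rng(seed)
    Xa = np.asarray(getattr(X, "values", X), dtype=float)
    if Xa.ndim == 1:
        Xa = Xa[:, None]
    ya = np.asarray([str(v) for v in np.asarray(y)])
    classes = sorted(set(ya))
    accs = np.empty(repeats)
    for r in range(repeats):
        test_idx: list[int] = []
        for c in classes:
            idx = np.flatnonzero(ya == c)
            n_test = max(1, round(len(idx) * (1.0 - train_fraction)))
            test_idx.extend(rng.choice(idx, size=n_test, replace=False).tolist())
        test = np.zeros(len(ya), dtype=bool)
        test[test_idx] = True
        clf = factory().fit(Xa[~test], ya[~test])
        accs[r] = 100.0 * np.mean(clf.predict(Xa[test]) == ya[test])
    return float(accs.mean()), float(accs.std(ddof=1)) if repeats > 1 else 0.0, accs


@dataclass
class SelectionTrace:
    """Greedy forward-selection path: chosen columns and LOOCV error per step."""

    chosen: list[str] = field(default_factory=list)
    errors: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.chosen)


def forward_select(X, y, spec, max_k: int | None = None) -> SelectionTrace:
    """Greedy forward feature selection driven by leave-one-out error.

    Starting from the empty set, each step adds the candidate column that
    minimises the LOOCV error of the augmented set (ties -> lowest column
    index) and stops when no candidate strictly improves or ``max_k`` is
    reached.  The LOOCV error along the trace never increases.
    """
    Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
    cols = list(Xdf.columns)
    max_k = len(cols) if max_k is None else min(max_k, len(cols))
    trace = SelectionTrace()
    best_err = np.inf
    while len(trace) < max_k:
        cand_errs = []
        remaining = [c for c in cols if c not in trace.chosen]
        for c in remaining:
            err = 1.0 - loocv_accuracy(Xdf[trace.chosen + [c]], y, spec)
            cand_errs.append(err)
        j = int(np.argmin(cand_errs))  # argmin takes the first minimum: lowest index
        if cand_errs[j] >= best_err:
            break
        best_err = cand_errs[j]
        trace.chosen.append(remaining[j])
        trace.errors.append(cand_errs[j])
    return trace


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    ss_between: float
    ss_within: float

    def __str__(self) -> str:
        return f"F({self.df_between}, {self.df_within}) = {self.F:.2f}, p = {self.p:.4g}"


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """One-way fixed-effects ANOVA from the between/within decomposition."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need at least 2 groups with at least 2 values each")
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    dfb = len(groups) - 1
    dfw = len(all_vals) - len(groups)
    if ssw == 0.0:
        F = 0.0 if ssb == 0.0 else float("inf")
    else:
        F = (ssb / dfb) / (ssw / dfw)
    p = 1.0 if F == 0.0 else float(stats.f.sf(F, dfb, dfw))
    return AnovaResult(float(F), dfb, dfw, p, float(ssb), float(ssw))
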