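"""Three-stage hierarchical classification of stop-signal EEG.

Stage 1 separates successful from failed stops during left-hand-response
inhibition (LHR-SS vs LHR-FS), stage 2 the same during right-hand-response
inhibition (RHR-SS vs RHR-FS), and stage 3 separates the two hands among
successful stops (RHR-SS vs LHR-SS).  Every (stage x electrode pair x
classifier) cell is evaluated with leave-one-out cross-validation for the
confusion-matrix metrics, and with repeated stratified 90/10 splits for the
mean ± SD accuracy.  Classifiers are compared per stage with a one-way ANOVA
over the per-pair accuracies (4 classifiers x 8 pairs -> df (3, 28)).

The public surface follows the model/results idiom:

>>> model = StopSignalHierarchy(epochs)
>>> res = model.fit(seed=0)
>>> print(res.summary())
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classifiers import CLASSIFIER_NAMES, make_classifier
from .epochs import EpochSet
from .evaluate import (
    AnovaResult,
    MetricSet,
    SelectionTrace,
    confusion_metrics,
    forward_select,
    loocv_predict,
    one_way_anova,
    split_validate,
    truncate2,
)
from .plv import WIDEBAND, FeatureTable, plv_features, znormalize_features
from .synth import ROI_PAIRS


@dataclass(frozen=True)
class StageSpec:
    """One binary stage: condition A vs condition B with a fixed positive class."""

    id: str
    condition_a: str
    condition_b: str
    positive: str        # positive class for sensitivity/PPV

    def __post_init__(self) -> None:
        if self.condition_a == self.condition_b:
            raise ValueError("stage conditions must be disjoint")
        if self.positive not in (self.condition_a, self.condition_b):
            raise ValueError("positive class must be one of the stage conditions")


#: The three stages; the positive class is FS in the stop-outcome stages and
#: RHR-SS in the hand stage, so sensitivity/PPV are consistently defined.
DEFAULT_STAGES = (
    StageSpec("stage1", "LHR-SS", "LHR-FS", positive="LHR-FS"),
    StageSpec("stage2", "RHR-SS", "RHR-FS", positive="RHR-FS"),
    StageSpec("stage3", "LHR-SS", "RHR-SS", positive="RHR-SS"),
)

STAGE_TITLES = {
    "stage1": "SS vs FS during LHR inhibition",
    "stage2": "SS vs FS during RHR inhibition",
    "stage3": "RHR (SS) vs LHR (SS)",
}


@dataclass
class CellResult:
    stage: str
    pair: str
    classifier: str
    metrics: MetricSet
    mean_accuracy: float
    sd_accuracy: float
    trace: SelectionTrace | None = None

    @property
    def loocv_accuracy(self) -> float | None:
        return self.metrics.accuracy


class StopSignalHierarchy:
    """Hierarchical PLV-classification model over an :class:`EpochSet`.

    Trials from all subjects are pooled per stage.  Features are the
    per-trial PLVs of the eight region-of-interest pairs over the 1-300 ms
    post-stimulus window (single 1-50 Hz band by default); each pair is
    evaluated with its own feature column(s).

    Parameters
    ----------
    epochs:
        Labelled stop-trial epochs (needs ``hand`` and ``outcome`` columns).
    select:
        If true, run greedy forward selection (up to ``max_k`` columns) inside
        each cell before evaluation; only meaningful with multiple bands.
    znorm:
        Z-transform features against the pre-stimulus (-200..0 ms) baseline
        feature distribution.
    """

    def __init__(
        self,
        epochs: EpochSet,
        pairs=ROI_PAIRS,
        stages=DEFAULT_STAGES,
        classifiers=CLASSIFIER_NAMES,
        window_ms: tuple[float, float] = (1.0, 300.0),
        bands: tuple = WIDEBAND,
        znorm: bool = False,
        select: bool = False,
        max_k: int = 3,
        split_repeats: int = 20,
        train_fraction: float = 0.9,
        knn_k: int = 10,
        shrinkage: float = 0.01,
        min_trials: int = 4,
    ) -> None:
        self.epochs = epochs
        self.pairs = [p if isinstance(p, str) else "-".join(p) for p in pairs]
        self.stages = list(stages)
        self.classifiers = list(classifiers)
        self.window_ms = tuple(window_ms)
        self.bands = tuple(map(tuple, bands))
        self.znorm = znorm
        self.select = select
        self.max_k = max_k
        self.split_repeats = split_repeats
        self.train_fraction = train_fraction
        self.knn_k = knn_k
        self.shrinkage = shrinkage
        self.min_trials = min_trials

    def _spec(self, name: str):
        return lambda: make_classifier(name, knn_k=self.knn_k, shrinkage=self.shrinkage)

    def extract_features(self) -> FeatureTable:
        feats = plv_features(self.epochs, self.pairs, self.window_ms, self.bands)
        if self.znorm:
            base = plv_features(self.epochs, self.pairs, (-200.0, 0.0), self.bands)
            feats = znormalize_features(feats, base)
        return feats

    def fit(self, seed: int = 0) -> "HierarchyResults":
        """Run every (stage, pair, classifier) cell. Deterministic given seed."""
        features = self.extract_features()
        labels = features.labels.to_numpy()
        cells: dict[tuple[str, str, str], CellResult] = {}
        anovas: dict[str, AnovaResult] = {}
        skipped: list[str] = []
        rng = np.random.default_rng(seed)

        for stage in self.stages:
            in_stage = np.isin(labels, [stage.condition_a, stage.condition_b])
            sub = features.subset(in_stage)
            y = sub.labels.to_numpy()
            n_a = int(np.sum(y == stage.condition_a))
            n_b = int(np.sum(y == stage.condition_b))
            if min(n_a, n_b) < self.min_trials:
                warnings.warn(
                    f"{stage.id}: only {n_a}/{n_b} trials per class; stage skipped"
                )
                skipped.append(stage.id)
                continue
            per_clf_acc: dict[str, list[float]] = {c: [] for c in self.classifiers}
            for pair in self.pairs:
                cols = sub.columns_for_pair(pair)
                Xp = sub.X[cols]
                split_seed = int(rng.integers(2**31))
                for clf_name in self.classifiers:
                    spec = self._spec(clf_name)
                    trace = None
                    Xc = Xp
                    if self.select and Xp.shape[1] > 1:
                        trace = forward_select(Xp, y, spec, max_k=self.max_k)
                        Xc = Xp[trace.chosen]
                    preds = loocv_predict(Xc, y, spec)
                    metrics = confusion_metrics(y, preds, stage.positive)
                    mean_acc, sd_acc, _ = split_validate(
                        Xc, y, spec,
                        train_fraction=self.train_fraction,
                        repeats=self.split_repeats,
                        seed=split_seed,
                    )
                    cells[(stage.id, pair, clf_name)] = CellResult(
                        stage.id, pair, clf_name, metrics, mean_acc, sd_acc, trace
                    )
                    per_clf_acc[clf_name].append(metrics.accuracy)
            try:
                anovas[stage.id] = one_way_anova(
                    [per_clf_acc[c] for c in self.classifiers]
                )
            except ValueError:
                pass
        return HierarchyResults(self, cells, anovas, skipped, seed, features)


class HierarchyResults:
    """Fitted hierarchy: per-cell metrics, best cells, ANOVA and reports."""

    def __init__(self, model, cells, anovas, skipped_stages, seed, features) -> None:
        self.model = model
        self.cells = cells
        self.anovas = anovas
        self.skipped_stages = skipped_stages
        self.seed = seed
        self.features = features

    # -- lookups --------------------------------------------------------
    def cell(self, stage: str, pair: str, classifier: str) -> CellResult:
        return self.cells[(stage, pair, classifier)]

    def stage_ids(self) -> list[str]:
        return [s.id for s in self.model.stages if s.id not in self.skipped_stages]

    def best_classifier(self, stage: str, pair: str) -> CellResult:
        """Best classifier for one (stage, pair), by LOOCV accuracy.

        Ties resolve in the canonical classifier order.
        """
        cands = [self.cells[(stage, pair, c)] for c in self.model.classifiers]
        return max(cands, key=lambda r: r.metrics.accuracy)

    def best(self, stage: str) -> CellResult:
        """The stage's best (pair, classifier) cell by LOOCV accuracy."""
        cands = [r for (s, _, _), r in self.cells.items() if s == stage]
        return max(cands, key=lambda r: r.metrics.accuracy)

    def anova(self, stage: str) -> AnovaResult:
        return self.anovas[stage]

    # -- tables ----------------------------------------------------------
    def accuracy_table(self, stage: str) -> pd.DataFrame:
        """LOOCV accuracy (%) per classifier (rows) and pair (columns)."""
        data = {
            pair: [self.cells[(stage, pair, c)].metrics.accuracy for c in self.model.classifiers]
            for pair in self.model.pairs
        }
        return pd.DataFrame(data, index=list(self.model.classifiers))

    def metric_table(self, stage: str, reported: bool = True) -> pd.DataFrame:
        """Best-classifier metric summary per pair (report-table layout).

        Rows: classifier, sensitivity, specificity, FPR, PPV, F-measure and
        mean ± SD accuracy; columns: electrode pairs.  With ``reported=True``
        values are truncated at two decimals, the convention of the printed
        tables.
        """
        fmt = truncate2 if reported else (lambda v: v)

        cols = {}
        for pair in self.model.pairs:
            r = self.best_classifier(stage, pair)
            d = r.metrics.as_dict(reported=reported)

            def _cell(v):
                return "" if v is None else v

            cols[pair] = [
                r.classifier,
                _cell(d["sensitivity"]),
                _cell(d["specificity"]),
                _cell(d["fpr"]),
                _cell(d["ppv"]),
                _cell(d["f_measure"]),
                f"{fmt(r.mean_accuracy)} ± {fmt(r.sd_accuracy)}",
            ]
        index = ["Classifier", "Sensitivity", "Specificity", "FPR", "PPV",
                 "F-measure", "Accuracy (Mean ± SD)"]
        return pd.DataFrame(cols, index=index)

    # -- presentation -----------------------------------------------------
    def summary(self) -> str:
        lines = ["Hierarchical stop-signal classification", "=" * 40]
        lines.append(f"trials: {self.model.epochs.n_trials}   seed: {self.seed}")
        lines.append(
            f"pairs: {', '.join(self.model.pairs)}   "
            f"window: {self.model.window_ms} ms   bands: {self.model.bands}"
        )
        for stage in self.stage_ids():
            lines.append("")
            lines.append(f"{stage}: {STAGE_TITLES.get(stage, stage)}")
            lines.append("-" * 40)
            lines.append(self.metric_table(stage).to_string())
            b = self.best(stage)
            lines.append(
                f"best cell: {b.pair} / {b.classifier} "
                f"(LOOCV accuracy {truncate2(b.metrics.accuracy)}%)"
            )
            if stage in self.anovas:
                lines.append(f"classifier ANOVA: {self.anovas[stage]}")
        if self.skipped_stages:
            lines.append("")
            lines.append(f"skipped stages (too few trials): {', '.join(self.skipped_stages)}")
        return "\n".join(lines)

    def save(self, out_dir: str) -> list[str]:
        """Write per-stage metric tables, the ANOVA summary and a run manifest.

        Idempotent: the same fitted results render byte-identical files.
        """
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = []
        for stage in self.stage_ids():
            p = out / f"{stage}_metrics.tsv"
            self.metric_table(stage).to_csv(p, sep="\t")
            written.append(str(p))
            p = out / f"{stage}_accuracy.tsv"
            self.accuracy_table(stage).to_csv(p, sep="\t")
            written.append(str(p))
        anova_rows = [
            {"stage": s, "F": a.F, "df_between": a.df_between,
             "df_within": a.df_within, "p": a.p}
            for s, a in self.anovas.items()
        ]
        p = out / "anova.tsv"
        pd.DataFrame(anova_rows).to_csv(p, sep="\t", index=False)
        written.append(str(p))
        p = out / "manifest.json"
        p.write_text(json.dumps(self.manifest(), indent=2, sort_keys=True))
        written.append(str(p))
        p = out / "summary.txt"
        p.write_text(self.summary() + "\n")
        written.append(str(p))
        return written

    def manifest(self) -> dict:
        import stopplv

        m = self.model
        return {
            "package_version": stopplv.__version__,
            "seed": self.seed,
            "n_trials": int(m.epochs.n_trials),
            "pairs": m.pairs,
            "stages": [
                {"id": s.id, "a": s.condition_a, "b": s.condition_b, "positive": s.positive}
                for s in m.stages
            ],
            "classifiers": m.classifiers,
            "window_ms": list(m.window_ms),
            "bands": [list(b) for b in m.bands],
            "znorm": m.znorm,
            "select": m.select,
            "split_repeats": m.split_repeats,
            "train_fraction": m.train_fraction,
            "knn_k": m.knn_k,
            "shrinkage": m.shrinkage,
        }


def run_hierarchy(
    epochs: EpochSet, pairs=ROI_PAIRS, stages=DEFAULT_STAGES, seed: int = 0, **kwargs
) -> HierarchyResults:
    """Functional entry point: build the model and fit it in one call."""
    return StopSignalHierarchy(epochs, pairs=pairs, stages=stages, **kwargs).fit(seed=seed)


def render_report(results: HierarchyResults, out_dir: str) -> list[str]:
    """Alias for :meth:`HierarchyResults.save`."""
    return results.save(out_dir)
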