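"""Leave-one-out evaluation harness.

Ties the whole pipeline together: per-subject network construction and
feature extraction, per-fold Fisher ranking and count selection on the
training subjects only, a linear max-margin classifier (C = 1 by default),
and confusion-count metrics reported as percentages.  Patients are the
positive class (label 1), controls negative (label 0), so sensitivity is
the patient detection rate and specificity the control detection rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .cohort import SubjectTimeSeries
from .graph import FeatureVector, extract_features
from .models import PearsonFBN, SparseFBN, SparseLowRankFBN
from .selection import fisher_score, select_feature_count

__all__ = [
    "ClassifierSpec",
    "ConfusionCounts",
    "EvaluationReport",
    "metrics",
    "cohort_features",
    "loocv_evaluate",
    "grid_search",
    "nested_grid_loocv",
    "selection_reports",
]

DEFAULT_CANDIDATE_COUNTS = tuple(range(1, 151))


@dataclass(frozen=True)
class ClassifierSpec:
    """Pluggable classifier: the default is a linear SVM with C = 1.

    A custom ``factory`` (no-argument callable returning a fitted-API
    estimator) replaces the default, so alternative classifiers can be
    supplied without being reimplemented here.
    """

    kind: str = "linear-max-margin"
    C: float = 1.0
    factory: object = None

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be > 0")

    def make(self):
        if self.factory is not None:
            return self.factory()
        # features are standardised on training statistics inside each fold
        return make_pipeline(StandardScaler(), SVC(kernel="linear", C=self.C))


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """Accuracy, sensitivity, specificity as percentages (2 decimals).

    A metric whose denominator is zero is reported as None (undefined),
    never as 0.
    """

    def pct(num: int, den: int) -> float | None:
        return round(100.0 * num / den, 2) if den > 0 else None

    return {
        "accuracy": pct(c.TP + c.TN, c.total),
        "sensitivity": pct(c.TP, c.TP + c.FN),
        "specificity": pct(c.TN, c.TN + c.FP),
    }


@dataclass
class EvaluationReport:
    """Full record of one leave-one-out run."""

    predictions: list[int]
    truths: list[int]
    confusion: ConfusionCounts
    metrics: dict
    selected_indices: list[list[int]]
    selected_counts: list[int]
    settings: dict = field(default_factory=dict)

    @property
    def n_folds(self) -> int:
        return len(self.predictions)

    def to_json(self, path=None) -> str:
        payload = {
            "settings": self.settings,
            "n_folds": self.n_folds,
            "predictions": self.predictions,
            "truths": self.truths,
            "confusion": vars(self.confusion),
            "metrics": self.metrics,
            "selected_counts": self.selected_counts,
            "selected_indices": self.selected_indices,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def summary(self) -> str:
        m = self.metrics
        fmt = lambda v: "undefined" if v is None else f"{v:.2f}%"
        return (
            f"LOOCV evaluation  [{self.settings.get('model', '?')}]\n"
            f"  folds:        {self.n_folds}\n"
            f"  confusion:    TP={self.confusion.TP} TN={self.confusion.TN} "
            f"FP={self.confusion.FP} FN={self.confusion.FN}\n"
            f"  accuracy:     {fmt(m['accuracy'])}\n"
            f"  sensitivity:  {fmt(m['sensitivity'])}\n"
            f"  specificity:  {fmt(m['specificity'])}\n"
            f"  median selected features: {int(np.median(self.selected_counts))}"
        )


def _build_network(ts: SubjectTimeSeries, model: str, params: dict):
    if model == "pearson":
        return PearsonFBN(ts).fit()
    if model == "sparse":
        return SparseFBN(ts, lam=params.get("lam", 1.0)).fit()
    if model in ("slr", "sparse_lowrank"):
        return SparseLowRankFBN(
            ts, lam1=params.get("lam1", 1.0), lam2=params.get("lam2", 1.0)
        ).fit()
    raise ValueError(f"unknown model {model!r}")


def cohort_features(
    subjects: list[SubjectTimeSeries],
    model: str = "sparse_lowrank",
    params: dict | None = None,
    binarize_method: str | None = None,
    density: float = 0.2,
) -> np.ndarray:
    """Subjects x features matrix via construct -> symmetrize -> binarize -> extract.

    The Pearson model keeps the strongest 20% of correlations by default;
    the regression models use their natural nonzero sparsity pattern.
    """
    params = params or {}
    rows = []
    for ts in subjects:
        res = _build_network(ts, model, params)
        if not res.symmetrized:
            res = res.symmetrize()
        method = binarize_method or ("proportional" if model == "pearson" else "nonzero")
        net = res.binarize(method=method, p=density if method == "proportional" else None)
        rows.append(extract_features(net, subject_id=ts.subject_id).values)
    return np.vstack(rows)


def loocv_evaluate(
    subjects: list[SubjectTimeSeries] | np.ndarray,
    labels: np.ndarray,
    model: str = "sparse_lowrank",
    params: dict | None = None,
    classifier: ClassifierSpec = ClassifierSpec(),
    candidate_counts=DEFAULT_CANDIDATE_COUNTS,
    binarize_method: str | None = None,
    density: float = 0.2,
    features: np.ndarray | None = None,
) -> EvaluationReport:
    """Leave-one-out evaluation of the full pipeline.

    Each subject is held out once; Fisher ranking, feature-count selection
    (inner leave-one-out) and classifier training see only the remaining
    subjects.  Per-subject feature extraction is a function of that subject
    alone, so it is computed once up front.  Precomputed ``features``
    (subjects x features) may be passed to skip network construction.
    """
    labels = np.asarray(labels, dtype=int)
    if features is None:
        features = cohort_features(
            subjects, model=model, params=params, binarize_method=binarize_method, density=density
        )
    X = np.asarray(features, dtype=float)
    n = X.shape[0]
    if n != labels.size:
        raise ValueError("labels do not match subjects")
    if min((labels == 1).sum(), (labels == 0).sum()) < 2:
        raise ValueError("need at least 2 subjects per class for LOOCV")
    counts = [k for k in candidate_counts if k <= X.shape[1]]

    predictions, sel_idx, sel_counts = [], [], []
    for held in range(n):
        tr = np.ones(n, dtype=bool)
        tr[held] = False
        if np.unique(labels[tr]).size < 2:
            raise ValueError("degenerate training fold: one class absent")
        ranking = fisher_score(X[tr], labels[tr])
        k, idx = select_feature_count(
            X[tr], labels[tr], ranking, counts, classifier.make
        )
        clf = classifier.make()
        clf.fit(X[np.ix_(tr, idx)], labels[tr])
        pred = int(clf.predict(X[held][idx].reshape(1, -1))[0])
        predictions.append(pred)
        sel_idx.append([int(i) for i in idx])
        sel_counts.append(int(k))

    preds = np.asarray(predictions)
    confusion = ConfusionCounts(
        TP=int(((preds == 1) & (labels == 1)).sum()),
        TN=int(((preds == 0) & (labels == 0)).sum()),
        FP=int(((preds == 1) & (labels == 0)).sum()),
        FN=int(((preds == 0) & (labels == 1)).sum()),
    )
    return EvaluationReport(
        predictions=[int(p) for p in preds],
        truths=[int(t) for t in labels],
        confusion=confusion,
        metrics=metrics(confusion),
        selected_indices=sel_idx,
        selected_counts=sel_counts,
        settings={
            "model": model,
            "params": params or {},
            "classifier": classifier.kind,
            "C": classifier.C,
            "candidate_counts": [int(c) for c in counts],
        },
    )


def grid_search(
    subjects: list[SubjectTimeSeries],
    labels: np.ndarray,
    lam1_grid,
    lam2_grid,
    **loocv_kwargs,
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Outer-accuracy surface over a (lam1, lam2) grid.

    Each cell is the leave-one-out accuracy of the sparse low-rank pipeline
    at that penalty pair; the best pair is the accuracy argmax with ties
    broken by the lexicographically smallest (lam1, lam2).  Because the
    surface is scored on the same outer folds used to pick the pair, it is
    the optimistic, figure-style protocol; see :func:`nested_grid_loocv`
    for the fully nested alternative.
    """
    lam1_grid = [float(x) for x in lam1_grid]
    lam2_grid = [float(x) for x in lam2_grid]
    if not lam1_grid or not lam2_grid:
        raise ValueError("grids must be nonempty")
    surface = pd.DataFrame(index=lam1_grid, columns=lam2_grid, dtype=float)
    best = None
    for lam1 in lam1_grid:
        for lam2 in lam2_grid:
            rep = loocv_evaluate(
                subjects, labels, model="sparse_lowrank",
                params={"lam1": lam1, "lam2": lam2}, **loocv_kwargs,
            )
            acc = rep.metrics["accuracy"]
            surface.loc[lam1, lam2] = acc
            if best is None or acc > best[0] or (acc == best[0] and (lam1, lam2) < best[1]):
                best = (acc, (lam1, lam2))
    surface.index.name = "lam1"
    surface.columns.name = "lam2"
    return surface, best[1]


def nested_grid_loocv(
    subjects: list[SubjectTimeSeries],
    labels: np.ndarray,
    lam1_grid,
    lam2_grid,
    classifier: ClassifierSpec = ClassifierSpec(),
    candidate_counts=DEFAULT_CANDIDATE_COUNTS,
) -> EvaluationReport:
    """Fully nested protocol: the penalty pair is chosen inside each fold.

    For every outer fold, an inner leave-one-out grid search over the
    training subjects picks (lam1, lam2); the held-out subject is scored
    with that pair.  Unbiased but quadratically more expensive than
    :func:`grid_search`.
    """
    labels = np.asarray(labels, dtype=int)
    n = len(subjects)
    feature_cache = {
        (l1, l2): cohort_features(
            subjects, model="sparse_lowrank", params={"lam1": l1, "lam2": l2}
        )
        for l1 in lam1_grid
        for l2 in lam2_grid
    }
    predictions, sel_idx, sel_counts = [], [], []
    for held in range(n):
        tr = np.ones(n, dtype=bool)
        tr[held] = False
        best = None
        for (l1, l2), X in feature_cache.items():
            inner = loocv_evaluate(
                None, labels[tr], classifier=classifier,
                candidate_counts=candidate_counts, features=X[tr],
            )
            acc = inner.metrics["accuracy"]
            if best is None or acc > best[0] or (acc == best[0] and (l1, l2) < best[1]):
                best = (acc, (l1, l2))
        X = feature_cache[best[1]]
        ranking = fisher_score(X[tr], labels[tr])
        counts = [k for k in candidate_counts if k <= X.shape[1]]
        k, idx = select_feature_count(X[tr], labels[tr], ranking, counts, classifier.make)
        clf = classifier.make()
        clf.fit(X[np.ix_(tr, idx)], labels[tr])
        predictions.append(int(clf.predict(X[held][idx].reshape(1, -1))[0]))
        sel_idx.append([int(i) for i in idx])
        sel_counts.append(int(k))
    preds = np.asarray(predictions)
    confusion = ConfusionCounts(
        TP=int(((preds == 1) & (labels == 1)).sum()),
        TN=int(((preds == 0) & (labels == 0)).sum()),
        FP=int(((preds == 1) & (labels == 0)).sum()),
        FN=int(((preds == 0) & (labels == 1)).sum()),
    )
    return EvaluationReport(
        predictions=[int(p) for p in preds],
        truths=[int(t) for t in labels],
        confusion=confusion,
        metrics=metrics(confusion),
        selected_indices=sel_idx,
        selected_counts=sel_counts,
        settings={"model": "sparse_lowrank", "protocol": "nested-grid"},
    )


def selection_reports(
    report: EvaluationReport, m: int, region_labels: list[str]
) -> tuple[pd.Series, pd.Series]:
    """Which feature kinds and which regions drive the classification.

    Returns ``(kind_proportions, region_fold_counts)``: the proportion of
    all selected feature slots falling in each of the eight kinds, and for
    each region the number of folds in which at least one of its nodal
    features was selected (a region selected in every fold is a stable
    discriminative region).
    """
    kind_counter: dict[str, int] = {}
    region_folds: dict[int, int] = {}
    total = 0
    for fold_idx in report.selected_indices:
        fold_regions = set()
        for idx in fold_idx:
            kind, region = FeatureVector.describe_index(idx, m)
            kind_counter[kind] = kind_counter.get(kind, 0) + 1
            total += 1
            if region is not None:
                fold_regions.add(region)
        for r in fold_regions:
            region_folds[r] = region_folds.get(r, 0) + 1
    props = pd.Series(
        {k: kind_counter.get(k, 0) / total if total else 0.0 for k in _all_kinds()},
        name="proportion",
    )
    counts = pd.Series(
        {region_labels[r]: region_folds.get(r, 0) for r in range(m)}, name="n_folds_selected"
    ).sort_values(ascending=False, kind="stable")
    return props, counts


def _all_kinds():
    from .graph import FEATURE_KINDS

    return FEATURE_KINDS
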