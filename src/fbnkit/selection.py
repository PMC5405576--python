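"""Fisher-score feature ranking and validation-based count selection.

The Fisher score of a single feature for a two-class problem is

    FS = [p1 (q1 - q)^2 + p2 (q2 - q)^2] / (p1 s1^2 + p2 s2^2)

with class sizes p1, p2, class means q1, q2, overall mean q and population
class variances s1^2, s2^2.  It is nonnegative, invariant to affine
rescaling of the feature, and large when the class means are well separated
relative to the within-class spread.  How many top-ranked features to keep
is chosen by inner leave-one-out accuracy on the training subjects alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FisherRanking", "fisher_score", "select_feature_count"]


@dataclass(frozen=True)
class FisherRanking:
    """Per-feature scores and the descending-score ranking.

    Ties are broken by ascending feature index; features whose pooled
    within-class variance is zero but whose class means differ get an
    infinite score and rank first.
    """

    scores: np.ndarray
    order: np.ndarray
    tie_rule: str = "ascending feature index"


def fisher_score(features: np.ndarray, labels: np.ndarray) -> FisherRanking:
    """Rank features (columns) of a subjects x features matrix.

    Parameters
    ----------
    features
        (n_subjects, n_features) array.
    labels
        Binary labels, one per subject; both classes must be present.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("features must be (n_subjects, n_features) matching labels")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes, got {classes.size}")
    mask1 = y == classes[0]
    mask2 = ~mask1
    p1, p2 = mask1.sum(), mask2.sum()
    q1 = X[mask1].mean(axis=0)
    q2 = X[mask2].mean(axis=0)
    q = X.mean(axis=0)
    v1 = X[mask1].var(axis=0, ddof=0)
    v2 = X[mask2].var(axis=0, ddof=0)
    num = p1 * (q1 - q) ** 2 + p2 * (q2 - q) ** 2
    den = p1 * v1 + p2 * v2
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = num / den
    scores[(den == 0) & (num == 0)] = 0.0
    scores[(den == 0) & (num > 0)] = np.inf
    order = np.lexsort((np.arange(scores.size), -scores))
    return FisherRanking(scores=scores, order=order)


def select_feature_count(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    ranking: FisherRanking,
    candidate_counts: list[int],
    classifier_factory,
) -> tuple[int, np.ndarray]:
    """Pick the feature count with best inner leave-one-out accuracy.

    For each candidate k, a classifier from ``classifier_factory()`` is
    evaluated by leave-one-out over the training subjects using only the
    top-k ranked features; the k with the highest inner accuracy wins, ties
    going to the smallest k.  Held-out data never enters this routine.

    Returns ``(k, selected_indices)``.
    """
    if not candidate_counts:
        raise ValueError("candidate_counts must be nonempty")
    X = np.asarray(train_features, dtype=float)
    y = np.asarray(train_labels)
    n = X.shape[0]
    counts = sorted(set(int(k) for k in candidate_counts))
    if counts[0] < 1 or counts[-1] > X.shape[1]:
        raise ValueError("candidate counts must lie in [1, n_features]")
    best_k, best_acc = counts[0], -1.0
    for k in counts:
        idx = ranking.order[:k]
        correct = 0
        for held in range(n):
            tr = np.ones(n, dtype=bool)
            tr[held] = False
            if np.unique(y[tr]).size < 2:
                continue
            clf = classifier_factory()
            clf.fit(X[np.ix_(tr, idx)], y[tr])
            correct += int(clf.predict(X[held][idx].reshape(1, -1))[0] == y[held])
        acc = correct / n
        if acc > best_acc:
            best_k, best_acc = k, acc
    return best_k, ranking.order[:best_k].copy()
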