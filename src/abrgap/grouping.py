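"""Categorical grouping of responses along the gap/NB1 ratio.

Conditions with gap/NB1 ratio at or below the boundary (0.5) form the
*suppressed* group (trailing onset response weaker than the leading one);
conditions above it form the *balanced/enhanced* group.  The grouping is
validated two ways: a supervised linear SVM with 10-fold cross-validation
and ROC analysis, and unsupervised k-means clustering under a cosine
distance, with the cluster count checked by silhouette analysis and the
cluster/group correspondence scored by a confusion matrix and its
informedness (sensitivity + specificity - 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from sklearn.metrics import precision_score, roc_curve, auc as _trapezoid_auc
from sklearn.metrics import silhouette_score
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "GroupLabel",
    "ConfusionMatrix",
    "ClassifierReport",
    "assign_group",
    "svm_classify",
    "roc_auc",
    "kmeans_cosine",
    "kmeans_two",
    "silhouette_optimal_k",
    "cluster_to_group",
    "confusion_and_informedness",
    "BOUNDARY_RATIO",
]

#: Grouping boundary on the gap/NB1 duration ratio.
BOUNDARY_RATIO = 0.5


class GroupLabel(str, Enum):
    SUPPRESSED = "suppressed"
    BALANCED_ENHANCED = "balanced_enhanced"


def assign_group(ratio: float, boundary: float = BOUNDARY_RATIO) -> GroupLabel:
    """Suppressed iff ratio <= boundary (boundary itself is suppressed)."""
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    return GroupLabel.SUPPRESSED if ratio <= boundary else GroupLabel.BALANCED_ENHANCED


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts with the balanced/enhanced class positive.

    Informedness (sensitivity + specificity - 1) is the probability of an
    informed — better than chance — prediction: 1 for perfect separation,
    0 for label-independent assignment, -1 for systematic inversion.
    """

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def informedness(self) -> float:
        return self.sensitivity + self.specificity - 1.0


@dataclass(frozen=True)
class ClassifierReport:
    accuracy_pct: float
    precision_pct: float
    cv_accuracy_pct: float
    cv_precision_pct: float
    roc_points: np.ndarray  # (n, 2): false-positive rate, true-positive rate
    auc: float


def _as_binary(labels: Sequence[GroupLabel | str]) -> np.ndarray:
    """1 for balanced/enhanced (positive class), 0 for suppressed."""
    values = [GroupLabel(l).value for l in labels]
    return np.array([1 if v == GroupLabel.BALANCED_ENHANCED.value else 0 for v in values])


def svm_classify(
    features: np.ndarray,
    labels: Sequence[GroupLabel | str],
    n_folds: int = 10,
    seed: int = 0,
    kernel: str = "linear",
    standardize: bool = True,
) -> ClassifierReport:
    """Supervised binary SVM with stratified 10-fold cross-validation.

    Reports resubstitution and cross-validated accuracy and precision
    (precision for the balanced/enhanced class) plus the ROC curve and
    AUC computed from the cross-validated decision scores.
    """
    X = np.asarray(features, dtype=float)
    y = _as_binary(labels)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("features must be (n_points, n_features) matching labels")
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise ValueError("need at least 2 points per class")
    if counts.min() < n_folds:  # stratification needs >= 1 minority point per fold
        warnings.warn(
            f"reducing folds from {n_folds} to {counts.min()} "
            "(minority class too small)",
            stacklevel=2,
        )
        n_folds = int(counts.min())

    steps = ([StandardScaler()] if standardize else []) + [SVC(kernel=kernel)]
    model = make_pipeline(*steps)
    model.fit(X, y)
    resub = model.predict(X)
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    cv_pred = cross_val_predict(model, X, y, cv=cv)
    cv_scores = cross_val_predict(model, X, y, cv=cv, method="decision_function")
    roc_points, auc_value = roc_auc(cv_scores, labels)
    return ClassifierReport(
        accuracy_pct=100.0 * float(np.mean(resub == y)),
        precision_pct=100.0 * float(precision_score(y, resub)),
        cv_accuracy_pct=100.0 * float(np.mean(cv_pred == y)),
        cv_precision_pct=100.0 * float(precision_score(y, cv_pred)),
        roc_points=roc_points,
        auc=auc_value,
    )


def roc_auc(
    decision_scores: np.ndarray, labels: Sequence[GroupLabel | str]
) -> tuple[np.ndarray, float]:
    """ROC by threshold sweep and its trapezoidal area.

    Returns points running from (0, 0) to (1, 1) as (FPR, TPR) pairs.
    """
    scores = np.asarray(decision_scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("decision scores must be finite")
    y = _as_binary(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, _ = roc_curve(y, scores)
    return np.column_stack([fpr, tpr]), float(_trapezoid_auc(fpr, tpr))


def _cosine_inertia(Xn: np.ndarray, centroids: np.ndarray, labels: np.ndarray) -> float:
    sims = np.einsum("ij,ij->i", Xn, centroids[labels])
    return float(np.sum(1.0 - sims))


def kmeans_cosine(
    features: np.ndarray,
    k: int,
    seed: int = 0,
    n_restarts: int = 20,
    max_iter: int = 300,
) -> np.ndarray:
    """Lloyd's k-means under cosine distance (1 - cosine similarity).

    Points are compared by direction only, so the partition is invariant
    to positive per-point scaling.  Centroids are normalized means of
    their members; the best of ``n_restarts`` seeded random
    initializations (lowest total cosine inertia) is returned.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or len(X) < k:
        raise ValueError(f"need at least k={k} points in a 2-D feature array")
    norms = np.linalg.norm(X, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero feature vector: cosine distance undefined at the origin")
    Xn = X / norms[:, None]
    rng = np.random.default_rng(seed)
    best_labels, best_inertia = None, np.inf
    for _ in range(n_restarts):
        centroids = Xn[rng.choice(len(Xn), size=k, replace=False)]
        labels = None
        for _iteration in range(max_iter):
            sims = Xn @ centroids.T
            new_labels = np.argmax(sims, axis=1)
            for j in range(k):  # re-seed empty clusters with the worst-fit point
                if not np.any(new_labels == j):
                    new_labels[np.argmin(np.max(sims, axis=1))] = j
            if labels is not None and np.array_equal(new_labels, labels):
                break
            labels = new_labels
            for j in range(k):
                c = Xn[labels == j].mean(axis=0)
                nc = np.linalg.norm(c)
                centroids[j] = c / nc if nc > 0 else Xn[rng.integers(len(Xn))]
        inertia = _cosine_inertia(Xn, centroids, labels)
        if inertia < best_inertia - 1e-12:
            best_inertia, best_labels = inertia, labels.copy()
    return best_labels


def kmeans_two(features: np.ndarray, seed: int = 0, n_restarts: int = 20) -> np.ndarray:
    """Binary cosine k-means partition (cluster ids 0/1)."""
    return kmeans_cosine(features, k=2, seed=seed, n_restarts=n_restarts)


def silhouette_optimal_k(
    features: np.ndarray,
    k_range: Sequence[int] = tuple(range(2, 11)),
    seed: int = 0,
    return_scores: bool = False,
):
    """Number of clusters maximizing the mean cosine silhouette.

    Clustering solutions for each candidate k are produced by cosine
    k-means; ties go to the smallest k.  A low best silhouette (< 0.25)
    triggers a warning since it indicates no real cluster structure.
    """
    X = np.asarray(features, dtype=float)
    k_range = sorted(k_range)
    if k_range[0] < 2 or k_range[-1] > len(X) - 1:
        raise ValueError("k_range must lie within [2, n_points - 1]")
    scores: dict[int, float] = {}
    for k in k_range:
        labels = kmeans_cosine(X, k=k, seed=seed)
        scores[k] = float(silhouette_score(X, labels, metric="cosine"))
    best_k = max(k_range, key=lambda k: (scores[k], -k))
    if scores[best_k] < 0.25:
        warnings.warn(
            f"best silhouette {scores[best_k]:.3f} is weak; "
            "cluster structure may be absent",
            stacklevel=2,
        )
    return (best_k, scores) if return_scores else best_k


def cluster_to_group(
    cluster_labels: np.ndarray, features: np.ndarray | None = None
) -> list[GroupLabel]:
    """Map a binary clustering onto group labels by cluster size.

    The larger cluster represents the suppressed group (most grid
    conditions have ratio <= 0.5).  An exact size tie is broken by
    feature magnitude: the cluster with the lower mean summed feature
    value is called suppressed.
    """
    labels = np.asarray(cluster_labels)
    ids = np.unique(labels)
    if len(ids) != 2:
        raise ValueError("cluster labels must form a binary partition")
    sizes = {i: int(np.sum(labels == i)) for i in ids}
    if sizes[ids[0]] != sizes[ids[1]]:
        larger = max(ids, key=lambda i: sizes[i])
    else:
        if features is None:
            raise ValueError("size tie: features needed for the tie-break")
        X = np.asarray(features, dtype=float)
        means = {i: X[labels == i].sum(axis=1).mean() for i in ids}
        larger = min(ids, key=lambda i: means[i])
    return [
        GroupLabel.SUPPRESSED if l == larger else GroupLabel.BALANCED_ENHANCED
        for l in labels
    ]


def confusion_and_informedness(
    predicted: Sequence[GroupLabel | str],
    reference: Sequence[GroupLabel | str],
) -> ConfusionMatrix:
    """Confusion counts of predicted vs reference group labels.

    Balanced/enhanced is the positive class: TP are balanced/enhanced
    points predicted balanced/enhanced, TN are suppressed points
    predicted suppressed.
    """
    if len(predicted) != len(reference):
        raise ValueError("label sequences must have equal length")
    p = _as_binary(predicted)
    r = _as_binary(reference)
    return ConfusionMatrix(
        tp=int(np.sum((p == 1) & (r == 1))),
        fn=int(np.sum((p == 0) & (r == 1))),
        tn=int(np.sum((p == 0) & (r == 0))),
        fp=int(np.sum((p == 1) & (r == 0))),
    )
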