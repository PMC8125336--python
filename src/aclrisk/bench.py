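"""Nine-classifier benchmark under 9-fold cross-validation.

Three SVMs (linear / quadratic / cubic polynomial kernels), three kNNs
(fine: k=1 Euclidean; cosine: k=10 cosine; weighted: k=10 squared-inverse
Euclidean) and three Gini decision trees (coarse / medium / complex: at most
4 / 20 / 100 splits). Features are z-scored with training-fold statistics
only; predictions are pooled into one confusion matrix per classifier
(per-fold averaging available as an option) from which accuracy, F1 (with
the *no-risk* class as positive) and the goodness index

    G = sqrt((1 - sensitivity)^2 + (1 - specificity)^2)

— the ROC-space distance to the perfect classifier — are computed.
G <= 0.25 is an optimum classifier, G <= 0.70 good, chance level sits at
sqrt(0.5) ~ 0.71, anything beyond is bad.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FEATURE_NAMES

POSITIVE = "NR"  # the no-risk class is the positive one throughout

CLASSIFIER_IDS = (
    "l-SVM", "q-SVM", "c-SVM",
    "f-kNN", "c-kNN", "w-kNN",
    "c-DT", "m-DT", "cx-DT",
)


def _squared_inverse(dist: np.ndarray) -> np.ndarray:
    return 1.0 / np.maximum(dist, 1e-12) ** 2


def make_classifier(variant: str, random_state: int | None = None):
    """Instantiate one of the nine benchmark configurations."""
    if variant == "l-SVM":
        return SVC(kernel="linear", C=1.0)
    if variant == "q-SVM":
        return SVC(kernel="poly", degree=2, coef0=1.0, C=1.0, gamma="scale")
    if variant == "c-SVM":
        return SVC(kernel="poly", degree=3, coef0=1.0, C=1.0, gamma="scale")
    if variant == "f-kNN":
        return KNeighborsClassifier(n_neighbors=1, metric="euclidean")
    if variant == "c-kNN":
        return KNeighborsClassifier(n_neighbors=10, metric="cosine")
    if variant == "w-kNN":
        return KNeighborsClassifier(
            n_neighbors=10, metric="euclidean", weights=_squared_inverse
        )
    if variant in ("c-DT", "m-DT", "cx-DT"):
        max_splits = {"c-DT": 4, "m-DT": 20, "cx-DT": 100}[variant]
        return DecisionTreeClassifier(
            criterion="gini",
            max_leaf_nodes=max_splits + 1,
            random_state=random_state,
        )
    raise ValueError(f"unknown classifier variant {variant!r}")


@dataclass
class ConfusionMatrix:
    """Pooled 2x2 counts; positive class is NR."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def accuracy(cm: ConfusionMatrix) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return (cm.tp + cm.tn) / cm.total


def f1_score(cm: ConfusionMatrix) -> float:
    """Harmonic mean of recall TP/(TP+FN) and precision TP/(TP+FP); 0 if TP=0."""
    if cm.tp == 0:
        return 0.0
    recall = cm.tp / (cm.tp + cm.fn)
    precision = cm.tp / (cm.tp + cm.fp)
    return 2 * recall * precision / (recall + precision)


def g_index(cm: ConfusionMatrix) -> float:
    """ROC-space distance to the perfect classifier, on sensitivity and
    specificity rates; ranges 0 (perfect) to sqrt(2)."""
    if cm.tp + cm.fn == 0 or cm.tn + cm.fp == 0:
        raise ValueError("G requires both classes present")
    sens = cm.tp / (cm.tp + cm.fn)
    spec = cm.tn / (cm.tn + cm.fp)
    return float(np.hypot(1 - sens, 1 - spec))


def goodness_category(g: float) -> str:
    """Band the goodness index: optimum (<= 0.25), good (<= 0.70), random
    (around the chance distance sqrt(0.5)), else bad."""
    if not 0 <= g <= np.sqrt(2) + 1e-9:
        raise ValueError("G must lie in [0, sqrt(2)]")
    if g <= 0.25:
        return "optimum"
    if g <= 0.70:
        return "good"
    if g <= np.sqrt(0.5) + 1e-9:
        return "random"
    return "bad"


def split_folds(
    n: int,
    scheme: str = "grouped-9fold",
    seed: int | None = None,
    labels: np.ndarray | None = None,
    n_folds: int = 9,
) -> list[np.ndarray]:
    """Test-fold index sets.

    ``grouped-9fold``: disjoint folds of size floor/ceil(n / folds), every
    athlete tested exactly once (class-stratified dealing when labels are
    given). ``random-holdout``: ``n_folds`` independent random hold-outs of 9
    athletes each (training 30 when n = 39), mirroring the published
    description, in which athletes may repeat across iterations.
    """
    if n < n_folds and scheme == "grouped-9fold":
        raise ValueError(f"need at least {n_folds} athletes for {n_folds} folds")
    rng = np.random.default_rng(seed)
    if scheme == "grouped-9fold":
        folds: list[list[int]] = [[] for _ in range(n_folds)]
        if labels is None:
            perm = rng.permutation(n)
            for k, idx in enumerate(np.array_split(perm, n_folds)):
                folds[k] = list(idx)
        else:
            labels = np.asarray(labels)
            for cls in pd.unique(labels):
                members = rng.permutation(np.flatnonzero(labels == cls))
                for idx in members:
                    smallest = min(range(n_folds), key=lambda k: len(folds[k]))
                    folds[smallest].append(int(idx))
        return [np.sort(np.array(f, dtype=int)) for f in folds]
    if scheme == "random-holdout":
        if n < 10:
            raise ValueError("random-holdout scheme needs at least 10 athletes")
        return [np.sort(rng.choice(n, size=9, replace=False)) for _ in range(n_folds)]
    raise ValueError(f"unknown scheme {scheme!r}")


@dataclass
class BenchResult:
    """Cross-validated metrics for every configured classifier."""

    entries: dict[str, dict]
    scheme: str
    seed: int | None
    n_athletes: int
    pooling: str = "pooled"

    def metric(self, variant: str, name: str) -> float:
        return self.entries[variant][name]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for variant, e in self.entries.items():
            rows.append(
                {"classifier": variant, "A": e["accuracy"], "F1": e["f1"],
                 "G": e["g"], "category": e["category"]}
            )
        return pd.DataFrame(rows).set_index("classifier")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "scheme": self.scheme,
            "seed": self.seed,
            "n_athletes": self.n_athletes,
            "pooling": self.pooling,
            "classifiers": self.entries,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _metrics_from_cm(cm: ConfusionMatrix) -> dict:
    g = g_index(cm)
    return {
        "confusion": {"tp": cm.tp, "tn": cm.tn, "fp": cm.fp, "fn": cm.fn},
        "accuracy": accuracy(cm),
        "f1": f1_score(cm),
        "g": g,
        "category": goodness_category(g),
    }


def run_bench(
    features: pd.DataFrame | np.ndarray,
    labels,
    configs: tuple[str, ...] = CLASSIFIER_IDS,
    scheme: str = "grouped-9fold",
    seed: int | None = None,
    pooling: str = "pooled",
    n_folds: int = 9,
) -> BenchResult:
    """Cross-validate the configured classifiers on a feature table.

    Per fold, features are standardized with training-fold mean/SD only and
    each classifier is fitted on the training athletes and evaluated on the
    held-out ones. With ``pooling="pooled"`` (default) confusion counts are
    summed across folds before computing the metrics; ``"per-fold"``
    averages per-fold metrics instead.
    """
    if isinstance(features, pd.DataFrame):
        X = features[FEATURE_NAMES].to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    n = len(X)
    if len(y) != n:
        raise ValueError("features and labels must align")
    if np.isnan(X).any():
        raise ValueError("missing feature values")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2 or counts.min() < 2:
        raise ValueError("need at least 2 athletes in each of two classes")

    rng = np.random.default_rng(seed)
    folds = split_folds(n, scheme, rng.integers(2**31), labels=y, n_folds=n_folds)
    all_idx = np.arange(n)

    pooled = {v: np.zeros(4, dtype=int) for v in configs}  # tp, tn, fp, fn
    per_fold: dict[str, list[dict]] = {v: [] for v in configs}
    for test_idx in folds:
        train_idx = np.setdiff1d(all_idx, test_idx)
        if len(np.unique(y[train_idx])) < 2:
            raise ValueError(
                "a training fold contains a single class; use the stratified "
                "grouped-9fold scheme or rebalance the cohort"
            )
        scaler = StandardScaler().fit(X[train_idx])
        Xtr = scaler.transform(X[train_idx])
        Xte = scaler.transform(X[test_idx])
        ytr, yte = y[train_idx], y[test_idx]
        for variant in configs:
            clf = make_classifier(variant, random_state=int(rng.integers(2**31)))
            clf.fit(Xtr, ytr)
            pred = clf.predict(Xte)
            tp = int(np.sum((pred == POSITIVE) & (yte == POSITIVE)))
            tn = int(np.sum((pred != POSITIVE) & (yte != POSITIVE)))
            fp = int(np.sum((pred == POSITIVE) & (yte != POSITIVE)))
            fn = int(np.sum((pred != POSITIVE) & (yte == POSITIVE)))
            pooled[variant] += np.array([tp, tn, fp, fn])
            if pooling == "per-fold":
                per_fold[variant].append(
                    _metrics_from_cm(ConfusionMatrix(tp, tn, fp, fn))
                )

    entries = {}
    for variant in configs:
        cm = ConfusionMatrix(*map(int, pooled[variant]))
        entry = _metrics_from_cm(cm)
        if pooling == "per-fold":
            entry["accuracy"] = float(np.mean([m["accuracy"] for m in per_fold[variant]]))
            entry["f1"] = float(np.mean([m["f1"] for m in per_fold[variant]]))
            entry["g"] = float(np.mean([m["g"] for m in per_fold[variant]]))
            entry["category"] = goodness_category(entry["g"])
        entries[variant] = entry
    return BenchResult(entries, scheme, seed, n, pooling)
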