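"""Sensitivity classification from selected tensor features.

Five commonly used classifiers (naive Bayes, logistic regression, random
forest with 500 trees, RBF-kernel SVM, and 5-nearest-neighbours) are scored
under stratified 10-fold cross-validation, sweeping the number H of retained
discriminative features.  With 30 samples in three classes of 12/10/8 a
plain stratified split at exact class proportions is impossible, so folds
are built by dealing each class's shuffled samples round-robin across folds;
every sample appears in exactly one test fold.  Scaling for the SVM and kNN
is fitted inside each training fold only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "CLASSIFIER_IDS", "FeatureTable", "AccuracyCurve", "make_classifier",
    "stratified_folds", "crossval_accuracy", "accuracy_vs_H",
    "scatter_selected_features",
]

log = logging.getLogger(__name__)

CLASSIFIER_IDS = ("naive_bayes", "logistic", "random_forest", "svm", "knn")


@dataclass
class FeatureTable:
    """Per-complex feature vectors with class labels."""

    names: list[str]
    features: np.ndarray          # (M, H)
    labels: np.ndarray            # class label per sample

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2 or self.features.shape[0] != len(self.labels):
            raise ValueError("features must be (M, H) with one label per row")
        if not np.isfinite(self.features).all():
            raise ValueError("feature table contains missing/non-finite values")

    @property
    def H(self) -> int:
        return self.features.shape[1]

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            self.features, columns=[f"f{i + 1}" for i in range(self.H)]
        )
        df.insert(0, "name", self.names)
        df["label"] = self.labels
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path)
        fcols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
        return cls(
            names=df["name"].tolist(),
            features=df[fcols].to_numpy(),
            labels=df["label"].to_numpy(),
        )


def make_classifier(classifier_id: str, n_features: int, seed: int = 0):
    """Instantiate one of the five reference classifiers.

    SVM: RBF kernel, C=1, gamma=1/H on standardized features.  kNN: k=5 on
    standardized features.  Random forest: 500 trees, seeded from the global
    seed.  Other parameters stay at library defaults.
    """
    if classifier_id == "naive_bayes":
        return GaussianNB()
    if classifier_id == "logistic":
        return LogisticRegression(max_iter=2000)
    if classifier_id == "random_forest":
        return RandomForestClassifier(n_estimators=500, random_state=seed)
    if classifier_id == "svm":
        return make_pipeline(
            StandardScaler(), SVC(kernel="rbf", C=1.0, gamma=1.0 / n_features)
        )
    if classifier_id == "knn":
        return make_pipeline(StandardScaler(), KNeighborsClassifier(n_neighbors=5))
    raise ValueError(
        f"unknown classifier {classifier_id!r}; choose from {CLASSIFIER_IDS}"
    )


def stratified_folds(labels, k: int, seed: int) -> list[np.ndarray]:
    """Deterministic stratified folds tolerant of classes smaller than k.

    Each class's indices are shuffled with the seeded generator and dealt
    round-robin across the k folds, so fold sizes differ by at most one per
    class and every sample lands in exactly one test fold.  If k exceeds the
    number of samples the split degrades to leave-one-out with a warning.
    """
    labels = np.asarray(labels)
    M = len(labels)
    if k > M:
        log.warning("k=%d folds exceed %d samples; using leave-one-out", k, M)
        warnings.warn("falling back to leave-one-out cross-validation",
                      stacklevel=2)
        k = M
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    cursor = 0
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        for i in idx:
            folds[cursor % k].append(int(i))
            cursor += 1
    return [np.sort(np.asarray(f, dtype=int)) for f in folds if len(f)]


def crossval_accuracy(
    table: FeatureTable, classifier_id: str, k: int = 10, seed: int = 0
) -> float:
    """Mean fraction of correctly classified samples over one stratified
    k-fold pass.

    Deterministic for a fixed seed: fold assignment, the random-forest tree
    seed and all preprocessing derive from it, and scaling is fitted inside
    each training fold.
    """
    X, y = table.features, table.labels
    folds = stratified_folds(y, k, seed)
    correct = 0
    for test_idx in folds:
        train_mask = np.ones(len(y), dtype=bool)
        train_mask[test_idx] = False
        clf = make_classifier(classifier_id, n_features=table.H, seed=seed)
        clf.fit(X[train_mask], y[train_mask])
        correct += int(np.sum(clf.predict(X[test_idx]) == y[test_idx]))
    return correct / len(y)


@dataclass
class AccuracyCurve:
    """Mean CV accuracy per (H, classifier)."""

    H_values: list[int]
    classifiers: list[str]
    accuracy: np.ndarray          # (len(H_values), len(classifiers))
    seed: int
    folds: int = 10

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"H": h, "classifier": c, "accuracy": self.accuracy[i, j]}
            for i, h in enumerate(self.H_values)
            for j, c in enumerate(self.classifiers)
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def at(self, H: int, classifier: str) -> float:
        return float(
            self.accuracy[self.H_values.index(H), self.classifiers.index(classifier)]
        )


def accuracy_vs_H(
    projected,
    labels,
    names: list[str] | None = None,
    H_values=range(3, 21),
    classifiers=CLASSIFIER_IDS,
    k: int = 10,
    seed: int = 0,
) -> AccuracyCurve:
    """Cross-validated accuracy as a function of the number of kept features.

    One stratified k-fold pass is shared by every (H, classifier) cell.
    Within each fold the discriminability ranking is fitted on the training
    samples only — like the feature scaling, feature *selection* is
    preprocessing, and fitting it on all samples would leak label
    information into the test folds — and each H re-truncates that same
    per-fold ranking.
    """
    from .mpca import DiscriminantFeatureSelector

    projected = np.asarray(projected, dtype=float)
    labels = np.asarray(labels)
    names = names or [f"s{i}" for i in range(len(labels))]
    flat = projected.reshape(projected.shape[0], -1)
    H_values = list(H_values)
    if max(H_values) > flat.shape[1]:
        raise ValueError(
            f"H up to {max(H_values)} requested but only {flat.shape[1]} "
            "projected entries exist"
        )
    folds = stratified_folds(labels, k, seed)
    split: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    for test_idx in folds:
        train_mask = np.ones(len(labels), dtype=bool)
        train_mask[test_idx] = False
        sel = DiscriminantFeatureSelector().fit(
            projected[train_mask], labels[train_mask]
        )
        split.append((
            test_idx,
            sel.transform(flat[train_mask]),
            sel.transform(flat[test_idx]),
        ))
    acc = np.zeros((len(H_values), len(classifiers)))
    for i, h in enumerate(H_values):
        for j, cid in enumerate(classifiers):
            correct = 0
            for test_idx, train_feats, test_feats in split:
                train_mask = np.ones(len(labels), dtype=bool)
                train_mask[test_idx] = False
                clf = make_classifier(cid, n_features=h, seed=seed)
                clf.fit(train_feats[:, :h], labels[train_mask])
                correct += int(np.sum(
                    clf.predict(test_feats[:, :h]) == labels[test_idx]
                ))
            acc[i, j] = correct / len(labels)
    return AccuracyCurve(
        H_values=H_values, classifiers=list(classifiers), accuracy=acc,
        seed=seed, folds=k,
    )


def scatter_selected_features(
    table: FeatureTable, pair: tuple[int, int]
) -> dict[str, dict[str, np.ndarray]]:
    """2-D scatter data for one feature pair: per-class points and centroids.

    ``pair`` is 1-based (feature 1 = most discriminative).  Rendering is a
    thin layer over the returned arrays.
    """
    i, j = pair
    if i == j:
        raise ValueError("feature pair must name two distinct features")
    for idx in (i, j):
        if not (1 <= idx <= table.H):
            raise IndexError(f"feature index {idx} out of range 1..{table.H}")
    out: dict[str, dict[str, np.ndarray]] = {}
    for c in np.unique(table.labels):
        pts = table.features[table.labels == c][:, [i - 1, j - 1]]
        out[str(c)] = {"points": pts, "centroid": pts.mean(axis=0)}
    return out


def plot_scatter(table: FeatureTable, pair: tuple[int, int], path) -> None:
    """Render :func:`scatter_selected_features` to a PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = scatter_selected_features(table, pair)
    fig, ax = plt.subplots(figsize=(5, 4))
    colors = {"high": "tab:red", "moderate": "tab:green", "low": "tab:blue"}
    for k_, (cls, d) in enumerate(sorted(data.items())):
        color = colors.get(cls, f"C{k_}")
        ax.scatter(d["points"][:, 0], d["points"][:, 1], s=25, label=cls,
                   color=color, alpha=0.8)
        ax.scatter(*d["centroid"], marker="+", s=120, color=color)
    ax.set_xlabel(f"feature {pair[0]}")
    ax.set_ylabel(f"feature {pair[1]}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
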