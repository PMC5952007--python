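"""Feature selection and classification for the flashing-image design.

The single-trial feature table holds PAC values per (band pair, channel)
plus band relative powers.  Selection is unsupervised multi-cluster feature
selection (spectral embedding of a trial-similarity graph followed by an
L1 regression of each embedding coordinate on the features) or greedy
sequential forward selection; an attended/non-attended k-NN gate on the
alpha1 relative power filters trials before a linear one-vs-rest SVM
predicts the stimulus class.  All statistics (scaling, selection) are fit
on training data only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist, pdist
from sklearn.linear_model import Lars
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .core import ValidationError

__all__ = [
    "FeatureTable",
    "mcfs_select",
    "sequential_select",
    "knn_attend",
    "svm_train",
    "svm_predict",
    "SvmModel",
]


@dataclass
class FeatureTable:
    """Trials x features matrix with names, class labels and attend flags."""

    matrix: np.ndarray
    names: list[str]
    labels: np.ndarray
    attend: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, float)
        if self.matrix.ndim != 2:
            raise ValidationError("feature matrix must be 2-D (trials x features)")
        if len(self.names) != self.matrix.shape[1]:
            raise ValidationError("feature name count does not match matrix")
        if len(set(self.names)) != len(self.names):
            raise ValidationError("feature names must be unique")
        self.labels = np.asarray(self.labels)
        if self.labels.shape[0] != self.matrix.shape[0]:
            raise ValidationError("label count does not match trials")
        if self.attend is not None:
            self.attend = np.asarray(self.attend, bool)

    def subset(self, rows=None, cols=None) -> "FeatureTable":
        rows = slice(None) if rows is None else rows
        m = self.matrix[rows]
        labels = self.labels[rows]
        attend = self.attend[rows] if self.attend is not None else None
        if cols is not None:
            m = m[:, cols]
            names = [self.names[c] for c in np.atleast_1d(cols)]
        else:
            names = list(self.names)
        return FeatureTable(m, names, labels, attend)


# -- multi-cluster feature selection ----------------------------------------

def mcfs_select(
    features: FeatureTable,
    n_clusters: int,
    n_select: int,
    knn_k: int = 5,
    max_nonzero: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """Unsupervised multi-cluster feature selection.

    Builds a symmetric k-NN trial graph with heat-kernel weights (width =
    median pairwise distance), takes the ``n_clusters`` smallest nontrivial
    eigenvectors of the normalised graph Laplacian, regresses each
    eigenvector on the features with least-angle regression capped at
    ``max_nonzero`` coefficients, and scores each feature by its maximum
    |standardised coefficient| across eigenvectors.  Returns (indices,
    scores) of the top ``n_select`` features; ties break to the lower
    index.

    The trial graph uses the features as given, so it is scale-dependent:
    standardise first if the features are on incomparable scales.  The
    regression coefficients are computed on internally standardised
    features so that scores are comparable across features regardless.
    """
    x = features.matrix
    n, p = x.shape
    if n_select > p:
        raise ValidationError(f"n_select {n_select} > n_features {p}")
    if n < 10:
        raise ValidationError("need at least 10 trials for graph construction")
    xs = x
    d = cdist(xs, xs)
    med = np.median(pdist(xs))
    sigma = med if med > 0 else 1.0
    w = np.exp(-(d ** 2) / (2 * sigma ** 2))
    # symmetric kNN sparsification
    keep = np.zeros_like(w, dtype=bool)
    for i in range(n):
        nbr = np.argsort(d[i])[1:knn_k + 1]
        keep[i, nbr] = True
    keep = keep | keep.T
    w = np.where(keep, w, 0.0)
    np.fill_diagonal(w, 0.0)
    n_comp, _ = connected_components(w > 0, directed=False)
    if n_comp > n_clusters:
        raise ValidationError(
            f"trial graph has {n_comp} components > n_clusters {n_clusters}")
    deg = w.sum(axis=1)
    dinv = 1.0 / np.sqrt(np.maximum(deg, 1e-12))
    lap = np.eye(n) - (dinv[:, None] * w) * dinv[None, :]
    lap = (lap + lap.T) / 2
    evals, evecs = np.linalg.eigh(lap)
    y = evecs[:, 1:n_clusters + 1]  # skip the trivial constant eigenvector
    xr = StandardScaler().fit_transform(x)
    scores = np.zeros(p)
    cap = min(max_nonzero, p, n - 1)
    for k in range(y.shape[1]):
        reg = Lars(n_nonzero_coefs=cap)
        reg.fit(xr, y[:, k])
        scores = np.maximum(scores, np.abs(reg.coef_))
    # identical columns are collinear (the L1 path keeps only one of them):
    # share the max score within each duplicate group so ties are honest
    seen: dict[bytes, list[int]] = {}
    for j in range(p):
        seen.setdefault(xs[:, j].tobytes(), []).append(j)
    for cols in seen.values():
        if len(cols) > 1:
            scores[cols] = scores[cols].max()
    order = np.lexsort((np.arange(p), -scores))  # score desc, index asc on ties
    sel = order[:n_select]
    return sel, scores[sel]


def sequential_select(
    features: FeatureTable,
    n_select: int,
    min_gain: float = 0.001,
    cv: int = 5,
    seed: int = 0,
) -> list[int]:
    """Greedy forward feature selection maximising stratified 5-fold CV
    accuracy of a linear SVM; stops at ``n_select`` features or when the
    best addition improves CV accuracy by less than ``min_gain``."""
    labels = features.labels
    if len(np.unique(labels)) < 2:
        raise ValidationError("need at least 2 classes")
    if n_select == 0:
        return []
    x = features.matrix
    selected: list[int] = []
    best_acc = -np.inf
    while len(selected) < n_select:
        gains = []
        for j in range(x.shape[1]):
            if j in selected:
                continue
            cols = selected + [j]
            acc = _cv_accuracy(x[:, cols], labels, cv, seed)
            gains.append((acc, j))
        if not gains:
            break
        acc, j = max(gains, key=lambda g: (g[0], -g[1]))
        if selected and acc < best_acc + min_gain:
            break
        selected.append(j)
        best_acc = max(best_acc, acc)
    return selected


def _cv_accuracy(x, y, cv, seed) -> float:
    counts = np.unique(y, return_counts=True)[1]
    k = int(min(cv, counts.min()))
    if k < 2:
        raise ValidationError("too few trials per class for CV")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(x, y):
        clf = make_pipeline(StandardScaler(), LinearSVC(C=1.0, random_state=0))
        clf.fit(x[tr], y[tr])
        accs.append(np.mean(clf.predict(x[te]) == np.asarray(y)[te]))
    return float(np.mean(accs))


# -- attended / non-attended gate -------------------------------------------

def knn_attend(
    train_features: np.ndarray,
    train_attend: np.ndarray,
    test_features: np.ndarray,
    k: int = 5,
) -> np.ndarray:
    """k-NN majority vote on alpha1 relative power; True = attended.

    k must be odd (tie avoidance) and no larger than the training set.
    """
    train_features = np.asarray(train_features, float)
    test_features = np.asarray(test_features, float)
    if train_features.ndim == 1:
        train_features = train_features.reshape(-1, 1)
    if test_features.ndim == 1:
        test_features = test_features.reshape(-1, 1)
    if k % 2 == 0:
        raise ValidationError(f"k must be odd, got {k}")
    if k > train_features.shape[0]:
        raise ValidationError(
            f"k={k} exceeds n_train={train_features.shape[0]}")
    clf = KNeighborsClassifier(n_neighbors=k)
    clf.fit(train_features, np.asarray(train_attend, bool))
    return clf.predict(test_features).astype(bool)


# -- multi-class SVM ---------------------------------------------------------

@dataclass
class SvmModel:
    pipeline: object
    feature_names: list[str] = field(default_factory=list)


def svm_train(features: FeatureTable, c: float = 1.0) -> SvmModel:
    """Linear one-vs-rest SVM with internal standardisation (train stats)."""
    if len(np.unique(features.labels)) < 2:
        raise ValidationError("need at least 2 classes")
    pipe = make_pipeline(StandardScaler(), LinearSVC(C=c, random_state=0))
    pipe.fit(features.matrix, features.labels)
    return SvmModel(pipeline=pipe, feature_names=list(features.names))


def svm_predict(model: SvmModel, features: FeatureTable) -> np.ndarray:
    """Predict class labels; feature columns are aligned by name."""
    if features.names != model.feature_names:
        try:
            cols = [features.names.index(n) for n in model.feature_names]
        except ValueError as e:
            raise ValidationError(f"feature mismatch at predict: {e}") from None
        x = features.matrix[:, cols]
    else:
        x = features.matrix
    return model.pipeline.predict(x)
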