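"""Corrected-vs-uncorrected classification studies.

Three classifiers compare feature sets extracted from partial-volume corrected
and uncorrected images under a strictly paired design: per repetition, the
fold assignments and every hyperparameter are identical between the two arms,
so the error-rate difference isolates the effect of the correction.

* SVM — linear support-vector machine on HOG descriptors of axial slices.
* LDA — linear discriminant analysis on regional mean vectors.
* MSD — graph matched-subspace detection: each class's training subjects
  define a correlation network; a subject's region-mean vector is scored by
  the fraction of its energy captured by the span of the low-frequency graph
  Laplacian eigenvectors of each class, and assigned to the class capturing
  more energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.feature import hog as _skimage_hog
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .core import VolumetricImage
from .network import (
    ConnectivityMatrix,
    correlation_network,
    normalize_and_threshold,
    standardize_columns,
)
from .quantify import IntensityMatrix


@dataclass
class FeatureSet:
    """Subjects x features matrix plus labels and provenance."""

    matrix: np.ndarray
    labels: np.ndarray
    provenance: str = "uncorrected"  # or "corrected"
    descriptor: str = "region_means"  # or "hog", "graph_signal"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.matrix.ndim != 2:
            raise ValueError("feature matrix must be 2-D (subjects x features)")
        if len(self.labels) != len(self.matrix):
            raise ValueError("labels must align with feature rows")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("feature matrix contains non-finite values")


@dataclass
class GraphSubspace:
    """First k graph-Laplacian eigenvectors (ascending eigenvalue)."""

    laplacian: np.ndarray
    basis: np.ndarray  # (m, k), orthonormal columns
    k: int
    eigenvalues: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.basis.shape[1] != self.k:
            raise ValueError("basis must have k columns")
        gram = self.basis.T @ self.basis
        if not np.allclose(gram, np.eye(self.k), atol=1e-10):
            raise ValueError("subspace basis columns must be orthonormal")


@dataclass
class CVReport:
    """Paired repeated cross-validation outcome."""

    error_pre: np.ndarray  # per repetition
    error_post: np.ndarray
    folds: int
    repetitions: int
    seed: int
    roc_pre: tuple[np.ndarray, np.ndarray, float]  # (fpr, tpr, auc)
    roc_post: tuple[np.ndarray, np.ndarray, float]

    @property
    def differences(self) -> np.ndarray:
        """error_pre - error_post per repetition (positive favours correction)."""
        return self.error_pre - self.error_post


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------


def hog_features(
    volume: VolumetricImage,
    slice_indices: list[int] | None = None,
    n_slices: int = 9,
    orientations: int = 9,
    pixels_per_cell: tuple[int, int] = (8, 8),
    cells_per_block: tuple[int, int] = (2, 2),
) -> np.ndarray:
    """Concatenated 2-D HOG descriptors of axial slices.

    HOG is defined for 2-D images, so the volume is summarized by
    ``n_slices`` evenly spaced axial (last-axis) slices (or an explicit
    ``slice_indices`` list). A uniform volume yields an all-zero descriptor.
    """
    nz = volume.shape[2]
    if slice_indices is None:
        slice_indices = np.linspace(0, nz - 1, n_slices).round().astype(int).tolist()
    feats = []
    for idx in slice_indices:
        if not 0 <= idx < nz:
            raise ValueError(f"slice index {idx} out of range [0, {nz})")
        feats.append(
            _skimage_hog(
                volume.values[:, :, idx],
                orientations=orientations,
                pixels_per_cell=pixels_per_cell,
                cells_per_block=cells_per_block,
                block_norm="L2-Hys",
                feature_vector=True,
            )
        )
    return np.concatenate(feats)


# ---------------------------------------------------------------------------
# Matched subspace detection
# ---------------------------------------------------------------------------


def graph_laplacian(weights: np.ndarray) -> np.ndarray:
    """Combinatorial Laplacian L = D - W of a symmetric weight matrix."""
    W = np.asarray(weights, dtype=float)
    return np.diag(W.sum(axis=1)) - W


def build_graph_subspace(weights: np.ndarray, k: int) -> GraphSubspace:
    """Span of the k lowest-frequency Laplacian eigenvectors."""
    L = graph_laplacian(weights)
    if not 1 <= k <= len(L):
        raise ValueError(f"k must lie in [1, {len(L)}]")
    eigvals, eigvecs = np.linalg.eigh(L)
    return GraphSubspace(
        laplacian=L, basis=eigvecs[:, :k], k=k, eigenvalues=eigvals[:k]
    )


def msd_statistic(signal: np.ndarray, subspace: GraphSubspace) -> float:
    """Energy fraction ||U_k U_k^T x||^2 / ||x||^2 in [0, 1]."""
    x = np.asarray(signal, dtype=float).ravel()
    if len(x) != subspace.basis.shape[0]:
        raise ValueError("signal length must match the subspace dimension")
    energy = float(x @ x)
    if energy == 0:
        raise ValueError("zero signal has no defined subspace energy fraction")
    proj = subspace.basis @ (subspace.basis.T @ x)
    return float(proj @ proj) / energy


class MatchedSubspaceClassifier:
    """Two-class MSD on graph signals (subjects' region-mean vectors).

    Per class, the training subjects' region x subject matrix yields a
    thresholded correlation network; the class subspace is anchored on the
    class's mean training profile and extended with the network Laplacian's
    low-frequency eigenvectors (ascending eigenvalue, ties — e.g. the
    degenerate null space of a disconnected graph — broken by descending
    training-signal energy), Gram-Schmidt orthonormalized. The dimension ``k``
    is the smallest capturing ``energy`` of the class's training-signal
    energy, capped at m/4. The mean anchor matters: projection energy is
    sign-blind, so without it two classes differing mainly in their mean
    profiles would span indistinguishable subspaces.
    """

    def __init__(self, threshold_p: float = 0.1, energy: float = 0.9):
        self.threshold_p = threshold_p
        self.energy = energy
        self.subspaces_: dict[int, GraphSubspace] = {}
        self.classes_: np.ndarray | None = None

    def _class_subspace(self, X: np.ndarray) -> GraphSubspace:
        m = X.shape[1]
        intensity = IntensityMatrix(
            values=X.T,
            region_labels=np.arange(1, m + 1),
            subject_ids=[f"s{i}" for i in range(len(X))],
        )
        net = normalize_and_threshold(
            standardize_columns(correlation_network(intensity)), self.threshold_p
        )
        L = graph_laplacian(net.weights)
        eigvals, eigvecs = np.linalg.eigh(L)
        coeffs = X @ eigvecs
        power = (coeffs**2).sum(axis=0)
        order = np.lexsort((-power, np.round(eigvals, 9)))
        eigvals, eigvecs = eigvals[order], eigvecs[:, order]

        candidates = [X.mean(axis=0)] + [eigvecs[:, i] for i in range(m)]
        total = float((X**2).sum())
        cap = max(1, m // 4)
        basis: list[np.ndarray] = []
        captured = 0.0
        for vec in candidates:
            v = vec.astype(float).copy()
            for b in basis:
                v -= (b @ v) * b
            norm = np.linalg.norm(v)
            if norm < 1e-10:
                continue
            v /= norm
            basis.append(v)
            captured += float(((X @ v) ** 2).sum())
            if captured >= self.energy * total or len(basis) >= cap:
                break
        U = np.column_stack(basis)
        return GraphSubspace(laplacian=L, basis=U, k=U.shape[1], eigenvalues=None)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MatchedSubspaceClassifier":
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("MatchedSubspaceClassifier is two-class")
        X = np.asarray(X, dtype=float)
        self.subspaces_ = {
            int(c): self._class_subspace(X[y == c]) for c in self.classes_
        }
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        lo, hi = (int(c) for c in self.classes_)
        return np.array(
            [
                msd_statistic(x, self.subspaces_[hi])
                - msd_statistic(x, self.subspaces_[lo])
                for x in np.asarray(X, dtype=float)
            ]
        )

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.decision_function(X)
        lo, hi = self.classes_
        return np.where(scores > 0, hi, lo)


# ---------------------------------------------------------------------------
# Paired repeated cross-validation
# ---------------------------------------------------------------------------


def _make_classifier(name: str):
    if name == "svm":
        return SVC(kernel="linear", C=1.0)
    if name == "lda":
        return LinearDiscriminantAnalysis()
    if name == "msd":
        return MatchedSubspaceClassifier()
    raise ValueError(f"unknown classifier {name!r}; expected svm, lda or msd")


def repeated_kfold(
    features_pre: FeatureSet,
    features_post: FeatureSet,
    classifier: str = "svm",
    folds: int = 10,
    repetitions: int = 200,
    seed: int = 0,
) -> CVReport:
    """Stratified k-fold CV repeated with identical folds for both arms.

    Stratification guarantees both classes in every training fold. Decision
    scores of held-out subjects are pooled across folds and repetitions for
    the ROC curves; per-repetition error rates are pooled over folds.
    """
    if not np.array_equal(features_pre.labels, features_post.labels):
        raise ValueError("pre and post feature sets must share subjects and labels")
    y = features_pre.labels
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("classification study is two-class")
    y01 = (y == classes[1]).astype(int)

    err = {"pre": [], "post": []}
    pooled_scores = {"pre": [], "post": []}
    pooled_labels = []
    for rep in range(repetitions):
        rep_seed = (seed + 104729 * rep) % (2**31 - 1)
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rep_seed)
        splits = list(skf.split(features_pre.matrix, y01))
        for arm, feats in (("pre", features_pre), ("post", features_post)):
            wrong = 0
            total = 0
            for train, test in splits:
                if len(np.unique(y01[train])) < 2:
                    raise RuntimeError("single-class training fold despite stratification")
                clf = _make_classifier(classifier)
                clf.fit(feats.matrix[train], y01[train])
                pred = clf.predict(feats.matrix[test])
                wrong += int(np.sum(pred != y01[test]))
                total += len(test)
                pooled_scores[arm].append(clf.decision_function(feats.matrix[test]))
                if arm == "pre":
                    pooled_labels.append(y01[test])
            err[arm].append(wrong / total)

    labels_all = np.concatenate(pooled_labels)
    roc = {}
    for arm in ("pre", "post"):
        scores_all = np.concatenate(pooled_scores[arm])
        roc[arm] = roc_points(scores_all, labels_all)
    return CVReport(
        error_pre=np.array(err["pre"]),
        error_post=np.array(err["post"]),
        folds=folds,
        repetitions=repetitions,
        seed=seed,
        roc_pre=roc["pre"],
        roc_post=roc["post"],
    )


def roc_points(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC step curve (false-alarm probability vs detection rate) and its area."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = _sk_roc_curve(labels, scores)
    area = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, area
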