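"""Gesture-model enumeration, classifiers, and grouped cross-validation.

A *gesture model* is a subset of the seven gesture labels that always
contains rest; models of size r = 4..7 enumerate C(6, r-1) label
combinations (20, 15, 6, 1). Classification uses one of three standard
supervised learners — SVM (RBF), LDA, k-NN (k = 5) — always preceded by
standardization fitted on the training data, optionally followed by PCA.

The cross-validation protocol is repeated subject-grouped hold-out: each
iteration holds out ``test_subjects`` whole subjects (all their segments)
and trains on the rest, so no subject contributes to both sides of a
split. ``folds x iterations`` random partitions are drawn from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import confusion_matrix
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .synth import GESTURES

NON_REST = tuple(g for g in GESTURES if g != "rest")


@dataclass(frozen=True)
class GestureModel:
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if "rest" not in self.labels:
            raise ValueError("every gesture model must contain 'rest'")
        if len(self.labels) not in (4, 5, 6, 7):
            raise ValueError("model size must be 4..7")

    @property
    def r(self) -> int:
        return len(self.labels)


def enumerate_models(r: int) -> list[GestureModel]:
    """All size-r gesture subsets containing rest, lexicographic order."""
    if r not in (4, 5, 6, 7):
        raise ValueError("r must be in {4, 5, 6, 7}")
    return [
        GestureModel(labels=("rest",) + combo)
        for combo in combinations(sorted(NON_REST), r - 1)
    ]


@dataclass(frozen=True)
class ClassifierSpec:
    kind: str  # svm | lda | knn
    params: dict = field(default_factory=dict)

    def build(self, seed: int | None = None):
        if self.kind == "svm":
            return SVC(
                kernel=self.params.get("kernel", "rbf"),
                C=self.params.get("C", 1.0),
                gamma=self.params.get("gamma", "scale"),
                random_state=seed,
            )
        if self.kind == "lda":
            return LinearDiscriminantAnalysis()
        if self.kind == "knn":
            return KNeighborsClassifier(n_neighbors=self.params.get("k", 5))
        raise ValueError(f"unknown classifier kind {self.kind!r}")


def _as_spec(spec) -> ClassifierSpec:
    return ClassifierSpec(kind=spec) if isinstance(spec, str) else spec


def train_predict(
    classifier_spec,
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    seed: int = 0,
    n_components: int | None = None,
) -> np.ndarray:
    """Fit one classifier (standardize [+ PCA] + learner) and predict.

    Deterministic given the seed; errors on single-class training sets.
    """
    train_y = np.asarray(train_y)
    classes, counts = np.unique(train_y, return_counts=True)
    if classes.size < 2:
        raise ValueError("training set has a single class")
    if counts.min() < 2:
        raise ValueError("every training class needs >= 2 samples")
    spec = _as_spec(classifier_spec)
    steps = [("scale", StandardScaler())]
    if n_components is not None:
        k = min(n_components, train_X.shape[1], train_X.shape[0] - 1)
        steps.append(("pca", PCA(n_components=k, svd_solver="full", random_state=seed)))
    steps.append(("clf", spec.build(seed)))
    pipe = Pipeline(steps)
    pipe.fit(np.asarray(train_X, float), train_y)
    return pipe.predict(np.asarray(test_X, float))


@dataclass(frozen=True)
class CVSpec:
    folds: int = 10
    iterations: int = 10
    test_subjects: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2 or self.iterations < 1 or self.test_subjects < 1:
            raise ValueError("invalid CVSpec")

    @property
    def n_partitions(self) -> int:
        return self.folds * self.iterations


def cross_validate(
    features: np.ndarray,
    labels: np.ndarray,
    groups: np.ndarray,
    model: GestureModel,
    classifier_spec,
    cv: CVSpec,
    n_components: int | None = None,
) -> list[np.ndarray]:
    """Repeated subject-grouped hold-out over one gesture model.

    Returns one confusion matrix per partition (rows = true label, in
    ``sorted(model.labels)`` order). Fully reproducible from ``cv.seed``;
    train and test subject sets never overlap.
    """
    labels = np.asarray(labels)
    groups = np.asarray(groups)
    mask = np.isin(labels, model.labels)
    X, y, g = np.asarray(features, float)[mask], labels[mask], groups[mask]
    present = set(np.unique(y))
    missing = [l for l in model.labels if l not in present]
    if missing:
        raise ValueError(f"model labels absent from data: {missing}")
    subjects = np.unique(g)
    if subjects.size < 4:
        raise ValueError("grouped CV needs at least 4 distinct subjects")
    order = sorted(model.labels)
    rng = np.random.default_rng(cv.seed)
    out = []
    for _ in range(cv.n_partitions):
        for _attempt in range(100):
            test_subj = rng.choice(subjects, size=cv.test_subjects, replace=False)
            te = np.isin(g, test_subj)
            tr = ~te
            tr_classes = np.unique(y[tr])
            if tr_classes.size == len(order) and te.any():
                break
        else:
            raise RuntimeError("could not draw a partition covering all labels")
        pred = train_predict(
            classifier_spec, X[tr], y[tr], X[te], seed=cv.seed, n_components=n_components
        )
        out.append(confusion_matrix(y[te], pred, labels=order))
    return out
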