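from itertools import combinations

import numpy as np
import pytest

from asfemg.classify import (
    ClassifierSpec,
    CVSpec,
    GestureModel,
    cross_validate,
    enumerate_models,
    train_predict,
)
from asfemg.synth import GESTURES


class TestEnumerateModels:
    @pytest.mark.parametrize("r,count", [(4, 20), (5, 15), (6, 6), (7, 1)])
    def test_printed_combination_counts(self, r, count):
        assert len(enumerate_models(r)) == count

    @pytest.mark.parametrize("r", [4, 5, 6, 7])
    def test_matches_bruteforce_subset_enumeration(self, r):
        non_rest = sorted(g for g in GESTURES if g != "rest")
        brute = {frozenset(("rest",) + c) for c in combinations(non_rest, r - 1)}
        got = {frozenset(m.labels) for m in enumerate_models(r)}
        assert got == brute

    def test_rest_always_present_and_order_deterministic(self):
        models = enumerate_models(5)
        assert all("rest" in m.labels for m in models)
        assert models == enumerate_models(5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            enumerate_models(3)
        with pytest.raises(ValueError):
            GestureModel(labels=("fist", "pinch", "thumb_up", "wrist_flexion"))


def _gaussian_classes(rng, n_per=100, dim=6, sep=10.0):
    Xa = rng.standard_normal((n_per, dim))
    Xb = rng.standard_normal((n_per, dim))
    Xb[:, 0] += sep
    X = np.vstack([Xa, Xb])
    y = np.array(["rest"] * n_per + ["fist"] * n_per)
    return X, y


class TestTrainPredict:
    @pytest.mark.parametrize("clf", ["svm", "lda", "knn"])
    def test_separated_gaussians_high_accuracy(self, clf, rng):
        X, y = _gaussian_classes(rng)
        Xte, yte = _gaussian_classes(rng, n_per=50)
        pred = train_predict(clf, X, y, Xte)
        assert np.mean(pred == yte) >= 0.99

    def test_knn_nearest_neighbor_identity(self, rng):
        X, y = _gaussian_classes(rng, n_per=20)
        pred = train_predict(ClassifierSpec("knn", {"k": 1}), X, y, X[:5])
        assert np.array_equal(pred, y[:5])

    def test_lda_chance_on_equal_means(self, rng):
        X = rng.standard_normal((400, 5))
        y = np.array(["rest", "fist"] * 200)
        Xte = rng.standard_normal((400, 5))
        yte = np.array(["rest", "fist"] * 200)
        acc = np.mean(train_predict("lda", X, y, Xte) == yte)
        assert 0.4 < acc < 0.6  # binomial CI around chance

    def test_single_class_rejected(self, rng):
        X = rng.standard_normal((10, 3))
        with pytest.raises(ValueError):
            train_predict("svm", X, np.array(["rest"] * 10), X)


def _grouped_data(rng, n_subjects=6, per_label=8, labels=("rest", "fist", "pinch", "thumb_up")):
    X, y, g = [], [], []
    for s in range(n_subjects):
        for li, lab in enumerate(labels):
            block = 0.3 * rng.standard_normal((per_label, 5))
            block[:, 0] += 6.0 * li
            X.append(block)
            y.extend([lab] * per_label)
            g.extend([f"subj{s}"] * per_label)
    return np.vstack(X), np.array(y), np.array(g)


class TestCrossValidate:
    def test_reproducible_from_seed(self, rng):
        X, y, g = _grouped_data(rng)
        model = GestureModel(labels=("rest", "fist", "pinch", "thumb_up"))
        cv = CVSpec(folds=2, iterations=3, test_subjects=2, seed=4)
        a = cross_validate(X, y, g, model, "svm", cv)
        b = cross_validate(X, y, g, model, "svm", cv)
        assert all(np.array_equal(m1, m2) for m1, m2 in zip(a, b))

    def test_confusion_counts_sum_to_test_segments(self, rng):
        X, y, g = _grouped_data(rng)
        model = GestureModel(labels=("rest", "fist", "pinch", "thumb_up"))
        cv = CVSpec(folds=2, iterations=2, test_subjects=2, seed=1)
        for m in cross_validate(X, y, g, model, "knn", cv):
            assert m.sum() == 2 * 4 * 8  # 2 test subjects x 4 labels x 8 segments

    def test_easy_instance_high_accuracy(self, rng):
        X, y, g = _grouped_data(rng)
        model = GestureModel(labels=("rest", "fist", "pinch", "thumb_up"))
        cv = CVSpec(folds=2, iterations=5, test_subjects=2, seed=2)
        mats = cross_validate(X, y, g, model, "svm", cv)
        acc = np.mean([np.trace(m) / m.sum() for m in mats])
        assert acc >= 0.95

    def test_missing_label_rejected(self, rng):
        X, y, g = _grouped_data(rng, labels=("rest", "fist", "pinch"))
        model = GestureModel(labels=("rest", "fist", "pinch", "thumb_up"))
        with pytest.raises(ValueError, match="thumb_up"):
            cross_validate(X, y, g, model, "svm", CVSpec(seed=0))

    def test_too_few_subjects_rejected(self, rng):
        X, y, g = _grouped_data(rng, n_subjects=3)
        model = GestureModel(labels=("rest", "fist", "pinch", "thumb_up"))
        with pytest.raises(ValueError, match="subjects"):
            cross_validate(X, y, g, model, "svm", CVSpec(seed=0))

    def test_label_permutation_drives_accuracy_to_chance(self, rng):
        X, y, g = _grouped_data(rng, n_subjects=8, per_label=10)
        # permute labels within each subject: destroys the signal while
        # preserving the grouped structure
        y_perm = y.copy()
        for s in np.unique(g):
            mask = g == s
            y_perm[mask] = rng.permutation(y_perm[mask])
        model = GestureModel(labels=("rest", "fist", "pinch", "thumb_up"))
        cv = CVSpec(folds=2, iterations=10, test_subjects=2, seed=6)
        mats = cross_validate(X, y_perm, g, model, "svm", cv)
        acc = np.mean([np.trace(m) / m.sum() for m in mats])
        assert abs(acc - 0.25) < 0.12
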