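"""RBF-SVM training/tuning/CV and diagnostic metric computation."""

import itertools
import math

import numpy as np
import pytest

from msiclassify.model import (
    SVMConfig,
    TrainedClassifier,
    compute_metrics,
    cross_validate,
    predict,
    train_svm,
    tune_svm,
)
from msiclassify.synthetic import generate_worked_example


def two_clusters(rng, n=20, sep=5.0, radius=0.5):
    half = n // 2
    X = np.vstack(
        [
            rng.normal(0, radius, size=(half, 2)) + sep,
            rng.normal(0, radius, size=(half, 2)) - sep,
        ]
    )
    y = np.array(["Ben"] * half + ["PTC"] * half)
    return X, y


class TestTrainSvm:
    def test_separable_clusters_fit_perfectly(self, rng):
        X, y = two_clusters(rng)
        clf = train_svm(X, y, SVMConfig())
        labels, d = clf.predict_labels(X)
        assert (labels == y).all()
        assert np.all(d[y == "Ben"] > 0) and np.all(d[y == "PTC"] < 0)

    def test_rbf_separates_xor(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
        y = np.array(["Ben", "Ben", "PTC", "PTC"])
        clf = train_svm(X, y, SVMConfig(cost=10.0, gamma=1.0))
        labels, _ = clf.predict_labels(X)
        assert (labels == y).all()

    def test_decision_matches_reference_solver(self, rng):
        """Manual kernel expansion equals sklearn's decision_function."""
        from sklearn.svm import SVC

        X, y = two_clusters(rng, n=30, sep=2.0, radius=1.0)
        cfg = SVMConfig(cost=10.0, gamma=0.11)
        clf = train_svm(X, y, cfg)
        center, scale = X.mean(0), X.std(0)
        ref = SVC(kernel="rbf", C=10.0, gamma=0.11).fit((X - center) / scale, y)
        # sklearn orients towards classes_[1]="PTC"; ours is benign-positive
        np.testing.assert_allclose(
            clf.decision_values(X),
            -ref.decision_function((X - center) / scale),
            atol=1e-8,
        )

    def test_duplicating_training_points_keeps_decisions(self, rng):
        X, y = two_clusters(rng, n=16, sep=5.0, radius=0.3)
        cfg = SVMConfig(cost=10.0, gamma=0.5)
        base = train_svm(X, y, cfg)
        doubled = train_svm(np.vstack([X, X]), np.concatenate([y, y]), cfg)
        np.testing.assert_allclose(
            base.decision_values(X), doubled.decision_values(X), atol=1e-8
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            train_svm(np.ones((4, 2)), ["Ben"] * 4)

    def test_symmetric_point_sits_on_boundary(self):
        X = np.array([[1.0, 0.0], [-1.0, 0.0]])
        y = np.array(["Ben", "PTC"])
        clf = train_svm(X, y, SVMConfig(cost=10.0, gamma=0.3))
        d = clf.decision_values(np.array([[0.0, 0.0]]))
        assert abs(d[0]) < 1e-9

    def test_json_round_trip(self, tmp_path, rng):
        X, y = two_clusters(rng)
        clf = train_svm(X, y, SVMConfig(), selected_mz=np.array([8000.0, 9000.0]),
                        provenance={"tolerance_ppm": 2000.0})
        path = tmp_path / "model.json"
        clf.to_json(path)
        back = TrainedClassifier.from_json(path)
        np.testing.assert_allclose(
            back.decision_values(X), clf.decision_values(X), atol=1e-12
        )
        assert back.provenance["tolerance_ppm"] == 2000.0

    def test_dimension_mismatch_names_features(self, rng):
        X, y = two_clusters(rng)
        clf = train_svm(X, y, selected_mz=np.array([8000.0, 9000.0]))
        with pytest.raises(ValueError, match="8000"):
            predict(clf, np.ones((1, 3)))


class TestTuneSvm:
    def test_single_point_grid(self, rng):
        X, y = two_clusters(rng)
        cfg = tune_svm(X, y, grid=[(10.0, 0.11)], k=5, repeats=1, seed=0)
        assert (cfg.cost, cfg.gamma) == (10.0, 0.11)

    def test_deterministic_for_fixed_seed(self, rng):
        X, y = two_clusters(rng, n=24)
        grid = [(10.0, 0.11), (10.0, 1.11)]
        a = tune_svm(X, y, grid=grid, k=4, repeats=2, seed=5)
        b = tune_svm(X, y, grid=grid, k=4, repeats=2, seed=5)
        assert (a.cost, a.gamma) == (b.cost, b.gamma)

    def test_ties_prefer_smaller_cost_then_gamma(self, rng):
        # perfectly separable: every grid point scores 1.0
        X, y = two_clusters(rng, n=20, sep=8.0, radius=0.1)
        grid = [(10.0, 0.11), (0.1, 0.11), (0.1, 0.01), (100.0, 1.11)]
        cfg = tune_svm(X, y, grid=grid, k=5, repeats=1, seed=0)
        assert (cfg.cost, cfg.gamma) == (0.1, 0.01)


class TestCrossValidate:
    def test_separable_data_scores_one(self, rng):
        X, y = two_clusters(rng, n=30, sep=6.0, radius=0.3)
        report = cross_validate(X, y, SVMConfig(), k=5, repeats=2, seed=1)
        assert report.accuracy == 1.0

    def test_fixed_seed_reproducible(self, rng):
        X, y = two_clusters(rng, n=30, sep=1.0, radius=1.5)
        a = cross_validate(X, y, SVMConfig(), k=5, repeats=2, seed=9)
        b = cross_validate(X, y, SVMConfig(), k=5, repeats=2, seed=9)
        assert a.as_dict() == b.as_dict()
        np.testing.assert_array_equal(a.confusion, b.confusion)

    def test_permuted_labels_near_majority_rate(self, rng):
        X, _ = two_clusters(rng, n=20)
        accs = []
        for i in range(60):
            y = rng.permutation(["Ben"] * 10 + ["PTC"] * 10)
            rep = cross_validate(X, y, SVMConfig(), k=5, repeats=1, seed=i)
            accs.append(rep.accuracy)
        assert abs(np.mean(accs) - 0.5) < 0.1

    def test_leave_one_out_equals_explicit_enumeration(self, rng):
        """repeats=1, k=n reduces to leave-one-out on n=12."""
        X, y = two_clusters(rng, n=12, sep=1.5, radius=1.0)
        report = cross_validate(X, y, SVMConfig(cost=1.0, gamma=0.5),
                                k=12, repeats=1, seed=0)
        hits = 0
        for i in range(12):
            mask = np.ones(12, dtype=bool)
            mask[i] = False
            clf = train_svm(X[mask], y[mask], SVMConfig(cost=1.0, gamma=0.5))
            lab, _ = clf.predict_labels(X[i])
            hits += int(lab[0] == y[i])
        assert report.accuracy == pytest.approx(hits / 12)


class TestComputeMetrics:
    def test_published_validation_outcome(self):
        table = generate_worked_example()
        report = compute_metrics(table["predicted"], table["true"],
                                 positive_class="Ben")
        assert report.accuracy == pytest.approx(0.818, abs=5e-4)
        assert report.sensitivity == pytest.approx(0.750, abs=5e-4)
        assert report.specificity == pytest.approx(1.000, abs=5e-4)
        assert report.ppv == pytest.approx(1.000, abs=5e-4)
        assert report.npv == pytest.approx(0.600, abs=5e-4)
        assert report.auc == pytest.approx(0.875, abs=5e-4)

    def test_all_correct_is_all_ones(self):
        y = ["Ben", "PTC", "Ben"]
        r = compute_metrics(y, y)
        assert (r.accuracy, r.sensitivity, r.specificity, r.ppv, r.npv) == (
            1.0, 1.0, 1.0, 1.0, 1.0,
        )

    def test_all_benign_prediction_on_published_truth(self):
        truth = generate_worked_example()["true"]
        r = compute_metrics(["Ben"] * 11, truth)
        assert r.sensitivity == 1.0
        assert r.specificity == 0.0
        assert r.accuracy == pytest.approx(8 / 11)
        assert math.isnan(r.npv)  # no negative calls: NPV undefined, not 0

    def test_hard_label_auc_identity(self, rng):
        for _ in range(50):
            pred = rng.choice(["Ben", "PTC"], size=12)
            true = rng.choice(["Ben", "PTC"], size=12)
            if len(set(true)) < 2:
                continue
            r = compute_metrics(pred, true)
            assert r.auc == (r.sensitivity + r.specificity) / 2

    def test_agrees_with_sklearn_on_random_draws(self, rng):
        from sklearn.metrics import confusion_matrix, roc_auc_score

        for _ in range(1000):
            n = int(rng.integers(4, 20))
            pred = rng.choice(["Ben", "PTC"], size=n)
            true = rng.choice(["Ben", "PTC"], size=n)
            d = rng.normal(size=n)
            r = compute_metrics(pred, true, decision_values=d)
            cm = confusion_matrix(true, pred, labels=["Ben", "PTC"])
            tp, fn, fp, tn = cm[0, 0], cm[0, 1], cm[1, 0], cm[1, 1]
            np.testing.assert_array_equal(r.confusion, [[tp, fn], [fp, tn]])
            assert r.accuracy == pytest.approx((tp + tn) / n)
            if len(set(true)) == 2:
                assert r.auc == pytest.approx(
                    roc_auc_score((true == "Ben").astype(int), d)
                )

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="vocabulary"):
            compute_metrics(["Ben"], ["Malignant"])
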