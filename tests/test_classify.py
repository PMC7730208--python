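import numpy as np
import pytest

from nirsbci import FeatureMatrix, FisherLDA, loocv_accuracy


def _fm(task_rows, rest_rows, names=None):
    task_rows = np.atleast_2d(np.asarray(task_rows, dtype=float))
    rest_rows = np.atleast_2d(np.asarray(rest_rows, dtype=float))
    names = names or tuple(f"f{i}" for i in range(task_rows.shape[1]))
    return FeatureMatrix(
        np.vstack([task_rows, rest_rows]),
        names,
        ("task",) * task_rows.shape[0] + ("rest",) * rest_rows.shape[0],
    )


class TestFisherLDA:
    def test_identity_scatter_direction_is_mean_difference(self, rng):
        # classes with exactly unit within-class scatter around their means
        base = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]]) / np.sqrt(2)
        mu1, mu2 = np.array([3.0, 1.0]), np.array([0.0, 0.0])
        fm = _fm(base + mu1, base + mu2)
        res = FisherLDA(fm).fit()
        direction = res.projection / np.linalg.norm(res.projection)
        expected = (mu1 - mu2) / np.linalg.norm(mu1 - mu2)
        np.testing.assert_allclose(direction, expected, atol=1e-10)

    def test_1d_midpoint_threshold(self):
        fm = _fm([[-1.0], [0.0], [1.0]], [[9.0], [10.0], [11.0]])
        res = FisherLDA(fm).fit()
        # projected threshold corresponds to feature value 5
        assert res.threshold / res.projection[0] == pytest.approx(5.0)
        assert res.predict(fm.values) == ["task"] * 3 + ["rest"] * 3

    def test_exact_threshold_tie_goes_to_first_class(self):
        fm = _fm([[0.0], [2.0]], [[8.0], [10.0]])
        res = FisherLDA(fm).fit()
        assert res.predict(np.array([[5.0]])) == ["task"]

    def test_eig_and_closed_form_agree_in_direction(self, rng):
        for _ in range(10):
            fm = _fm(rng.normal(size=(10, 3)) + 2.0, rng.normal(size=(10, 3)))
            a = FisherLDA(fm).fit(method="closed_form").projection
            b = FisherLDA(fm).fit(method="eig").projection
            cos = abs(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))
            assert cos >= 1 - 1e-8

    def test_matches_sklearn_predictions(self, rng):
        sklearn = pytest.importorskip("sklearn.discriminant_analysis")
        X1 = rng.normal(size=(20, 3)) + [1.5, 0.0, 0.5]
        X2 = rng.normal(size=(20, 3))
        fm = _fm(X1, X2)
        res = FisherLDA(fm).fit()
        clf = sklearn.LinearDiscriminantAnalysis().fit(
            fm.values, list(fm.labels)
        )
        probe = rng.normal(size=(50, 3)) + 0.75
        ours = res.predict(probe)
        theirs = list(clf.predict(probe))
        agree = np.mean([o == t for o, t in zip(ours, theirs)])
        assert agree >= 0.95

    def test_one_class_rejected(self):
        fm = FeatureMatrix(np.zeros((4, 2)), ("a", "b"), ("t",) * 4)
        with pytest.raises(ValueError, match="2 classes"):
            FisherLDA(fm)

    def test_dimension_mismatch_rejected(self, rng):
        fm = _fm(rng.normal(size=(5, 3)), rng.normal(size=(5, 3)))
        res = FisherLDA(fm).fit()
        with pytest.raises(ValueError, match="dimension"):
            res.predict(np.zeros((2, 4)))

    def test_singular_scatter_ridge_recovery(self):
        # separable, zero within-class variance -> singular S_W
        fm = _fm([[0.0, 0.0]] * 3, [[1.0, 1.0]] * 3)
        res = FisherLDA(fm).fit()
        assert res.predict(fm.values) == ["task"] * 3 + ["rest"] * 3


class TestLOOCV:
    def test_separable_classes_perfect_accuracy(self, rng):
        task = rng.normal(0.0, 0.05, size=(20, 3)) + 10.0
        rest = rng.normal(0.0, 0.05, size=(20, 3))
        acc, folds = loocv_accuracy(_fm(task, rest))
        assert acc == 100.0
        assert len(folds) == 20

    def test_chance_level_under_label_shuffling(self, rng):
        accs = []
        for _ in range(200):
            rows = rng.normal(size=(20, 3))
            labels = np.array(["task"] * 10 + ["rest"] * 10)
            rng.shuffle(labels)
            order = np.argsort(labels != "task", kind="stable")
            fm = FeatureMatrix(rows[order], ("a", "b", "c"), tuple(labels[order]))
            accs.append(loocv_accuracy(fm)[0])
        assert np.mean(accs) == pytest.approx(50.0, abs=5.0)

    def test_two_trial_degenerate_enumeration(self, rng):
        fm = _fm(rng.normal(size=(2, 2)), rng.normal(size=(2, 2)))
        acc, folds = loocv_accuracy(fm)
        assert acc in {0.0, 25.0, 50.0, 75.0, 100.0}
        assert len(folds) == 2

    def test_unbalanced_rejected(self, rng):
        fm = _fm(rng.normal(size=(3, 2)), rng.normal(size=(4, 2)))
        with pytest.raises(ValueError, match="unbalanced"):
            loocv_accuracy(fm)

    def test_invariance_to_feature_permutation_and_affine(self, rng):
        task = rng.normal(size=(10, 3)) + 1.0
        rest = rng.normal(size=(10, 3))
        fm = _fm(task, rest)
        acc, _ = loocv_accuracy(fm)
        perm = [2, 0, 1]
        fm_p = FeatureMatrix(fm.values[:, perm], ("c", "a", "b"), fm.labels)
        assert loocv_accuracy(fm_p)[0] == acc
        fm_a = FeatureMatrix(2.5 * fm.values - 1.25, fm.feature_names, fm.labels)
        assert loocv_accuracy(fm_a)[0] == acc
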