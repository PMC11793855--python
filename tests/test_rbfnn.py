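"""RBF network: k-means centers, Gaussian activations, NLMS training."""

import itertools
import math

import numpy as np
import pytest
from sklearn.base import clone
from sklearn.exceptions import NotFittedError
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from neoperf.rbfnn import (
    RBFNetClassifier,
    kmeans_centers,
    nlms_train,
    rbf_activations,
    split_trials,
)


def brute_force_kmeans_objective(X, k):
    """Global k-means optimum by enumerating all assignments (tiny n only)."""
    n = len(X)
    best = math.inf
    for assign in itertools.product(range(k), repeat=n):
        obj = 0.0
        for j in range(k):
            pts = X[np.array(assign) == j]
            if len(pts):
                obj += float(((pts - pts.mean(axis=0)) ** 2).sum())
        best = min(best, obj)
    return best


class TestKMeans:
    def test_k_equals_n_returns_the_points(self, rng):
        X = rng.normal(size=(5, 3))
        centers = kmeans_centers(X, 5, rng)
        # every point is a center (in some order)
        for x in X:
            assert np.min(np.linalg.norm(centers - x, axis=1)) < 1e-12

    def test_two_separated_blobs(self, rng):
        X = np.array([[0.0, 0.0], [0.2, 0.0], [10.0, 10.0], [10.2, 10.0]])
        centers = kmeans_centers(X, 2, rng)
        expected = {(0.1, 0.0), (10.1, 10.0)}
        got = {tuple(np.round(c, 6)) for c in centers}
        assert got == expected

    @pytest.mark.parametrize("n,k,seed", [(6, 2, 0), (7, 3, 1), (8, 3, 2)])
    def test_matches_brute_force_optimum_on_tiny_instances(self, n, k, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 2))
        centers = kmeans_centers(X, k, np.random.default_rng(seed + 100))
        d2 = ((X[:, None, :] - centers[None]) ** 2).sum(-1)
        obj = float(d2.min(axis=1).sum())
        assert obj == pytest.approx(brute_force_kmeans_objective(X, k), rel=1e-9)

    def test_k_larger_than_n_pads_with_warning(self, rng):
        X = rng.normal(size=(3, 2))
        with pytest.warns(UserWarning, match="padding"):
            centers = kmeans_centers(X, 6, rng)
        assert centers.shape == (6, 2)


class TestActivations:
    def test_unit_at_center(self, rng):
        centers = rng.normal(size=(4, 3))
        phi = rbf_activations(centers[2], centers, sigma2=0.7)
        assert phi[2] == pytest.approx(1.0)

    def test_inverse_e_at_squared_distance_two_sigma2(self):
        sigma2 = 0.9
        centers = np.array([[0.0, 0.0]])
        x = np.array([math.sqrt(2 * sigma2), 0.0])
        phi = rbf_activations(x, centers, sigma2)
        assert phi[0] == pytest.approx(math.exp(-1.0))

    def test_matches_scalar_loop_oracle(self, rng):
        X = rng.normal(size=(6, 4))
        centers = rng.normal(size=(5, 4))
        sigma2 = 1.3
        phi = rbf_activations(X, centers, sigma2)
        for i in range(6):
            for k in range(5):
                d2 = sum((X[i, j] - centers[k, j]) ** 2 for j in range(4))
                assert phi[i, k] == pytest.approx(math.exp(-d2 / (2 * sigma2)))

    def test_monotone_decrease_with_distance(self):
        centers = np.array([[0.0]])
        phis = [rbf_activations(np.array([d]), centers, 1.0)[0] for d in (0.0, 0.5, 1.5, 3.0)]
        assert all(a > b for a, b in zip(phis, phis[1:]))

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError, match="dimension"):
            rbf_activations(rng.normal(size=3), rng.normal(size=(2, 4)), 1.0)


class TestNLMS:
    def test_single_point_interpolation(self, rng):
        X = np.array([[0.3, -0.2]])
        w, errs = nlms_train(X, np.array([1.0]), X.copy(), 1.0, epochs=300, rng=rng)
        y = rbf_activations(X, X, 1.0) @ w
        assert abs(y[0] - 1.0) < 1e-3
        assert errs[-1] < errs[0]

    def test_all_zero_targets_keep_zero_weights(self, rng):
        X = rng.normal(size=(10, 2))
        w, _ = nlms_train(X, np.zeros(10), X[:4], 1.0, epochs=20, rng=rng)
        assert np.array_equal(w, np.zeros(4))

    def test_non_binary_targets_rejected(self, rng):
        X = rng.normal(size=(4, 2))
        with pytest.raises(ValueError, match="binary"):
            nlms_train(X, np.array([0.0, 0.5, 1.0, 1.0]), X, 1.0, rng=rng)

    def test_interpolation_with_one_center_per_point(self, rng):
        """k = n distinct points drives the training error toward zero."""
        X = rng.normal(size=(8, 2)) * 3.0
        t = rng.integers(0, 2, size=8).astype(float)
        model = RBFNetClassifier(
            n_hidden=8, width=1.0, lms_epochs=2000, lms_step=0.5, random_state=0
        ).fit(X, t)
        assert model.training_error_[-1] < 1e-3


class TestClassifier:
    def blobs(self, rng, n=40, sep=6.0):
        X = np.vstack([
            rng.normal(0.0, 1.0, size=(n // 2, 2)),
            rng.normal(sep, 1.0, size=(n // 2, 2)),
        ])
        y = np.repeat([0, 1], n // 2)
        return X, y

    def test_separable_blobs_high_training_accuracy(self, rng):
        X, y = self.blobs(rng)
        model = RBFNetClassifier(n_hidden=8, random_state=1).fit(X, y)
        assert (model.predict(X) == y).mean() >= 0.95

    def test_zero_weights_give_zero_output(self, rng):
        X, y = self.blobs(rng, n=10)
        model = RBFNetClassifier(n_hidden=4, lms_epochs=1, random_state=0).fit(X, y)
        model.weights_ = np.zeros_like(model.weights_)
        assert np.allclose(model.decision_function(X), 0.0)
        # all outputs below threshold -> everything labelled good (class 0)
        assert np.all(model.predict(X) == model.classes_[0])

    def test_single_neuron_unit_weight_outputs_one_at_center(self):
        model = RBFNetClassifier(n_hidden=1)
        model.centers_ = np.array([[1.0, 2.0]])
        model.sigma2_ = 0.5
        model.weights_ = np.array([1.0])
        model.classes_ = np.array([0, 1])
        model.n_features_in_ = 2
        assert model.decision_function([[1.0, 2.0]])[0] == pytest.approx(1.0)

    def test_threshold_rule_with_poor_on_tie(self):
        model = RBFNetClassifier(n_hidden=1, threshold=0.5)
        model.centers_ = np.array([[0.0]])
        model.sigma2_ = 1.0
        model.classes_ = np.array(["good", "poor"])
        model.n_features_in_ = 1
        for w, expected in ((0.51, "poor"), (0.49, "good"), (0.5, "poor")):
            model.weights_ = np.array([w])
            assert model.predict([[0.0]])[0] == expected

    def test_unfitted_predict_raises(self):
        with pytest.raises(NotFittedError):
            RBFNetClassifier().predict([[0.0, 0.0]])

    def test_sklearn_protocol(self, rng):
        X, y = self.blobs(rng, n=20)
        est = RBFNetClassifier(n_hidden=4, lms_epochs=10, random_state=3)
        cloned = clone(est)
        assert cloned.get_params()["n_hidden"] == 4
        pipe = Pipeline([("scale", StandardScaler()), ("rbf", est)])
        pipe.fit(X, y)
        assert pipe.predict(X).shape == (20,)

    def test_fixed_seed_reproducible(self, rng):
        X, y = self.blobs(rng, n=30)
        a = RBFNetClassifier(n_hidden=6, random_state=7).fit(X, y)
        b = RBFNetClassifier(n_hidden=6, random_state=7).fit(X, y)
        assert np.array_equal(a.weights_, b.weights_)
        assert np.array_equal(a.centers_, b.centers_)

    def test_json_round_trip(self, rng):
        X, y = self.blobs(rng, n=16)
        model = RBFNetClassifier(n_hidden=4, lms_epochs=20, random_state=0).fit(X, y)
        clone_ = RBFNetClassifier.from_json(model.to_json())
        assert np.allclose(clone_.decision_function(X), model.decision_function(X))


class TestSplit:
    def make_cohort(self, n_subj=12, trials=6):
        subjects = np.repeat([f"s{i}" for i in range(2 * n_subj)], trials)
        labels = np.repeat(["good"] * n_subj + ["poor"] * n_subj, trials)
        return subjects, labels

    def test_subject_level_split_has_no_subject_overlap(self, rng):
        subjects, labels = self.make_cohort()
        tr, te = split_trials(subjects, labels, 35, 15, level="subject", rng=rng)
        assert len(tr) == 70 and len(te) == 30
        assert not set(subjects[tr]) & set(subjects[te])
        for cls in ("good", "poor"):
            assert (labels[tr] == cls).sum() == 35
            assert (labels[te] == cls).sum() == 15

    def test_trial_level_split_counts(self, rng):
        subjects, labels = self.make_cohort()
        tr, te = split_trials(subjects, labels, 30, 10, level="trial", rng=rng)
        assert len(tr) == 60 and len(te) == 20
        assert not set(tr) & set(te)

    def test_insufficient_trials_raise(self, rng):
        subjects, labels = self.make_cohort(n_subj=2)
        with pytest.raises(ValueError, match="not enough|has"):
            split_trials(subjects, labels, 35, 15, rng=rng)
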