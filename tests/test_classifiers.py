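import json

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from mammotex import KNN, MLP, LinearSVM, MLPConfig, make_classifier
from mammotex.classifiers import (
    mean_squared_error,
    model_from_dict,
    relative_error,
    sigmoid,
)


@pytest.fixture
def gaussian_clusters(rng):
    """Two well-separated 2-D Gaussian clusters, 100 points per class."""
    a = rng.normal(loc=(-2.0, -2.0), scale=0.4, size=(100, 2))
    b = rng.normal(loc=(2.0, 2.0), scale=0.4, size=(100, 2))
    X = np.vstack([a, b])
    y = np.r_[np.zeros(100), np.ones(100)].astype(int)
    return X, y


class TestErrorMeasures:
    def test_sigmoid_midpoint_and_range(self):
        assert sigmoid(np.array([0.0]))[0] == 0.5
        x = np.linspace(-30, 30, 101)  # saturates to exactly 0/1 beyond ~36
        s = sigmoid(x)
        assert (s > 0).all() and (s < 1).all()
        np.testing.assert_allclose(s + sigmoid(-x), 1.0, atol=1e-12)

    def test_relative_error_is_signed_mean(self, rng):
        assert relative_error(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 0.0
        assert mean_squared_error(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 1.0
        y = rng.random(30)
        t = rng.random(30)
        assert relative_error(y, t) == pytest.approx(sum(y - t) / 30, rel=1e-12)
        assert relative_error(t, t) == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            relative_error(np.array([]), np.array([]))


class TestMLP:
    def test_reaches_target_mse_on_separable_clusters(self, gaussian_clusters):
        X, y = gaussian_clusters
        model = MLP(MLPConfig(seed=0)).fit(X, y)
        assert model.final_mse_ < 1e-3
        assert model.n_iterations_ <= 2000
        assert (model.predict(X) == y).all()

    def test_outputs_are_sigmoid_scores(self, gaussian_clusters):
        X, y = gaussian_clusters
        model = MLP(MLPConfig(seed=0)).fit(X, y)
        s = model.decision_scores(X)
        assert (s > 0).all() and (s < 1).all()

    def test_deterministic_under_fixed_seed(self, gaussian_clusters):
        X, y = gaussian_clusters
        m1 = MLP(MLPConfig(seed=7)).fit(X, y)
        m2 = MLP(MLPConfig(seed=7)).fit(X, y)
        np.testing.assert_array_equal(m1.w1, m2.w1)
        np.testing.assert_array_equal(
            m1.decision_scores(X), m2.decision_scores(X)
        )
        m3 = MLP(MLPConfig(seed=8)).fit(X, y)
        assert not np.array_equal(m1.w1, m3.w1)

    def test_json_round_trip_preserves_scores(self, gaussian_clusters, tmp_path):
        X, y = gaussian_clusters
        model = MLP(MLPConfig(seed=0)).fit(X, y)
        path = tmp_path / "mlp.json"
        path.write_text(json.dumps(model.to_dict()))
        restored = model_from_dict(json.loads(path.read_text()))
        np.testing.assert_allclose(
            restored.decision_scores(X), model.decision_scores(X), atol=1e-12
        )

    def test_input_validation(self):
        model = MLP(MLPConfig(seed=0))
        with pytest.raises(ValueError):
            model.fit(np.zeros((4, 3)), np.array([0, 1, 2, 1]))  # non-binary
        with pytest.raises(ValueError):
            model.fit(np.zeros((4, 3)), np.array([0, 1]))  # length mismatch
        fitted = MLP(MLPConfig(seed=0)).fit(np.eye(4), np.array([0, 1, 0, 1]))
        with pytest.raises(ValueError):
            fitted.decision_scores(np.zeros((2, 7)))


class TestLinearSVM:
    def test_constant_model_scores_bias(self):
        model = LinearSVM()
        model.support_vectors_ = np.zeros((1, 3))
        model.dual_weights_ = np.zeros(1)
        model.bias_ = 1.0
        assert model.decision_scores(np.ones((2, 3))) == pytest.approx([1.0, 1.0])
        assert (model.predict(np.ones((2, 3))) == 1).all()

    def test_perfect_on_linearly_separable_toy(self, gaussian_clusters):
        X, y = gaussian_clusters
        model = LinearSVM().fit(X, y)
        assert (model.predict(X) == y).all()

    def test_dual_decision_matches_sklearn(self, gaussian_clusters):
        from sklearn.svm import SVC

        X, y = gaussian_clusters
        model = LinearSVM(C=1.0).fit(X, y)
        svc = SVC(kernel="linear", C=1.0).fit(X, y)
        np.testing.assert_allclose(
            model.decision_scores(X), svc.decision_function(X), atol=1e-9
        )

    def test_decision_is_affine_in_input(self, gaussian_clusters):
        X, y = gaussian_clusters
        model = LinearSVM().fit(X, y)
        model.bias_ = 0.0
        s1 = model.decision_scores(X)
        s2 = model.decision_scores(3.0 * X)
        np.testing.assert_allclose(s2, 3.0 * s1, rtol=1e-9)

    def test_json_round_trip(self, gaussian_clusters):
        X, y = gaussian_clusters
        model = LinearSVM().fit(X, y)
        restored = model_from_dict(model.to_dict())
        np.testing.assert_allclose(
            restored.decision_scores(X), model.decision_scores(X), atol=1e-12
        )


class TestKNN:
    def test_query_on_training_point_k1(self):
        X = np.array([[0.0, 0.0], [5.0, 5.0]])
        y = np.array([0, 1])
        model = KNN(k=1).fit(X, y)
        assert model.predict(X[1:2])[0] == 1
        assert model.vote_score(X[1:2])[0] == 1.0

    def test_majority_vote_score(self):
        X = np.array([[0.0], [0.1], [0.2], [10.0], [11.0]])
        y = np.array([1, 1, 0, 0, 0])
        model = KNN(k=3).fit(X, y)
        # query at 0: neighbors are the first three points, 2 of 3 class 1
        assert model.decision_scores(np.array([[0.0]]))[0] == pytest.approx(2 / 3)
        assert model.predict(np.array([[0.0]]))[0] == 1
        assert model.vote_score(np.array([[0.0]]))[0] == pytest.approx(2 / 3)

    def test_matches_exhaustive_sort_oracle(self, rng):
        X = rng.random((40, 2))
        y = rng.integers(0, 2, 40)
        q = rng.random((10, 2))
        model = KNN(k=5).fit(X, y)
        scores = model.decision_scores(q)
        d = cdist(q, X)
        for i in range(10):
            nearest = np.argsort(d[i], kind="stable")[:5]
            assert scores[i] == pytest.approx(y[nearest].mean())

    def test_vote_score_bounds_for_odd_k(self, rng):
        X = rng.random((30, 3))
        y = rng.integers(0, 2, 30)
        model = KNN(k=5).fit(X, y)
        v = model.vote_score(rng.random((20, 3)))
        assert (v > 0.5).all() and (v <= 1.0).all()

    def test_distance_ties_broken_by_training_order(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, 0.0], [0.0, -1.0]])
        y = np.array([1, 0, 0, 0])
        model = KNN(k=1).fit(X, y)
        # all four training points are equidistant from the origin
        assert model.predict(np.array([[0.0, 0.0]]))[0] == 1

    def test_validation(self):
        with pytest.raises(ValueError):
            KNN(k=3).fit(np.zeros((2, 2)), np.array([0, 1]))
        with pytest.raises(ValueError):
            KNN(k=1).fit(np.zeros((0, 2)), np.array([]))


class TestFactory:
    def test_all_three_separate_a_separable_set(self, gaussian_clusters):
        X, y = gaussian_clusters
        for name in ("mlp", "svm", "knn"):
            clf = make_classifier(name, seed=0)
            clf.fit(X, y)
            assert (clf.predict(X) == y).all(), name

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            make_classifier("forest")
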