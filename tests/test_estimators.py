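"""From-equation classifiers: hand-computed posteriors, KKT checks,
reference-implementation agreement."""

import numpy as np
import pytest

from sarsmon.estimators import (
    BinnedMultinomialNB,
    DecisionTableClassifier,
    GaussianNB,
    RidgeLogisticRegression,
    SMOClassifier,
    model_from_dict,
    model_to_dict,
)

ALL_MODELS = [
    GaussianNB,
    BinnedMultinomialNB,
    DecisionTableClassifier,
    RidgeLogisticRegression,
    SMOClassifier,
]


@pytest.fixture(scope="module")
def random_data():
    rng = np.random.default_rng(99)
    X = np.vstack([rng.normal(0, 1, (120, 3)), rng.normal(1.0, 1, (120, 3))])
    y = np.repeat([0, 1], 120)
    return X, y


class TestCommonContracts:
    @pytest.mark.parametrize("cls", ALL_MODELS)
    def test_predict_proba_rows_are_distributions(self, cls, random_data):
        X, y = random_data
        proba = cls().fit(X, y).predict_proba(X)
        assert proba.shape == (len(X), 2)
        assert np.all(proba >= 0)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    @pytest.mark.parametrize("cls", ALL_MODELS)
    def test_fit_is_deterministic(self, cls, random_data):
        X, y = random_data
        a = cls().fit(X, y).predict_proba(X[:20])
        b = cls().fit(X, y).predict_proba(X[:20])
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("cls", ALL_MODELS)
    def test_single_class_training_rejected(self, cls):
        X = np.zeros((5, 2))
        with pytest.raises(ValueError):
            cls().fit(X, np.ones(5))

    @pytest.mark.parametrize("cls", ALL_MODELS)
    def test_json_round_trip(self, cls, random_data):
        import json

        X, y = random_data
        model = cls().fit(X, y)
        blob = json.dumps(model_to_dict(model))
        clone = model_from_dict(json.loads(blob))
        np.testing.assert_allclose(
            model.predict_proba(X[:25]), clone.predict_proba(X[:25]), atol=1e-12
        )

    @pytest.mark.parametrize("cls", ALL_MODELS)
    def test_get_set_params(self, cls):
        est = cls()
        params = est.get_params()
        assert est.set_params(**params) is est
        with pytest.raises(ValueError):
            est.set_params(not_a_parameter=1)


class TestGaussianNB:
    def test_symmetric_toy_gives_half_half(self):
        X = np.array([[-1.0], [-1.2], [-0.8], [1.0], [1.2], [0.8]])
        y = np.array([0, 0, 0, 1, 1, 1])
        proba = GaussianNB().fit(X, y).predict_proba(np.array([[0.0]]))
        np.testing.assert_allclose(proba, [[0.5, 0.5]], atol=1e-9)

    def test_four_instance_hand_posterior(self):
        # class 0: x in {0, 2} -> mean 1, var 1; class 1: x in {3, 5} -> mean 4, var 1
        X = np.array([[0.0], [2.0], [3.0], [5.0]])
        y = np.array([0, 0, 1, 1])
        model = GaussianNB().fit(X, y)
        x = 2.0
        lik0 = np.exp(-((x - 1) ** 2) / 2) / np.sqrt(2 * np.pi)
        lik1 = np.exp(-((x - 4) ** 2) / 2) / np.sqrt(2 * np.pi)
        expected = 0.5 * lik0 / (0.5 * lik0 + 0.5 * lik1)
        proba = model.predict_proba(np.array([[x]]))
        assert proba[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_feature_survives_via_floor(self):
        X = np.array([[1.0, 0.0], [1.0, 1.0], [1.0, 10.0], [1.0, 11.0]])
        y = np.array([0, 0, 1, 1])
        proba = GaussianNB().fit(X, y).predict_proba(X)
        assert np.isfinite(proba).all()

    def test_agreement_with_reference_implementation(self, rng):
        from sklearn.naive_bayes import GaussianNB as SkGNB

        X = rng.normal(0, 1, (500, 5)) + rng.integers(0, 2, 500)[:, None] * 0.8
        y = (X[:, 0] + rng.normal(0, 1, 500) > 0.4).astype(int)
        if y.min() == y.max():
            pytest.skip("degenerate draw")
        ours = GaussianNB().fit(X, y).predict(X)
        theirs = SkGNB().fit(X, y).predict(X)
        assert np.mean(ours == theirs) >= 0.99


class TestBinnedMultinomialNB:
    def test_large_alpha_limit_approaches_priors(self, random_data):
        X, y = random_data
        proba = BinnedMultinomialNB(alpha=1e9).fit(X, y).predict_proba(X[:10])
        np.testing.assert_allclose(proba, 0.5, atol=1e-4)

    def test_two_bin_hand_count_posterior(self):
        # feature <=0.5 -> bin 0, >0.5 -> bin 1 with n_bins=2 on range [0,1]
        X = np.array([[0.0], [0.0], [1.0], [0.0], [1.0], [1.0]])
        y = np.array([0, 0, 0, 1, 1, 1])
        model = BinnedMultinomialNB(n_bins=2, alpha=1.0).fit(X, y)
        # bin 0 counts: class0 2, class1 1; smoothed: (2+1)/(3+2), (1+1)/(3+2)
        p0, p1 = 3 / 5, 2 / 5
        expected0 = 0.5 * p0 / (0.5 * p0 + 0.5 * p1)
        proba = model.predict_proba(np.array([[0.0]]))
        assert proba[0, 0] == pytest.approx(expected0, abs=1e-12)

    def test_unseen_bin_keeps_finite_probability(self):
        X = np.array([[0.0], [0.1], [0.9], [1.0]])
        y = np.array([0, 0, 1, 1])
        model = BinnedMultinomialNB(n_bins=4).fit(X, y)
        proba = model.predict_proba(np.array([[0.5]]))
        assert np.isfinite(proba).all() and (proba > 0).all()

    def test_constant_feature_is_uninformative(self):
        X = np.column_stack([np.array([0.0, 0.0, 1.0, 1.0]), np.full(4, 3.3)])
        y = np.array([0, 0, 1, 1])
        with_const = BinnedMultinomialNB(n_bins=3).fit(X, y).predict_proba(X)
        without = BinnedMultinomialNB(n_bins=3).fit(X[:, :1], y).predict_proba(X[:, :1])
        np.testing.assert_allclose(with_const, without, atol=1e-12)

    @pytest.mark.parametrize("kwargs", [{"n_bins": 1}, {"alpha": 0.0}])
    def test_invalid_hyperparameters_rejected(self, kwargs, random_data):
        X, y = random_data
        with pytest.raises(ValueError):
            BinnedMultinomialNB(**kwargs).fit(X, y)


class TestDecisionTable:
    def test_selects_perfect_feature_among_noise(self, rng):
        n = 200
        signal = rng.integers(0, 2, n).astype(float)
        noise = rng.normal(size=(n, 3))
        X = np.column_stack([noise[:, 0], signal, noise[:, 1:]])
        y = signal.astype(int)
        model = DecisionTableClassifier(n_bins=4, cv=5).fit(X, y)
        assert model.selected_features_ == [1]
        assert model.score(X, y) == 1.0

    def test_unseen_condition_falls_back_to_majority(self):
        X = np.array([[0.0], [0.1], [0.9], [1.0], [0.05]])
        y = np.array([0, 0, 1, 1, 0])
        model = DecisionTableClassifier(n_bins=10, cv=2).fit(X, y)
        assert model.predict(np.array([[0.5]]))[0] == model.global_majority_ == 0

    def test_memorizes_training_keys(self, rng):
        X = rng.integers(0, 3, (60, 2)).astype(float)
        y = (X[:, 0] > 1).astype(int)
        model = DecisionTableClassifier(n_bins=3, cv=3).fit(X, y)
        assert model.score(X, y) == 1.0

    def test_empty_selection_is_majority_classifier(self, rng):
        X = rng.normal(size=(80, 2))
        y = np.array([0] * 60 + [1] * 20)
        model = DecisionTableClassifier(n_bins=3, cv=4).fit(X, y)
        if not model.selected_features_:
            assert (model.predict(X) == 0).all()


class TestRidgeLogistic:
    def test_separable_data_keeps_finite_coefficients(self):
        X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        y = np.array([0, 0, 1, 1])
        model = RidgeLogisticRegression(ridge=1e-4).fit(X, y)
        assert np.isfinite(model.coef_).all() and np.isfinite(model.intercept_)

    def test_zero_coefficients_closed_form(self):
        # balanced data with a useless feature: P = sigmoid(b0) for everything
        X = np.zeros((10, 1))
        X[::2] = 0.0
        y = np.array([0, 1] * 5)
        model = RidgeLogisticRegression().fit(X, y)
        proba = model.predict_proba(np.array([[0.0]]))
        expected = 1 / (1 + np.exp(-model.intercept_))
        assert proba[0, 1] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.5, abs=1e-6)

    def test_recovers_generator_effect_directions(self):
        from sarsmon.benchmark import run_benchmark  # noqa: F401  (import guard)
        from sarsmon.cohort import CHANNELS, CohortConfig, Preprocessor, generate_cohort

        df = generate_cohort(
            CohortConfig(n_patients=300, records_per_patient=20, seed=5)
        )
        df = Preprocessor().fit_transform(df)
        X = df[list(CHANNELS)].to_numpy()
        y = df["label"].to_numpy()
        model = RidgeLogisticRegression().fit(X, y)
        coef = dict(zip(CHANNELS, model.coef_))
        assert coef["heart_rate"] > 0  # tachycardia raises distress odds
        assert coef["body_temp_f"] > 0
        assert coef["spo2"] < 0  # desaturation raises distress odds

    def test_agreement_with_reference_implementation(self, rng):
        from sklearn.linear_model import LogisticRegression as SkLR

        X = rng.normal(0, 1, (500, 4))
        y = (X @ np.array([1.0, -0.5, 0.3, 0.0]) + rng.normal(0, 1, 500) > 0).astype(int)
        ours = RidgeLogisticRegression(ridge=1e-6).fit(X, y).predict(X)
        theirs = SkLR(C=1e6, max_iter=2000).fit(X, y).predict(X)
        assert np.mean(ours == theirs) >= 0.99

    def test_non_convergence_sets_flag(self, random_data):
        X, y = random_data
        model = RidgeLogisticRegression(max_iter=1).fit(X, y)
        assert model.converged_ is False

    @pytest.mark.parametrize("kwargs", [{"ridge": -1.0}, {"max_iter": 0}])
    def test_invalid_hyperparameters_rejected(self, kwargs, random_data):
        X, y = random_data
        with pytest.raises(ValueError):
            RidgeLogisticRegression(**kwargs).fit(X, y)


class TestSMO:
    SEPARABLE_X = np.array([[0.0, 0.0], [0.0, 1.0], [2.0, 0.0], [2.0, 1.0]])
    SEPARABLE_Y = np.array([-1, -1, 1, 1])

    def test_separable_toy_kkt_feasible_and_exact(self):
        model = SMOClassifier(C=1.0).fit(self.SEPARABLE_X, self.SEPARABLE_Y)
        assert model.score(self.SEPARABLE_X, self.SEPARABLE_Y) == 1.0
        assert np.all(model.alpha_ >= -1e-12) and np.all(model.alpha_ <= 1.0 + 1e-12)
        y_signed = np.where(self.SEPARABLE_Y == 1, 1.0, -1.0)
        assert abs(np.sum(model.alpha_ * y_signed)) < 1e-6

    def test_no_kkt_violations_after_fit(self, random_data):
        X, y = random_data
        model = SMOClassifier(C=1.0, tol=1e-3).fit(X, y)
        yi = np.where(y == model.classes_[1], 1.0, -1.0)
        f = model._raw_decision(X)
        E = f - yi
        viol = ((yi * E < -model.tol) & (model.alpha_ < model.C - 1e-9)) | (
            (yi * E > model.tol) & (model.alpha_ > 1e-9)
        )
        assert viol.sum() == 0

    def test_xor_is_not_linearly_separable(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
        y = np.array([-1, -1, 1, 1])
        assert SMOClassifier(kernel="linear").fit(X, y).score(X, y) < 1.0

    def test_xor_separable_with_rbf(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
        y = np.array([-1, -1, 1, 1])
        assert SMOClassifier(kernel="rbf", gamma=2.0, C=10.0).fit(X, y).score(X, y) == 1.0

    def test_vanishing_c_collapses_alphas(self, random_data):
        X, y = random_data
        model = SMOClassifier(C=1e-8).fit(X, y)
        assert np.all(model.alpha_ <= 1e-8 + 1e-15)
        preds = model.predict(X)
        assert len(np.unique(preds)) <= 2

    def test_subsampling_is_deterministic_and_stratified(self, rng):
        X = rng.normal(size=(5000, 3))
        y = (X[:, 0] > 0.3).astype(int)
        m1 = SMOClassifier(max_samples=400, random_state=3).fit(X, y)
        m2 = SMOClassifier(max_samples=400, random_state=3).fit(X, y)
        np.testing.assert_array_equal(m1.alpha_, m2.alpha_)
        assert m1.alpha_.size == 400

    def test_invalid_c_rejected(self, random_data):
        X, y = random_data
        with pytest.raises(ValueError):
            SMOClassifier(C=0.0).fit(X, y)
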