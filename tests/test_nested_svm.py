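"""Feature ranking, the linear SVM, inner k-selection, and the nested CV."""

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import minimize
from sklearn.svm import SVC

import mrsidh as m
from mrsidh.errors import ClassBalanceError, DegenerateDataError, InvalidParameterError
from mrsidh.features import FeatureMatrix
from mrsidh.nested_svm import _inner_accuracies, _as_pm1

MUT, WT = m.IDHMUT, m.IDHWT


def _labels(n_mut, n_wt):
    return [MUT] * n_mut + [WT] * n_wt


def _gaussian_data(rng, n_mut, n_wt, p, informative=(), shift=3.0):
    """Noise features, with class-mean shifts on the given columns."""
    X = rng.normal(size=(n_mut + n_wt, p))
    for j in informative:
        X[:n_mut, j] += shift
    return X, _labels(n_mut, n_wt)


class TestRankFeatures:
    def test_strong_feature_ranked_first(self):
        rng = np.random.default_rng(0)
        X, labels = _gaussian_data(rng, 10, 10, 20, informative=(7,), shift=10.0)
        assert m.rank_features_ttest(X, labels)[0] == 7

    def test_constant_feature_ranked_last(self):
        rng = np.random.default_rng(1)
        X, labels = _gaussian_data(rng, 8, 8, 5)
        X[:, 2] = 4.2
        assert m.rank_features_ttest(X, labels)[-1] == 2

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(2)
        X, labels = _gaussian_data(rng, 9, 7, 12, informative=(3, 8))
        perm = rng.permutation(len(labels))
        a = m.rank_features_ttest(X, labels)
        b = m.rank_features_ttest(X[perm], [labels[i] for i in perm])
        assert np.array_equal(a, b)

    def test_matches_scipy_welch_statistic(self):
        # independent route: scipy's Welch t on each column
        rng = np.random.default_rng(3)
        X, labels = _gaussian_data(rng, 12, 9, 15, informative=(0, 4), shift=1.5)
        y = np.array(labels)
        t = stats.ttest_ind(X[y == MUT], X[y == WT], equal_var=False).statistic
        expected = np.argsort(-np.abs(t), kind="stable")
        assert np.array_equal(m.rank_features_ttest(X, labels), expected)

    def test_small_class_rejected(self):
        X = np.zeros((3, 2))
        with pytest.raises(ClassBalanceError):
            m.rank_features_ttest(X, [MUT, MUT, WT])


def _hinge_objective(params, X, y, cost):
    w, b = params[:-1], params[-1]
    margins = 1.0 - y * (X @ w + b)
    return 0.5 / cost * w @ w + np.maximum(0.0, margins).sum()


class TestTrainAndPredict:
    def test_separable_clouds(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(5, 0.3, (10, 2)), rng.normal(-5, 0.3, (10, 2))])
        labels = _labels(10, 10)
        model = m.train_linear_svm(X, [0, 1], labels=labels)
        preds = [m.predict(model, X[i])[0] for i in range(20)]
        assert preds == labels
        assert all(m.predict(model, X[i])[1] > 0 for i in range(10))

    def test_label_flip_negates_decisions(self):
        rng = np.random.default_rng(5)
        X, labels = _gaussian_data(rng, 8, 8, 3, informative=(0,), shift=2.0)
        flipped = [WT if l == MUT else MUT for l in labels]
        cfg = m.SVMConfig(tol=1e-8)  # tight solve so the symmetry is numerical
        ma = m.train_linear_svm(X, [0, 1, 2], cfg, labels=labels)
        mb = m.train_linear_svm(X, [0, 1, 2], cfg, labels=flipped)
        da = np.array([ma.decision_value(x) for x in X])
        db = np.array([mb.decision_value(x) for x in X])
        assert np.allclose(da, -db, atol=1e-6)

    def test_weights_match_bruteforce_hinge_minimum(self):
        # tiny 2-D toy set; oracle = direct minimization of the regularized
        # hinge objective over (w, b), refined from a coarse grid
        X = np.array([[-1.0, 0.0], [-2.0, 1.0], [1.0, 0.0], [2.0, -1.0]])
        y = np.array([-1.0, -1.0, 1.0, 1.0])
        labels = [WT, WT, MUT, MUT]
        cfg = m.SVMConfig(standardize=False, tol=1e-8)
        model = m.train_linear_svm(X, [0, 1], cfg, labels=labels)

        best = None
        for w1 in np.linspace(-3, 3, 25):
            for w2 in np.linspace(-3, 3, 25):
                for b in np.linspace(-2, 2, 17):
                    val = _hinge_objective(np.array([w1, w2, b]), X, y, 1.0)
                    if best is None or val < best[1]:
                        best = (np.array([w1, w2, b]), val)
        res = minimize(_hinge_objective, best[0], args=(X, y, 1.0),
                       method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
        w_oracle = res.x[:2]
        cos = (model.weights @ w_oracle) / (
            np.linalg.norm(model.weights) * np.linalg.norm(w_oracle)
        )
        assert cos > 0.999
        obj_model = _hinge_objective(np.r_[model.weights, model.bias], X, y, 1.0)
        assert obj_model <= res.fun + 1e-4

    def test_agrees_with_public_svc(self):
        # same solver through the estimator API
        rng = np.random.default_rng(6)
        for _ in range(5):
            X = rng.normal(size=(20, 4))
            labels = [MUT if v else WT for v in rng.random(20) < 0.5]
            if sum(l == MUT for l in labels) < 2 or sum(l == WT for l in labels) < 2:
                continue
            cfg = m.SVMConfig(standardize=False)
            model = m.train_linear_svm(X, [0, 1, 2, 3], cfg, labels=labels)
            y = _as_pm1(labels, MUT)
            svc = SVC(kernel="linear", C=1.0).fit(X, y)
            ours = np.array([model.decision_value(x) for x in X])
            assert np.allclose(ours, svc.decision_function(X), atol=1e-6)

    def test_midpoint_of_symmetric_clusters_scores_zero(self):
        X = np.array([[2.0], [2.1], [1.9], [-2.0], [-2.1], [-1.9]])
        labels = _labels(3, 3)
        model = m.train_linear_svm(X, [0], m.SVMConfig(standardize=False), labels=labels)
        assert abs(model.decision_value(np.array([0.0]))) < 1e-6

    def test_standardization_reproduces_training_decision(self):
        rng = np.random.default_rng(7)
        X, labels = _gaussian_data(rng, 6, 6, 4, informative=(1,), shift=2.0)
        X[:, 2] *= 100.0  # wildly different scales
        model = m.train_linear_svm(X, [0, 1, 2, 3], labels=labels)
        d_again = [m.predict(model, X[i])[1] for i in range(len(labels))]
        d_model = [model.decision_value(X[i]) for i in range(len(labels))]
        assert np.allclose(d_again, d_model)

    def test_missing_feature_rejected(self):
        rng = np.random.default_rng(8)
        X, labels = _gaussian_data(rng, 5, 5, 6, informative=(5,))
        model = m.train_linear_svm(X, [5], labels=labels)
        with pytest.raises(InvalidParameterError):
            model.decision_value(np.zeros(3))

    def test_identical_rows_rejected(self):
        X = np.ones((6, 2))
        with pytest.raises(DegenerateDataError):
            m.train_linear_svm(X, [0, 1], labels=_labels(3, 3))


class TestChooseK:
    def test_single_informative_feature_gives_k1(self):
        rng = np.random.default_rng(9)
        X, labels = _gaussian_data(rng, 8, 8, 10, informative=(4,), shift=8.0)
        assert m.choose_k_inner_cv(X, labels=labels) == 1

    def test_two_informative_features_concentrate_low(self):
        # neither feature separates alone; together they do
        ks = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            X, labels = _gaussian_data(rng, 10, 10, 30, informative=(2, 11), shift=1.4)
            ks.append(m.choose_k_inner_cv(X, labels=labels))
        assert 1 <= np.median(ks) <= 4

    def test_pure_noise_has_chance_level_inner_accuracy(self):
        rng = np.random.default_rng(10)
        X, labels = _gaussian_data(rng, 10, 10, 25)
        acc = _inner_accuracies(X, _as_pm1(labels, MUT), m.SVMConfig())
        assert 0.2 < acc.mean() < 0.7


def _matrix_from(X, labels):
    edges = [(4.5 - 0.01 * j, 4.49 - 0.01 * j) for j in range(X.shape[1])]
    return FeatureMatrix(X, edges, [f"s{i}" for i in range(len(labels))], labels,
                         stage="log2")


class TestNestedLoocv:
    def test_perfectly_separable_cohort(self):
        rng = np.random.default_rng(11)
        X, labels = _gaussian_data(rng, 17, 17, 40, informative=(3, 7), shift=8.0)
        cv = m.nested_loocv(_matrix_from(X, labels))
        assert cv.accuracy == 1.0

    def test_deterministic(self, default_matrix):
        a = m.nested_loocv(default_matrix)
        b = m.nested_loocv(default_matrix)
        assert np.array_equal(a.decision_values, b.decision_values)
        assert a.fold_k == b.fold_k
        assert a.predicted_labels == b.predicted_labels

    def test_class_count_precondition(self):
        rng = np.random.default_rng(12)
        X, labels = _gaussian_data(rng, 2, 8, 5)
        with pytest.raises(ClassBalanceError):
            m.nested_loocv(_matrix_from(X, labels))

    def test_unlabeled_samples_rejected(self):
        X = np.random.default_rng(13).normal(size=(8, 4))
        labels = [MUT] * 4 + [WT] * 3 + ["unknown"]
        with pytest.raises(InvalidParameterError):
            m.nested_loocv(_matrix_from(X, labels))

    def test_decision_sign_matches_prediction(self, default_matrix):
        cv = m.nested_loocv(default_matrix)
        for pred, d in zip(cv.predicted_labels, cv.decision_values):
            assert (pred == MUT) == (d >= 0)

    def test_leakage_freedom_quick(self):
        # the fold's model must not depend on the held-out row at all
        rng = np.random.default_rng(14)
        X, labels = _gaussian_data(rng, 6, 6, 15, informative=(1,), shift=2.0)
        for i in (0, 5, 11):
            model_a, k_a = m.outer_fold_model(X, labels, i)
            X2 = X.copy()
            X2[i] = 1e6 * rng.normal(size=X.shape[1])
            model_b, k_b = m.outer_fold_model(X2, labels, i)
            assert k_a == k_b
            assert np.array_equal(model_a.weights, model_b.weights)
            assert model_a.bias == model_b.bias
            assert np.array_equal(model_a.selected, model_b.selected)

    def test_accuracy_increases_with_effect_size(self):
        # scaled-down difficulty sweep: effect x noise grid on small cohorts
        mean_acc = []
        for strength in (0.0, 1.0, 2.5):
            accs = []
            for noise in (1.0, 3.0):
                basis = m.default_basis(effect_strength=strength)
                for rep in range(2):
                    cfg = m.SimulationConfig(n_mut=8, n_wt=7, seed=400 + rep,
                                             noise_sd=noise)
                    fm = m.preprocess_cohort(m.simulate_cohort(basis, cfg))
                    accs.append(m.nested_loocv(fm, m.SVMConfig(k_max=8)).accuracy)
            mean_acc.append(np.mean(accs))
        rho = stats.spearmanr([0, 1, 2], mean_acc).statistic
        assert rho > 0
        assert mean_acc[-1] > mean_acc[0]
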