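"""Diagonal-LDA classifier, LOO cross-validation, permutation null, t-tests."""

import logging

import numpy as np
import pytest
from scipy import stats as sps

from matdecode.classification import (DiagLinearClassifier,
                                      accuracy_vs_chance_ttest, loo_cv,
                                      permutation_null, zscore_fit_apply)
from matdecode.classification import _loo_diag_predict


def diag_gaussian_posteriors(X, means, var, priors):
    """Brute-force density-evaluation oracle (independent of the estimator)."""
    like = np.stack([
        np.prod(sps.norm.pdf(X, loc=means[c], scale=np.sqrt(var)), axis=1)
        * priors[c]
        for c in (0, 1)], axis=1)
    return like / like.sum(axis=1, keepdims=True)


class TestZscore:
    def test_training_columns_standardized(self):
        rng = np.random.default_rng(0)
        tr, te = rng.normal(2, 3, (10, 4)), rng.normal(2, 3, (3, 4))
        tz, vz, st = zscore_fit_apply(tr, te)
        assert np.allclose(tz.mean(0), 0, atol=1e-12)
        assert np.allclose(tz.std(0), 1, atol=1e-12)

    def test_test_row_equal_to_train_row_maps_identically(self):
        tr = np.random.default_rng(1).normal(size=(6, 3))
        tz, vz, _ = zscore_fit_apply(tr, tr[2:3])
        assert np.allclose(vz[0], tz[2])

    def test_constant_column_dropped_and_logged(self, caplog):
        tr = np.random.default_rng(2).normal(size=(6, 3))
        tr[:, 1] = 7.0
        with caplog.at_level(logging.WARNING):
            tz, _, st = zscore_fit_apply(tr, tr[:2])
        assert tz.shape[1] == 2
        assert st["kept"].tolist() == [True, False, True]
        assert "zero-variance" in caplog.text

    def test_all_constant_columns_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            zscore_fit_apply(np.ones((5, 2)), np.ones((1, 2)))


class TestDiagLinear:
    def test_symmetric_1d_boundary_at_zero(self):
        X = np.array([[-1.2], [-1.0], [-0.8], [0.8], [1.0], [1.2]])
        y = np.array([0, 0, 0, 1, 1, 1])
        clf = DiagLinearClassifier().fit(X, y)
        assert clf.predict([[-0.01]])[0] == 0
        assert clf.predict([[0.01]])[0] == 1
        # exactly on the boundary: tie broken toward first sorted class
        assert clf.predict([[0.0]])[0] == 0
        assert clf.predict_proba([[0.0]])[0] == pytest.approx([0.5, 0.5])

    def test_duplicating_observations_leaves_model_unchanged(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 4))
        y = np.repeat([0, 1], 6)
        a = DiagLinearClassifier().fit(X, y)
        b = DiagLinearClassifier().fit(np.vstack([X, X]), np.hstack([y, y]))
        assert np.allclose(a.theta_, b.theta_)
        # pooled variance denominators differ (n-2) but estimates converge;
        # means and priors are sufficient and identical
        assert np.allclose(a.priors_, b.priors_)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_posteriors_match_density_evaluation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(20, 3))
        y = np.repeat([0, 1], 10)
        X[y == 1] += 0.7
        clf = DiagLinearClassifier().fit(X, y)
        Xt = rng.normal(size=(50, 3))
        oracle = diag_gaussian_posteriors(Xt, clf.theta_, clf.var_,
                                          clf.priors_)
        assert np.allclose(clf.predict_proba(Xt), oracle, atol=1e-10)
        assert np.array_equal(clf.predict(Xt),
                              clf.classes_[oracle.argmax(axis=1)])

    def test_prediction_invariant_to_feature_order_and_affine_scale(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(16, 5))
        y = np.repeat([0, 1], 8)
        X[y == 1, 0] += 1.0
        Xt = rng.normal(size=(20, 5))
        base = DiagLinearClassifier().fit(*_std(X, y)).predict(_stdt(X, Xt))
        perm = np.array([3, 0, 4, 1, 2])
        p2 = DiagLinearClassifier().fit(
            *_std(X[:, perm], y)).predict(_stdt(X[:, perm], Xt[:, perm]))
        scale = X * np.array([2.0, 0.5, 10.0, 1.0, 3.0]) + 5.0
        st = DiagLinearClassifier().fit(*_std(scale, y)).predict(
            _stdt(scale, Xt * np.array([2.0, 0.5, 10.0, 1.0, 3.0]) + 5.0))
        assert np.array_equal(base, p2)
        assert np.array_equal(base, st)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            DiagLinearClassifier().fit(np.zeros((4, 2)), [1, 1, 1, 1])

    def test_dimension_mismatch_rejected(self):
        clf = DiagLinearClassifier().fit(np.random.default_rng(0).normal(
            size=(8, 3)), [0, 0, 0, 0, 1, 1, 1, 1])
        with pytest.raises(ValueError, match="features"):
            clf.predict(np.zeros((2, 5)))


def _std(X, y):
    tz, _, _ = zscore_fit_apply(X, X)
    return tz, y


def _stdt(X, Xt):
    _, vz, _ = zscore_fit_apply(X, Xt)
    return vz


class TestLooCv:
    def test_balanced_21_21_runs_42_folds(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(42, 5))
        y = np.repeat([0, 1], 21)
        assert loo_cv(X, y).n_folds == 42

    def test_distant_clusters_classified_perfectly(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(16, 3))
        X[8:] += 50.0
        y = np.repeat(["low", "high"], 8)
        assert loo_cv(X, y).accuracy == 1.0

    @pytest.mark.parametrize("zscore", ["fold", "global", "none"])
    def test_vectorized_path_equals_explicit_fold_loop(self, zscore):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(18, 6))
        X[:, 2] *= 40.0
        y = np.array([0, 1] * 9)
        X[y == 1, 0] += 1.0
        cv = loo_cv(X, y, zscore=zscore)
        preds, posts = [], []
        for i in range(len(y)):
            tr = np.delete(np.arange(len(y)), i)
            tz, vz, _ = zscore_fit_apply(X[tr], X[i:i + 1])
            clf = DiagLinearClassifier().fit(tz, y[tr])
            preds.append(clf.predict(vz)[0])
            posts.append(clf.predict_proba(vz)[0].max())
        assert np.array_equal(cv.predicted, np.array(preds))
        assert np.allclose(cv.posterior, posts, atol=1e-10)

    def test_accuracy_invariant_to_observation_order(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 4))
        y = np.repeat([0, 1], 10)
        X[y == 1] += 0.5
        perm = rng.permutation(20)
        assert loo_cv(X, y).accuracy == loo_cv(X[perm], y[perm]).accuracy

    def test_null_data_mean_accuracy_near_chance(self):
        # random labels on shared-distribution features: over 200 seeded
        # runs the mean LOO accuracy sits within 0.5 +/- 0.05
        accs = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(20, 5))
            y = rng.permutation(np.repeat([0, 1], 10))
            accs.append(loo_cv(X, y).accuracy)
        assert abs(np.mean(accs) - 0.5) < 0.05

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            loo_cv(np.zeros((3, 2)), [0, 0, 1])


class TestPermutationNull:
    def test_same_seed_reproduces_null_distribution(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(16, 4))
        y = np.repeat([0, 1], 8)
        a = permutation_null(X, y, n_perm=100, seed=7)
        b = permutation_null(X, y, n_perm=100, seed=7)
        assert np.array_equal(a.null_accuracies, b.null_accuracies)
        assert a.threshold == b.threshold

    def test_strong_signal_exceeds_threshold(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(16, 3))
        y = np.repeat([0, 1], 8)
        X[y == 1] += 10.0
        pn = permutation_null(X, y, n_perm=100, seed=0)
        assert loo_cv(X, y).accuracy > pn.threshold

    def test_type_one_error_rate_is_nominal(self):
        # null data: observed accuracy exceeds the 95% threshold in about 5%
        # of 200 seeded runs (binomial 95% acceptance band)
        hits = 0
        for seed in range(200):
            rng = np.random.default_rng(10_000 + seed)
            X = rng.normal(size=(16, 4))
            y = np.repeat([0, 1], 8)
            pn = permutation_null(X, y, n_perm=100, seed=seed)
            if loo_cv(X, y).accuracy > pn.threshold:
                hits += 1
        lo, hi = sps.binom.ppf([0.025, 0.975], 200, 0.05)
        assert lo <= hits <= hi

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ValueError, match="n_perm"):
            permutation_null(np.zeros((8, 2)), [0] * 4 + [1] * 4, n_perm=10)


class TestAccuracyTtest:
    def test_all_at_chance_gives_t0_p_half(self):
        t, p = accuracy_vs_chance_ttest([0.5, 0.5, 0.5])
        assert t == 0.0 and p == 0.5

    def test_symmetric_around_chance_gives_t0(self):
        t, _ = accuracy_vs_chance_ttest([0.4, 0.6, 0.45, 0.55])
        assert t == pytest.approx(0.0, abs=1e-12)

    def test_three_subject_closed_form(self):
        a = np.array([0.6, 0.7, 0.65])
        t, p = accuracy_vs_chance_ttest(a)
        expect_t = (a.mean() - 0.5) / (a.std(ddof=1) / np.sqrt(3))
        assert t == pytest.approx(expect_t)
        assert p == pytest.approx(1 - sps.t.cdf(expect_t, df=2))

    def test_fewer_than_two_subjects_rejected(self):
        with pytest.raises(ValueError):
            accuracy_vs_chance_ttest([0.6])
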