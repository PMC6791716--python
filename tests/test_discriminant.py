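"""Fisher LDA, split-half predictive power, best-subset search, permutations."""

import numpy as np
import pandas as pd
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.utils.estimator_checks import check_estimator  # noqa: F401

from dastride.discriminant import (LDA_VARIABLES, BestSubsetLDA, FisherLDA,
                                   _enumerate_subsets, _half_masks,
                                   _subset_powers, best_subset_search,
                                   full_data_accuracy, lda_fit_predict,
                                   permutation_test, predictive_power)
from dastride.synthetic import generate_feature_table


def two_gaussians(n0, n1, p, delta, rng, col=0):
    X = rng.normal(size=(n0 + n1, p))
    X[n0:, col] += delta
    y = np.array(["a"] * n0 + ["b"] * n1)
    return X, y


class TestFisherLDA:
    def test_agrees_with_sklearn_equal_priors(self, rng):
        for _ in range(20):
            X, y = two_gaussians(12, 8, 4, 1.5, rng)
            ours = FisherLDA().fit(X, y)
            ref = LinearDiscriminantAnalysis(priors=[0.5, 0.5]).fit(X, y)
            Xt = rng.normal(size=(40, 4))
            assert np.array_equal(ours.predict(Xt), ref.predict(Xt))

    def test_separable_memorisation(self, rng):
        X, y = two_gaussians(10, 10, 3, 50.0, rng)
        assert np.array_equal(lda_fit_predict(X, y, X), y)

    def test_requires_two_classes(self, rng):
        X = rng.normal(size=(6, 2))
        with pytest.raises(ValueError):
            FisherLDA().fit(X, np.zeros(6))

    def test_sklearn_protocol(self):
        est = FisherLDA(ridge=1e-5)
        assert est.get_params() == {"ridge": 1e-5}
        est.set_params(ridge=1e-4)
        assert est.ridge == 1e-4


class TestPredictivePower:
    def test_matches_per_split_sklearn(self, rng):
        X, y = two_gaussians(9, 7, 5, 1.0, rng)
        y01 = (y == "b").astype(int)
        half = _half_masks(y01, 25, np.random.default_rng(5))
        fast = _subset_powers(X, y01, [(0, 2), (1, 3, 4)], half)
        for si, s in enumerate([(0, 2), (1, 3, 4)]):
            accs = []
            for k in range(25):
                for tr in (half[k], ~half[k]):
                    te = ~tr
                    clf = LinearDiscriminantAnalysis(priors=[0.5, 0.5]) \
                        .fit(X[tr][:, s], y[tr])
                    accs.append(np.mean(clf.predict(X[te][:, s]) == y[te]))
            assert fast[si] == pytest.approx(100 * np.mean(accs), abs=1e-9)

    def test_no_signal_near_chance(self, rng):
        vals = [predictive_power(*two_gaussians(10, 10, 4, 0.0,
                                                rng), subset=(0, 1, 2, 3),
                                 n_splits=60, seed=k)
                for k in range(30)]
        assert abs(np.mean(vals) - 50.0) < 4.0

    def test_large_separation_high_power(self, rng):
        X, y = two_gaussians(12, 12, 3, 5.0, rng)
        assert predictive_power(X, y, (0,), n_splits=200, seed=0) > 95.0

    def test_reproducible_under_seed(self, rng):
        X, y = two_gaussians(8, 8, 3, 1.0, rng)
        a = predictive_power(X, y, (0, 1), n_splits=100, seed=42)
        b = predictive_power(X, y, (0, 1), n_splits=100, seed=42)
        assert a == b

    def test_affine_rescaling_invariance(self, rng):
        X, y = two_gaussians(10, 8, 4, 1.2, rng)
        X2 = X.copy()
        X2[:, 1] = X2[:, 1] * 370.0 - 12.0  # rescale one feature
        for s in [(1,), (0, 1), (1, 2, 3)]:
            a = predictive_power(X, y, s, n_splits=80, seed=3)
            b = predictive_power(X2, y, s, n_splits=80, seed=3)
            assert b == pytest.approx(a, abs=1e-9)

    def test_stratified_halves(self):
        y01 = np.array([0] * 15 + [1] * 9)
        half = _half_masks(y01, 10, np.random.default_rng(0))
        n0 = half[:, :15].sum(axis=1)
        n1 = half[:, 15:].sum(axis=1)
        assert set(n0) <= {7, 8} and set(n1) <= {4, 5}


class TestBestSubsetSearch:
    def test_enumerates_all_subsets(self):
        assert len(_enumerate_subsets(range(13))) == 8191
        assert len(_enumerate_subsets(range(3))) == 7

    def test_finds_planted_variable(self, rng):
        X, y = two_gaussians(12, 12, 4, 2.5, rng, col=2)
        res = best_subset_search(X, y, n_splits=100, seed=0)
        assert "x2" in res.subset

    def test_named_columns_from_dataframe(self, rng):
        df = generate_feature_table(10, {"sfb_pct": 3.0}, seed=1)
        res = best_subset_search(df[list(LDA_VARIABLES[:5])
                                    + ["sfb_pct"]].iloc[:, :6],
                                 df["group"], n_splits=50, seed=2)
        assert res.predictive_power > 50

    def test_full_data_accuracy_beats_split_half(self, rng):
        X, y = two_gaussians(10, 10, 3, 1.5, rng)
        res = best_subset_search(X, y, n_splits=100, seed=1)
        acc, calls = full_data_accuracy(X, y, res.subset)
        assert acc >= res.predictive_power - 5
        assert len(calls) == 20
        assert {c[1] for c in calls} == {"a", "b"}


class TestPermutationTest:
    def test_resolution_bound_and_strong_signal(self, rng):
        X, y = two_gaussians(10, 10, 3, 5.0, rng)
        pt = permutation_test(X, y, candidates=(0, 1, 2), n_perm=40,
                              n_splits_inner=40, seed=0)
        assert pt["p_value"] >= 1 / 40
        assert pt["p_value"] <= 0.05
        assert pt["scaled_down"]

    def test_null_p_not_extreme(self, rng):
        X, y = two_gaussians(8, 8, 3, 0.0, rng)
        pt = permutation_test(X, y, candidates=(0, 1, 2), n_perm=30,
                              n_splits_inner=30, seed=1)
        assert pt["p_value"] > 0.1


class TestBestSubsetLDAEstimator:
    def test_fit_predict_roundtrip(self, rng):
        df = generate_feature_table(12, {"sfb_pct": 4.0, "rel_trough": 2.0},
                                    seed=3)
        est = BestSubsetLDA(candidates=["sfb_pct", "rel_trough", "cv_pct"],
                            n_splits=60, random_state=0)
        est.fit(df[list(LDA_VARIABLES)], df["group"])
        assert "sfb_pct" in est.best_subset_
        assert est.predictive_power_ > 80
        assert est.full_data_accuracy_ >= est.predictive_power_ - 5
        pred = est.predict(df[list(LDA_VARIABLES)])
        assert np.mean(pred == df["group"].to_numpy()) > 0.8

    def test_get_set_params(self):
        est = BestSubsetLDA(n_splits=77)
        assert est.get_params()["n_splits"] == 77
        est.set_params(n_perm=5)
        assert est.n_perm == 5
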