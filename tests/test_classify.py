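"""SVM protocol: standardization, grid search, CV, mixture test,
forward selection (with a brute-force per-step oracle)."""

import numpy as np
import pandas as pd
import pytest

from mdcyto import (DataError, FEATURE_NAMES, ForwardPhenotypeSelector,
                    RBFPhenotypeSVM, cv_accuracy, fit_standardizer,
                    forward_select, grid_search_rbf, mixture_test)
from mdcyto.classify import BASELINE_FEATURES, _cv_mean_accuracy
from mdcyto.synthetic import two_class_table

COARSE_C = (0.5, 2.0, 8.0)
COARSE_GAMMA = (0.01, 0.1, 1.0)


@pytest.fixture(scope="module")
def signal_table():
    """Classes separated 6 sd on surface_roughness_5deg only."""
    return two_class_table(600, seed=21,
                           shift_features={"surface_roughness_5deg": 6.0})


@pytest.fixture(scope="module")
def null_table():
    return two_class_table(600, seed=22)


class TestStandardizer:
    def test_constant_column_maps_to_zeros(self):
        X = np.column_stack([np.zeros(50), np.arange(50.0)])
        s = fit_standardizer(X)
        out = s.transform(X)
        assert np.allclose(out[:, 0], 0.0)
        assert out[:, 1].std() == pytest.approx(1.0, abs=1e-9)
        assert out[:, 1].mean() == pytest.approx(0.0, abs=1e-9)

    def test_train_params_applied_to_test(self):
        rng = np.random.default_rng(0)
        train, test = rng.normal(5, 3, (100, 4)), rng.normal(5, 3, (40, 4))
        s = fit_standardizer(train)
        assert np.allclose(s.inverse_transform(s.transform(test)), test)


class TestGridSearch:
    def test_separable_blobs_reach_high_subset_accuracy(self):
        table = two_class_table(
            600, seed=30, shift_features={"mean_diameter": 8.0,
                                          "area": 8.0, "circularity": 8.0})
        C, gamma, acc = grid_search_rbf(table, subset_per_class=300,
                                        seed=1, c_grid=COARSE_C,
                                        gamma_grid=COARSE_GAMMA)
        assert acc >= 99.0

    def test_no_signal_near_chance(self, null_table):
        _, _, acc = grid_search_rbf(null_table, subset_per_class=300,
                                    seed=1, c_grid=COARSE_C,
                                    gamma_grid=COARSE_GAMMA)
        # best-of-grid on null data is optimistically biased upward, but
        # subset CV stays near chance
        assert 45.0 <= acc <= 60.0

    def test_deterministic_under_seed(self, signal_table):
        r1 = grid_search_rbf(signal_table, subset_per_class=200, seed=5,
                             c_grid=COARSE_C, gamma_grid=COARSE_GAMMA)
        r2 = grid_search_rbf(signal_table, subset_per_class=200, seed=5,
                             c_grid=COARSE_C, gamma_grid=COARSE_GAMMA)
        assert r1 == r2

    def test_subset_larger_than_class_errors(self, null_table):
        with pytest.raises(DataError):
            grid_search_rbf(null_table, subset_per_class=10_000, seed=0)


class TestCvAccuracy:
    def test_no_signal_is_chance(self, null_table):
        acc = cv_accuracy(null_table, list(FEATURE_NAMES), C=1.0,
                          gamma=1 / 21, train_per_class=600, seed=3)
        assert acc == pytest.approx(50.0, abs=4.0)

    def test_six_sd_signal_is_near_perfect(self, signal_table):
        acc = cv_accuracy(signal_table, ["surface_roughness_5deg"],
                          C=1.0, gamma=1.0, train_per_class=600, seed=3)
        assert acc >= 99.0

    def test_bitwise_deterministic(self, signal_table):
        kw = dict(C=2.0, gamma=0.1, train_per_class=400, seed=17)
        a1 = cv_accuracy(signal_table, ["mean_diameter", "area"], **kw)
        a2 = cv_accuracy(signal_table, ["mean_diameter", "area"], **kw)
        assert a1 == a2

    def test_too_few_rows_for_folds(self):
        tiny = two_class_table(3, seed=1)
        with pytest.raises(DataError):
            cv_accuracy(tiny, ["area"], C=1.0, gamma=1.0, folds=5, seed=0)

    def test_monotone_information_guard(self, signal_table):
        """Adding features never costs more than ~1 CV standard error on
        a clean fixture."""
        base = cv_accuracy(signal_table, ["surface_roughness_5deg"],
                           C=1.0, gamma=0.1, train_per_class=600, seed=3)
        sup = cv_accuracy(signal_table,
                          ["surface_roughness_5deg", "mean_diameter",
                           "area", "circularity"],
                          C=1.0, gamma=0.1, train_per_class=600, seed=3)
        assert sup >= base - 2.0


class TestMixture:
    def test_constant_predictor_scores_chance(self, null_table):
        class Constant:
            def predict(self, X):
                return np.repeat("A", len(X))
        acc = mixture_test(Constant(), null_table.drop(columns="label"),
                           null_table["label"])
        assert acc == pytest.approx(50.0, abs=0.1)

    def test_unbalanced_mixture_rejected(self, null_table):
        unbal = pd.concat([null_table[null_table.label == "A"],
                           null_table[null_table.label == "B"].head(100)])
        class Constant:
            def predict(self, X):
                return np.repeat("A", len(X))
        with pytest.raises(DataError):
            mixture_test(Constant(), unbal.drop(columns="label"),
                         unbal["label"])

    def test_separable_mixture_scores_100(self, signal_table):
        clf = RBFPhenotypeSVM(C=1.0, gamma=0.5,
                              features=["surface_roughness_5deg"])
        clf.fit(signal_table, signal_table["label"])
        acc = mixture_test(clf, signal_table, signal_table["label"])
        assert acc >= 99.5

    def test_label_permutation_null(self, signal_table):
        rng = np.random.default_rng(8)
        permuted = signal_table.copy()
        permuted["label"] = rng.permutation(permuted["label"].to_numpy())
        acc = cv_accuracy(permuted, list(FEATURE_NAMES), C=1.0,
                          gamma=1 / 21, train_per_class=600, seed=4)
        assert acc == pytest.approx(50.0, abs=4.0)


def independent_stepwise_argmax(table, start, n_add, C, gamma, seed,
                                train_per_class):
    """Brute-force oracle: recompute the exhaustive argmax at each step
    without reusing any state from forward_select."""
    chosen = list(start)
    remaining = [f for f in FEATURE_NAMES if f not in chosen]
    order = []
    for _ in range(n_add):
        scores = {}
        for cand in remaining:
            scores[cand] = cv_accuracy(table, chosen + [cand], C=C,
                                       gamma=gamma, seed=seed,
                                       train_per_class=train_per_class)
        best = max(scores.values())
        # registry-order tie-break
        pick = next(f for f in FEATURE_NAMES
                    if f in scores and scores[f] == best)
        order.append(pick)
        chosen.append(pick)
        remaining.remove(pick)
    return order


class TestForwardSelection:
    def test_informative_feature_selected_first(self, signal_table):
        res = forward_select(signal_table, n_add=2, seed=9, C=1.0,
                             gamma=0.1, train_per_class=400)
        assert res.ordered_added_features[0] == "surface_roughness_5deg"
        assert len(res.accuracy_trajectory) == 3
        assert res.accuracy_trajectory[1] >= 95.0

    def test_matches_independent_stepwise_oracle(self, signal_table):
        res = forward_select(signal_table, n_add=3, seed=12, C=2.0,
                             gamma=0.1, train_per_class=300)
        oracle = independent_stepwise_argmax(
            signal_table, BASELINE_FEATURES, 3, C=2.0, gamma=0.1,
            seed=12, train_per_class=300)
        assert res.ordered_added_features == oracle

    def test_too_many_additions_rejected(self, null_table):
        with pytest.raises(Exception):
            forward_select(null_table, n_add=25, seed=0, C=1.0, gamma=0.1)

    def test_null_trajectory_stays_near_chance(self, null_table):
        # picking the best of ~19 noise candidates inflates the selected
        # accuracy by the max-order statistic; at 600/class the CV SE is
        # ~1.7 points, so the null trajectory sits within ~50 + 3 SE
        res = forward_select(null_table, n_add=3, seed=2, C=1.0,
                             gamma=1 / 21, train_per_class=600)
        traj = np.asarray(res.accuracy_trajectory)
        assert np.all(np.abs(traj - 50.0) <= 8.0)
        assert np.all(np.diff(traj) <= 4.0)


class TestEstimators:
    def test_svm_fit_predict_score(self, signal_table):
        clf = RBFPhenotypeSVM(C=1.0, gamma=0.1)
        clf.fit(signal_table, signal_table["label"])
        assert clf.score(signal_table, signal_table["label"]) > 0.97
        assert set(clf.predict(signal_table)) <= {"A", "B"}
        assert clf.C_ == 1.0 and clf.features_ == list(FEATURE_NAMES)

    def test_svm_grid_search_inside_fit(self, signal_table):
        clf = RBFPhenotypeSVM(c_grid=COARSE_C, gamma_grid=COARSE_GAMMA,
                              subset_per_class=200, random_state=3)
        clf.fit(signal_table, signal_table["label"])
        assert clf.C_ in COARSE_C and clf.gamma_ in COARSE_GAMMA

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone
        clf = RBFPhenotypeSVM(C=4.0, gamma=0.25, random_state=7)
        cloned = clone(clf)
        assert cloned.get_params() == clf.get_params()

    def test_selector_transform(self, signal_table):
        sel = ForwardPhenotypeSelector(n_add=1, C=1.0, gamma=0.1,
                                       train_per_class=300, random_state=5)
        sel.fit(signal_table[list(FEATURE_NAMES)], signal_table["label"])
        out = sel.transform(signal_table[list(FEATURE_NAMES)])
        assert list(out.columns) == list(BASELINE_FEATURES) + \
            sel.selected_features_
        assert len(sel.accuracy_trajectory_) == 2


def test_internal_cv_requires_min_rows():
    X = np.random.default_rng(0).normal(size=(8, 3))
    y = np.array(["A"] * 4 + ["B"] * 4)
    with pytest.raises(DataError):
        _cv_mean_accuracy(X, y, 1.0, 0.1, folds=5, seed=0)
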