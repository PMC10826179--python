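"""Classification stack: AUC, feature ranking, elastic-net logistic,
nested CV (leakage, determinism), random forest, permutation importance."""

import numpy as np
import pandas as pd
import pytest

import lymphomir as lm
from lymphomir._utils import derive_seed
from lymphomir.classify import _effective_inner_folds
from tests.conftest import make_cohort, normalize_chain


def brute_force_auc(scores, labels):
    """O(n^2) pair counting: P(score_pos > score_neg) + 0.5 P(tie)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    pos, neg = scores[labels], scores[~labels]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAuc:
    def test_perfect_separation_and_ties(self):
        assert lm.auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
        assert lm.auc([0.5, 0.5, 0.5, 0.5], [1, 1, 0, 0]) == 0.5

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = rng.integers(4, 30)
            scores = rng.choice(np.linspace(0, 1, 7), size=n)  # force ties
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                labels[0] = 1 - labels[0]
            assert lm.auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-10
            )

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, size=50)
        labels[0] = 1; labels[1] = 0
        assert lm.auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_label_complement_sums_to_one(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=20)
        labels = np.array([1] * 8 + [0] * 12)
        assert lm.auc(scores, labels) + lm.auc(scores, 1 - labels) == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            lm.auc([0.1, 0.2], [1, 1])


class TestRankFeatures:
    def test_panel_percentages_match_reported_counts(self):
        # 246 retained miRNAs: 20% -> 49, 10% -> 25, 5% -> 12 (round(12.3))
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 246))
        y = np.array([0] * 15 + [1] * 15)
        ids = [f"M{i}" for i in range(246)]
        assert len(lm.rank_features(X, y, ids, 20)) == 49
        assert len(lm.rank_features(X, y, ids, 10)) == 25
        assert len(lm.rank_features(X, y, ids, 5)) == 12

    def test_perfect_separator_ranked_first(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 10))
        y = np.array([0] * 10 + [1] * 10)
        X[:, 7] = y * 5.0  # clean separator
        sel = lm.rank_features(X, y, [f"M{i}" for i in range(10)], 10)
        assert sel[0] == "M7"

    def test_minimum_one_feature_and_validation(self):
        X = np.random.default_rng(2).normal(size=(10, 5))
        y = np.array([0] * 5 + [1] * 5)
        assert len(lm.rank_features(X, y, list("abcde"), 1)) == 1
        with pytest.raises(ValueError):
            lm.rank_features(X, y, list("abcde"), 0)


class TestGrids:
    def test_grid_enumerations(self):
        assert lm.LrGrid().n_combinations == 135
        assert len(lm.LrGrid().combinations()) == 135
        assert lm.RfGrid().n_combinations == 48
        assert len(lm.RfGrid().combinations()) == 48

    def test_lr_tie_break_order(self):
        combos = lm.LrGrid().combinations()
        first = combos[0]
        assert first["feature_percentage"] == 5.0
        assert first["inv_reg"] == 1e-4
        assert first["l1_ratio"] == 1.0  # larger l1 preferred on ties


class TestFitElasticLogistic:
    def test_total_shrinkage_limit_gives_constant_scores(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 4))
        y = np.array([0] * 10 + [1] * 20)
        fit = lm.fit_elastic_logistic(X, y, inv_reg=1e-8, l1_ratio=1.0)
        assert np.allclose(fit.coef_, 0.0)
        scores = fit.decision_scores(rng.normal(size=(5, 4)))
        assert np.ptp(scores) < 1e-12

    def test_weak_penalty_approaches_unpenalized_fit(self):
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 3))
        beta = np.array([1.0, -2.0, 0.5])
        y = (rng.random(200) < 1 / (1 + np.exp(-X @ beta))).astype(int)
        fit = lm.fit_elastic_logistic(X, y, inv_reg=1e6, l1_ratio=0.0, max_iter=5000)
        Z = (X - fit.mean) / fit.scale
        ref = LogisticRegression(C=1e6, max_iter=5000).fit(Z, y)
        assert np.allclose(fit.coef_, ref.coef_.ravel(), atol=1e-2)

    def test_separable_toy_reaches_auc_one(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        y = np.array([0, 0, 1, 1])
        fit = lm.fit_elastic_logistic(X, y, inv_reg=1.0, l1_ratio=0.5)
        assert lm.auc(fit.decision_scores(X), y) == 1.0


SMALL_GRID = lm.LrGrid(
    feature_percentages=(10.0, 20.0),
    inv_regularization=(0.01, 1.0, 100.0),
    l1_ratios=(0.0, 0.5, 1.0),
)


@pytest.fixture(scope="module")
def lr_run(small_normalized):
    nm, ann = small_normalized[0], small_normalized[1]
    spec = lm.CvSpec(outer_folds=5, inner_folds=5, seed=3)
    return lm.nested_cv_logistic(
        nm, ann, positive=("nTFHL", "nPTCL"), negative="RLN",
        grid=SMALL_GRID, spec=spec,
    )


class TestNestedCvLogistic:
    def test_planted_signal_is_learned(self, lr_run):
        assert lr_run.mean_auc > 0.9
        assert lr_run.best_auc == max(lr_run.fold_aucs)

    def test_one_out_of_fold_score_per_sample(self, lr_run, small_normalized):
        nm = small_normalized[0]
        assert sorted(lr_run.oof_scores.index) == sorted(nm.sample_ids)
        assert not lr_run.oof_scores.isna().any()

    def test_deterministic_given_seed(self, lr_run, small_normalized):
        nm, ann = small_normalized[0], small_normalized[1]
        again = lm.nested_cv_logistic(
            nm, ann, positive=("nTFHL", "nPTCL"), negative="RLN",
            grid=SMALL_GRID, spec=lm.CvSpec(outer_folds=5, inner_folds=5, seed=3),
        )
        assert np.allclose(again.fold_aucs, lr_run.fold_aucs)
        assert again.best_params == lr_run.best_params
        assert again.selected_features == lr_run.selected_features

    def test_spy_feature_visible_only_in_validation_is_never_selected(
        self, small_normalized
    ):
        # A miRNA equal to the label on fold-0 validation samples and pure
        # noise on its training samples must not enter fold 0's selection:
        # ranking may only look at training data.
        from sklearn.model_selection import StratifiedKFold

        nm, ann = small_normalized[0], small_normalized[1]
        seed = 17
        samples = [s for s in nm.sample_ids]
        y = np.array([1 if ann.labels[s] in ("nTFHL", "nPTCL") else 0 for s in samples])
        outer = StratifiedKFold(n_splits=5, shuffle=True,
                                random_state=derive_seed(seed, "outer"))
        X = nm.values[samples].T.to_numpy()
        tr0, va0 = next(iter(outer.split(X, y)))
        rng = np.random.default_rng(0)
        spy = pd.Series(rng.normal(scale=0.01, size=len(samples)), index=samples)
        spy.iloc[va0] = y[va0] * 10.0
        values = pd.concat([nm.values, spy.to_frame("SPY_MIRNA").T])
        values -= values.mean(axis=0)
        nm_spy = lm.NormalizedMatrix(values=values, provenance=nm.provenance)
        res = lm.nested_cv_logistic(
            nm_spy, ann, positive=("nTFHL", "nPTCL"), negative="RLN",
            grid=SMALL_GRID, spec=lm.CvSpec(outer_folds=5, inner_folds=5, seed=seed),
        )
        assert "SPY_MIRNA" not in res.selected_features[0]

    def test_effective_inner_folds_capped_by_rarest_class(self):
        y = np.array([0] * 3 + [1] * 20)
        with pytest.warns(UserWarning, match="reduced"):
            assert _effective_inner_folds(y, 10) == 3


TINY_RF_GRID = lm.RfGrid(
    max_depths=(3,), bootstrap=(True,), max_features=("sqrt",),
    criterion=("gini",), n_trees=30,
)


@pytest.fixture(scope="module")
def rf_run(small_normalized):
    nm, ann = small_normalized[0], small_normalized[1]
    return lm.nested_cv_random_forest(
        nm, ann, grid=TINY_RF_GRID, spec=lm.CvSpec(outer_folds=5, inner_folds=3, seed=5)
    )


class TestNestedCvRandomForest:
    def test_confusion_counts_sum_to_cohort_size(self, rf_run):
        assert int(rf_run.confusion.counts.to_numpy().sum()) == 88
        assert np.allclose(rf_run.confusion.fractions.sum(axis=1), 1.0)

    def test_every_sample_predicted_once(self, rf_run):
        proba = rf_run.model_result.oof_scores
        assert not proba.isna().any().any()
        assert np.allclose(proba.sum(axis=1), 1.0)

    def test_reactive_class_separates_from_lymphomas(self, rf_run):
        # planted shared effects make RLN separable while subtypes blur
        assert rf_run.model_result.mean_auc > 0.7


class TestPermutationImportance:
    def test_ignored_feature_scores_exactly_zero(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 3))
        y = (X[:, 0] > 0).astype(int)
        fit = lm.fit_elastic_logistic(X[:, :1], y, inv_reg=10.0, l1_ratio=0.0)

        class OneFeatureModel:
            classes_ = np.array([0, 1])

            def predict_proba(self, X):
                return fit.predict_proba(X[:, :1])

        imp = lm.permutation_importance(
            OneFeatureModel(), X, y, ["used", "ignored1", "ignored2"],
            repeats=5, seed=1,
        )
        assert imp.table.loc["ignored1", "mean_importance"] == 0.0
        assert imp.table.loc["ignored2", "mean_importance"] == 0.0
        assert imp.table.loc["used", "mean_importance"] > 0.2

    def test_perfect_feature_importance_equals_baseline_minus_chance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(200, 2))
        y = (X[:, 0] > 0).astype(int)
        fit = lm.fit_elastic_logistic(X, y, inv_reg=100.0, l1_ratio=0.0)
        imp = lm.permutation_importance(fit, X, y, ["f0", "f1"], repeats=200, seed=2)
        # AUC baseline 1.0; permuting the sole informative feature -> ~0.5
        assert imp.table.loc["f0", "mean_importance"] == pytest.approx(0.5, abs=0.05)

    def test_repeats_validated_and_deterministic(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 2))
        y = (X[:, 0] > 0).astype(int)
        fit = lm.fit_elastic_logistic(X, y, inv_reg=1.0, l1_ratio=0.0)
        with pytest.raises(ValueError):
            lm.permutation_importance(fit, X, y, ["a", "b"], repeats=1)
        a = lm.permutation_importance(fit, X, y, ["a", "b"], repeats=5, seed=9)
        b = lm.permutation_importance(fit, X, y, ["a", "b"], repeats=5, seed=9)
        assert a.table.equals(b.table)


class TestCommonPanel:
    def _result(self, folds):
        return lm.ModelResult(
            comparison="x", fold_aucs=np.full(len(folds), 0.9), mean_auc=0.9,
            ci_halfwidth=0.0, best_auc=0.9, best_params=[{}] * len(folds),
            selected_features=folds,
            oof_scores=pd.Series([0.5], index=["S"]),
        )

    def test_intersection_of_stable_sets(self):
        a = self._result([["x", "y"]] * 5)
        b = self._result([["y", "z"]] * 5)
        assert lm.common_panel([a, b]) == {"y"}

    def test_disjoint_and_single(self):
        a = self._result([["x"]] * 5)
        b = self._result([["z"]] * 5)
        assert lm.common_panel([a, b]) == set()
        assert lm.common_panel([a]) == {"x"}

    def test_frequency_threshold(self):
        folds = [["x", "y"], ["x", "y"], ["x", "y"], ["x", "y"], ["x"]]
        a = self._result(folds)  # y in 4/5 folds
        assert lm.common_panel([a], min_fold_frequency=0.8) == {"x", "y"}
        assert lm.common_panel([a], min_fold_frequency=0.9) == {"x"}
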