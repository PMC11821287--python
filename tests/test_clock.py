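import numpy as np
import pandas as pd
import pytest

from ednaclock import clock, solver
from ednaclock.errors import DataError

AGES = np.array([10.0, 12.0, 14.0, 17.0, 19.0, 24.0])


class TestGroupLabels:
    def test_pasting_two_features(self, small_random_design):
        md = small_random_design.metadata.copy()
        md.loc[0, ["gene", "mod_type"]] = ["ND1", "6mA"]
        labels = clock.make_group_labels(md, ("gene", "mod_type"))
        assert labels[0] == "ND1|6mA"

    def test_empty_scheme_gives_distinct_labels(self, small_random_design):
        labels = clock.make_group_labels(small_random_design.metadata, ())
        assert len(set(labels)) == len(labels)

    def test_identical_features_share_label(self):
        md = pd.DataFrame(
            {
                "gene": ["ND1", "ND1"],
                "mod_type": ["6mA", "6mA"],
                "mean_coverage": [3.2, 2.8],  # both round to 3
                "mean_reliability": [0.97, 1.0],  # both round to 1.0
            }
        )
        labels = clock.make_group_labels(
            md, ("gene", "mod_type", "coverage", "reliability")
        )
        assert labels[0] == labels[1] == "ND1|6mA|3|1.0"


class TestMae:
    def test_median_definition(self):
        assert clock.mae([0, 0, 0], [1, 2, 10]) == 2
        assert clock.mae([5, 5], [4, 2]) == 2  # mid-point for even n
        assert clock.mae([1, 2], [1, 2]) == 0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            clock.mae([], [])

    def test_scaled_mae(self):
        assert clock.scaled_mae(0.0, 10, 24) == 0.0
        assert clock.scaled_mae(14.0, 10, 24) == 1.0
        with pytest.raises(ValueError):
            clock.scaled_mae(1.0, 24, 24)


class TestCrossValidation:
    def test_three_folds_of_two_each_sample_predicted_once(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(0, 100, size=(6, 10))
        cv = clock.cross_validate(X, AGES, None, alpha=0.5, k=3, seed=5)
        sizes = sorted(len(f) for f in cv.folds)
        assert sizes == [2, 2, 2]
        assert np.all(np.isfinite(cv.oof_predictions))

    def test_large_lambda_cv_predicts_training_fold_mean(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 100, size=(6, 8))
        Xs, _, _ = solver.standardize_columns(X)
        groups = solver.singleton_groups(8)
        lmax = solver.lambda_max(Xs, AGES - AGES.mean(), groups, 0.8)
        cv = clock.cross_validate(
            X, AGES, None, alpha=0.8, lambdas=np.array([100 * lmax]), k=3, seed=1
        )
        for fold in cv.folds:
            train = np.setdiff1d(np.arange(6), fold)
            assert cv.oof_predictions[fold, 0] == pytest.approx(AGES[train].mean())

    def test_training_fold_too_small_raises(self):
        X = np.random.default_rng(0).uniform(size=(3, 4))
        with pytest.raises(DataError):
            clock.cross_validate(X, AGES[:3], None, alpha=0.5, k=2, seed=0)

    def test_same_seed_same_folds_and_curve(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(0, 100, size=(6, 10))
        a = clock.cross_validate(X, AGES, None, alpha=0.3, k=3, seed=9)
        b = clock.cross_validate(X, AGES, None, alpha=0.3, k=3, seed=9)
        assert all(np.array_equal(fa, fb) for fa, fb in zip(a.folds, b.folds))
        assert np.array_equal(a.cv_curve, b.cv_curve)


class TestFitCandidate:
    def test_perfect_linear_predictor_found(self, small_random_design):
        d = small_random_design
        X = d.X.copy()
        X[:, 7] = 10 + 2 * AGES  # exact linear encoding of age
        design = clock.ClockDesignMatrix(ages=AGES, X=X, metadata=d.metadata)
        fitted = clock.fit_candidate(design, (), alpha=1.0, k=3, seed=0)
        assert fitted.train_mae < 0.2
        assert fitted.coefficients[7] != 0

    def test_constant_design_predicts_mean_age(self, small_random_design):
        d = small_random_design
        X = np.full_like(d.X, 50.0)
        design = clock.ClockDesignMatrix(ages=AGES, X=X, metadata=d.metadata)
        fitted = clock.fit_candidate(design, (), alpha=0.5, k=3, seed=0)
        preds = fitted.predict(X)
        assert preds == pytest.approx(np.full(6, AGES.mean()))
        assert fitted.n_selected == 0

    def test_different_seeds_both_recorded(self, small_random_design):
        f1 = clock.fit_candidate(small_random_design, (), 0.5, 3, seed=1)
        f2 = clock.fit_candidate(small_random_design, (), 0.5, 3, seed=2)
        assert f1.cv_mae >= 0 and f2.cv_mae >= 0  # both valid, possibly unequal


class TestSelectBest:
    def _df(self, rows):
        return pd.DataFrame(
            [
                {"scheme": "none", "alpha": a, "k": 3, "iteration": i,
                 "cv_mae": cv, "train_mae": tr}
                for a, i, cv, tr in rows
            ]
        )

    def test_hand_zscore_tie_broken_by_cv(self):
        df = self._df([(0.1, 0, 2.0, 1.0), (0.2, 0, 3.0, 0.5)])
        scores = clock.selection_scores(df)
        assert scores[0] == pytest.approx(0.0, abs=1e-12)
        assert scores[1] == pytest.approx(0.0, abs=1e-12)
        best, _ = clock.select_best(df)
        assert best["cv_mae"] == 2.0

    def test_single_candidate_scores_zero(self):
        df = self._df([(0.3, 0, 1.7, 0.4)])
        best, scores = clock.select_best(df)
        assert scores[0] == 0.0
        assert best["alpha"] == 0.3

    def test_dominating_candidate_selected(self):
        df = self._df([(0.1, 0, 1.0, 0.1), (0.2, 0, 2.0, 0.5), (0.3, 0, 3.0, 1.0)])
        best, _ = clock.select_best(df)
        assert best["alpha"] == 0.1

    def test_ranking_invariant_under_common_affine_transform(self):
        rng = np.random.default_rng(8)
        df = self._df(
            [(round(a, 2), i, cv, tr) for (a, i), (cv, tr) in zip(
                [(x, y) for x in np.arange(0, 1, 0.2) for y in range(2)],
                rng.uniform(0.5, 5.0, size=(10, 2)),
            )]
        )
        best, _ = clock.select_best(df)
        df2 = df.copy()
        df2["cv_mae"] = 3.5 * df2["cv_mae"] + 11.0
        df2["train_mae"] = 3.5 * df2["train_mae"] + 11.0
        best2, _ = clock.select_best(df2)
        assert (best["alpha"], best["iteration"]) == (best2["alpha"], best2["iteration"])


class TestGridSearch:
    def test_bookkeeping_candidate_count(self, small_random_design):
        summary = clock.grid_search(
            small_random_design,
            alpha_grid=np.array([0.0, 1.0]),
            schemes=[()],
            n_bootstrap=2,
            base_seed=3,
        )
        assert len(summary.candidates) == 4
        assert len(summary.scheme_optima) == 1

    def test_rerun_same_seed_identical_summary(self, small_random_design):
        kwargs = dict(
            alpha_grid=np.array([0.0, 0.5, 1.0]),
            schemes=[(), ("gene",)],
            n_bootstrap=2,
            base_seed=17,
        )
        s1 = clock.grid_search(small_random_design, **kwargs)
        s2 = clock.grid_search(small_random_design, **kwargs)
        pd.testing.assert_frame_equal(s1.candidates, s2.candidates)
        assert np.array_equal(s1.best_clock.coefficients, s2.best_clock.coefficients)

    def test_best_clock_reproduces_table_metrics(self, small_random_design):
        summary = clock.grid_search(
            small_random_design,
            alpha_grid=np.array([0.2, 0.8]),
            schemes=[(), ("mod_type",)],
            n_bootstrap=2,
            base_seed=5,
        )
        assert summary.best_clock.cv_mae == pytest.approx(
            summary.best["cv_mae"], abs=1e-6
        )
        assert summary.best_clock.train_mae == pytest.approx(
            summary.best["train_mae"], abs=1e-6
        )


class TestPredictionAndImportance:
    def _clock(self, coefs, genes=None, intercept=10.0):
        n = len(coefs)
        return clock.FittedClock(
            intercept=intercept,
            coefficients=np.asarray(coefs, float),
            site_keys=[f"MT:{i}:+" for i in range(n)],
            site_genes=genes or ["ND1"] * n,
            site_mod_types=["6mA"] * n,
            alpha=0.5, lam=1.0, scheme=(), k=3, seed=0,
            cv_mae=1.0, train_mae=0.5,
            n_selected=int(np.count_nonzero(coefs)),
        )

    def test_simple_arithmetic(self):
        c = self._clock([0.1])
        assert clock.predict_ages(c, np.array([[50.0]])) == pytest.approx([15.0])

    def test_all_zero_row_predicts_intercept(self):
        c = self._clock([0.1, 0.2])
        assert clock.predict_ages(c, np.zeros((1, 2))) == pytest.approx([10.0])

    def test_missing_sites_listed(self):
        c = self._clock([0.1, 0.2])
        X_new = pd.DataFrame({"MT:0:+": [1.0]})
        with pytest.raises(DataError, match="MT:1"):
            clock.predict_ages(c, X_new)

    def test_training_matrix_reproduces_train_mae(self, small_random_design):
        fitted = clock.fit_candidate(small_random_design, (), 0.5, 3, seed=0)
        preds = clock.predict_ages(
            fitted, small_random_design.X, site_keys=fitted.site_keys
        )
        assert clock.mae(AGES, preds) == pytest.approx(fitted.train_mae)

    def test_importance_split_between_genes(self):
        c = self._clock([0.2, -0.3, 0.5], genes=["ND1", "ND1", "COX1"])
        df = clock.gene_importance(c).set_index("gene")
        assert df.loc["ND1", "proportion"] == pytest.approx(0.5)
        assert df.loc["COX1", "proportion"] == pytest.approx(0.5)
        assert df.loc["ND1", "n_selected"] == 2

    def test_single_gene_gets_everything(self):
        df = clock.gene_importance(self._clock([0.1, 0.4]))
        assert df["proportion"].tolist() == [1.0]

    def test_proportions_sum_to_one(self, small_random_design):
        # ridge keeps every coefficient nonzero, so importance is defined
        fitted = clock.fit_candidate(small_random_design, (), 0.0, 3, seed=0)
        df = clock.gene_importance(fitted)
        assert df["proportion"].sum() == pytest.approx(1.0)

    def test_all_zero_coefficients_raise(self):
        with pytest.raises(DataError):
            clock.gene_importance(self._clock([0.0, 0.0]))
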