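"""Scaling, design assembly, cross-validation and permutation testing."""

import numpy as np
import pandas as pd
import pytest

from mousestress.ml import (
    ModelSpec,
    evaluate_regression,
    fit_predict_cv,
    make_design,
    permutation_test,
    robust_scale,
    run_model_grid,
    win_threshold,
)


class TestRobustScale:
    def test_hand_example(self):
        out = robust_scale(np.array([1.0, 2.0, 3.0, 4.0, 5.0]))
        np.testing.assert_allclose(out[:, 0], [-1, -0.5, 0, 0.5, 1])

    def test_constant_column_centered_only(self):
        out = robust_scale(np.full((5, 1), 7.0))
        np.testing.assert_allclose(out, 0.0)

    def test_location_invariance(self, rng):
        X = rng.normal(size=(30, 3))
        np.testing.assert_allclose(robust_scale(X), robust_scale(X + 13.0), atol=1e-12)

    def test_matches_sklearn_robust_scaler(self, rng):
        from sklearn.preprocessing import RobustScaler

        X = rng.normal(size=(40, 4))
        np.testing.assert_allclose(
            robust_scale(X), RobustScaler().fit_transform(X), atol=1e-12
        )


class TestMakeDesign:
    def _table(self):
        return pd.DataFrame(
            {
                "pid": ["p1", "p1", "p2", "p2"],
                "stage": ["baseline", "application"] * 2,
                "condition": ["high_stress"] * 2 + ["low_stress"] * 2,
                "f1": [1.0, 3.0, 2.0, 2.5],
                "f2": [10.0, 10.0, 20.0, 25.0],
                "valence": [1.0, 2.0, 3.0, 1.0],
            }
        )

    def test_difference_scores_entrywise(self):
        X, y, pids = make_design(self._table(), "difference_score")
        df = pd.DataFrame(X, index=pids, columns=["f1", "f2"])
        assert df.loc["p1"].tolist() == [2.0, 0.0]
        assert df.loc["p2"].tolist() == [0.5, 5.0]

    def test_identical_stages_give_zero_difference(self):
        t = self._table()
        t.loc[t["stage"] == "application", ["f1", "f2"]] = (
            t.loc[t["stage"] == "baseline", ["f1", "f2"]].to_numpy()
        )
        X, _, _ = make_design(t, "difference_score")
        np.testing.assert_allclose(X, 0.0)

    def test_application_only_ignores_baseline(self):
        t1 = self._table()
        t2 = self._table()
        t2.loc[t2["stage"] == "baseline", ["f1", "f2"]] = -999.0
        X1, y1, _ = make_design(t1, "application_only")
        X2, y2, _ = make_design(t2, "application_only")
        np.testing.assert_array_equal(X1, X2)
        np.testing.assert_array_equal(y1, y2)

    def test_rating_target_differences(self):
        X, y, pids = make_design(self._table(), "difference_score", target="valence")
        assert dict(zip(pids, y)) == {"p1": 1.0, "p2": -2.0}

    def test_missing_baseline_drops_participant(self, caplog):
        t = self._table().drop(0)  # p1 baseline gone
        with caplog.at_level("WARNING"):
            X, y, pids = make_design(t, "difference_score")
        assert pids == ["p2"]
        assert "without a baseline" in caplog.text


class TestCV:
    def test_separable_blobs_are_perfectly_classified(self, rng):
        n = 200
        X = np.vstack(
            [rng.normal(0, 1, (n // 2, 4)), rng.normal(10, 1, (n // 2, 4))]
        )
        y = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
        for fam in ("linear_logistic", "rbf_svm_classifier", "random_forest_classifier"):
            res = fit_predict_cv(X, y, ModelSpec(fam), seed=0)
            assert res.mean_score == 1.0
            assert len(res.fold_scores) == 5

    def test_random_labels_score_near_chance(self, rng):
        n = 500
        X = rng.normal(size=(n, 6))
        accs = []
        for seed in range(20):
            y = rng.permutation(np.array(["a", "b"] * (n // 2)))
            accs.append(fit_predict_cv(X, y, ModelSpec("linear_logistic"), seed=seed).mean_score)
        assert 0.42 <= np.mean(accs) <= 0.58

    def test_noiseless_linear_regression_recovers(self, rng):
        X = rng.normal(size=(100, 3))
        y = X @ np.array([3.0, -1.0, 0.5]) + 2.0
        res = evaluate_regression(X, y, ModelSpec("linear_least_squares"), seed=1)
        assert res.mean_score > 0.999

    def test_uninformative_regression_scores_nonpositive(self, rng):
        X = rng.normal(size=(120, 5))
        scores = [
            evaluate_regression(
                X, rng.normal(size=120), ModelSpec("linear_least_squares"), seed=s
            ).mean_score
            for s in range(20)
        ]
        assert np.mean(scores) <= 0

    def test_mean_predictor_r2_zero_on_training_data(self, rng):
        from sklearn.metrics import r2_score

        y = rng.normal(size=50)
        assert r2_score(y, np.full_like(y, y.mean())) == pytest.approx(0.0, abs=1e-12)

    def test_constant_target_raises(self, rng):
        X = rng.normal(size=(20, 2))
        with pytest.raises(ValueError, match="constant"):
            evaluate_regression(X, np.ones(20), ModelSpec("linear_least_squares"))

    def test_single_class_raises(self, rng):
        X = rng.normal(size=(20, 2))
        with pytest.raises(ValueError, match="class"):
            fit_predict_cv(X, np.array(["a"] * 20), ModelSpec("linear_logistic"))

    def test_svm_gamma_matches_stated_formula(self, rng):
        # sklearn's gamma="scale" realises 1/(n_features * var(flattened X))
        from sklearn.svm import SVC

        X = rng.normal(2.0, 3.0, size=(60, 5))
        y = np.array(["a", "b"] * 30)
        est = SVC(kernel="rbf", gamma="scale", C=1.0).fit(X, y)
        assert est._gamma == pytest.approx(1.0 / (X.shape[1] * X.var()))


class TestPermutation:
    def test_win_thresholds(self):
        assert win_threshold(0.05, 500) == 475
        assert win_threshold(0.0083, 500) == 496

    def test_separable_data_wins_everything(self, rng):
        n = 60
        X = np.vstack([rng.normal(0, 1, (n // 2, 3)), rng.normal(12, 1, (n // 2, 3))])
        y = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
        res = permutation_test(X, y, ModelSpec("linear_logistic"), n_perm=100, seed=0)
        assert res.true_score == 1.0
        assert res.wins == 100
        assert res.p_emp == 0.0
        assert res.significant_at[0.05] and res.significant_at[0.0083]

    def test_tie_convention_counts_against_true_model(self, rng):
        # constant features: every refit predicts the same way, all
        # permutation scores tie with the true score
        X = np.ones((40, 2))
        y = np.array(["a", "b"] * 20)
        res = permutation_test(X, y, ModelSpec("linear_logistic"), n_perm=50, seed=0)
        assert res.wins == 0
        assert res.p_emp == 1.0

    def test_no_scaler_leakage_from_test_fold(self, rng):
        """Perturbing test-fold rows must not change training-fold scores."""
        from sklearn.model_selection import StratifiedKFold

        X = rng.normal(size=(50, 4))
        y = np.array(["a", "b"] * 25)
        splitter = StratifiedKFold(5, shuffle=True, random_state=3)
        tr, te = next(splitter.split(X, y))
        X2 = X.copy()
        X2[te] += 1000.0  # outrageous test rows
        from sklearn.pipeline import Pipeline
        from sklearn.preprocessing import RobustScaler
        from sklearn.linear_model import LogisticRegression

        m1 = Pipeline([("s", RobustScaler()), ("m", LogisticRegression(solver="liblinear"))])
        m2 = Pipeline([("s", RobustScaler()), ("m", LogisticRegression(solver="liblinear"))])
        m1.fit(X[tr], y[tr])
        m2.fit(X2[tr], y[tr])
        np.testing.assert_allclose(
            m1.named_steps["s"].center_, m2.named_steps["s"].center_
        )
        assert m1.score(X[tr], y[tr]) == m2.score(X2[tr], y[tr])


class TestModelGrid:
    def _features(self, rng, n=40, effect=0.0):
        rows = []
        for i in range(n):
            cond = "high_stress" if i % 2 else "low_stress"
            for stage in ("baseline", "application"):
                shift = effect if (cond == "high_stress" and stage == "application") else 0.0
                rows.append(
                    {
                        "pid": f"p{i}",
                        "stage": stage,
                        "condition": cond,
                        "f1": rng.normal() + shift,
                        "f2": rng.normal(),
                        "valence": rng.normal(2, 1),
                    }
                )
        return pd.DataFrame(rows)

    def test_six_rows_per_task_target(self, rng):
        table = run_model_grid(
            self._features(rng), "slider", target="condition", n_perm=10, seed=0
        )
        assert len(table) == 6
        assert set(table["design_mode"]) == {"application_only", "difference_score"}
        assert table["algorithm"].nunique() == 3

    def test_regression_rows_omit_permutation_when_r2_nonpositive(self, rng):
        table = run_model_grid(
            self._features(rng), "slider", target="valence", n_perm=10, seed=0
        )
        assert len(table) == 6
        nonpos = table[table["score"] <= 0]
        assert not nonpos.empty
        assert nonpos["wins"].isna().all() if "wins" in table.columns else True

    def test_null_cohort_accuracies_near_chance(self, rng):
        table = run_model_grid(
            self._features(rng, n=60), "slider", target="condition", n_perm=5, seed=1
        )
        # binomial 99% band around 0.5 for n = 60
        assert (table["score"] - 0.5).abs().max() < 2.58 * np.sqrt(0.25 / 60) + 0.05
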