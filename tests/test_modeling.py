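"""LASSO selection, logistic refit, AUC, and cross-scheme orchestration."""

import numpy as np
import pandas as pd
import pytest

from pvsweet.modeling import (auc_ci, lasso_select, logistic_fit,
                              run_all_schemes)


def toy_frame(n=2000, seed=0, n_noise=5, signal_strength=None):
    """Design with one informative drug indicator and pure-noise indicators."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "primaryid": np.arange(n),
        "age": rng.normal(55, 15, n).round(),
        "sex": rng.choice(["M", "F"], n),
    })
    y = rng.random(n) < 0.25
    if signal_strength is None:
        df["marker"] = y.astype(int)  # perfectly tracks case status
    else:
        p = np.where(y, signal_strength, 0.05)
        df["marker"] = (rng.random(n) < p).astype(int)
    for j in range(n_noise):
        df[f"noise{j}"] = (rng.random(n) < 0.1).astype(int)
    df.insert(1, "case", y.astype(int))
    return df


class TestLassoSelect:
    def test_informative_variable_selected_at_lambda_min(self):
        """A drug indicator strongly predictive of case status survives
        cross-validated selection in every one of 5 seeds."""
        for seed in range(5):
            df = toy_frame(seed=seed, signal_strength=0.7)
            res = lasso_select(df, folds=5, seed=seed, n_lambdas=30)
            assert "marker" in res.selected_min

    def test_lambda_max_shrinks_everything(self):
        df = toy_frame(signal_strength=0.7)
        res = lasso_select(df, folds=5, seed=0, n_lambdas=30)
        assert res.n_nonzero[0] == 0          # null model at the path top
        assert res.lambda_1se >= res.lambda_min

    def test_1se_no_larger_than_min_selection(self):
        df = toy_frame(signal_strength=0.6)
        res = lasso_select(df, folds=5, seed=1, n_lambdas=30)
        assert len(res.selected_1se) <= len(res.selected_min)

    def test_age_sex_only_dataset_runs(self):
        df = toy_frame().drop(columns=[c for c in toy_frame().columns
                                       if c.startswith(("marker", "noise"))])
        res = lasso_select(df, variables=["age", "sex"], folds=5, seed=0,
                           n_lambdas=20)
        assert len(res.lambdas) == 20

    def test_constant_predictor_dropped(self):
        df = toy_frame(n=600, signal_strength=0.7)
        df["allzero"] = 0
        res = lasso_select(df, folds=5, seed=0, n_lambdas=15)
        assert "allzero" in res.dropped_allzero
        assert "allzero" not in res.variables

    def test_deterministic_given_seed(self):
        df = toy_frame(signal_strength=0.5)
        a = lasso_select(df, folds=5, seed=3, n_lambdas=20)
        b = lasso_select(df, folds=5, seed=3, n_lambdas=20)
        np.testing.assert_array_equal(a.cv_mean, b.cv_mean)
        assert a.selected_min == b.selected_min

    def test_deviance_criterion_supported(self):
        df = toy_frame(signal_strength=0.6)
        res = lasso_select(df, folds=5, seed=0, n_lambdas=20,
                           criterion="deviance")
        assert "marker" in res.selected_min


class TestLogisticFit:
    def test_single_binary_predictor_equals_contingency_or(self):
        """Saturated one-predictor logistic reproduces the 2×2 odds ratio:
        cases 20 exposed / 80 not, controls 10 / 90 -> OR 2.25."""
        rows = ([{"case": 1, "x": 1}] * 20 + [{"case": 1, "x": 0}] * 80
                + [{"case": 0, "x": 1}] * 10 + [{"case": 0, "x": 0}] * 90)
        df = pd.DataFrame(rows)
        df["age"], df["sex"] = 50.0, "M"
        res = logistic_fit(df, ["x"])
        assert res.table.set_index("variable").loc["x", "or"] == pytest.approx(
            2.25, rel=1e-6)

    def test_null_predictor_ci_covers_one(self):
        """A predictor independent of outcome: 95% Wald CI covers OR = 1 in
        at least 90% of 20 seeds."""
        covered = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 4000
            df = pd.DataFrame({
                "case": (rng.random(n) < 0.2).astype(int),
                "x": (rng.random(n) < 0.3).astype(int),
                "age": 50.0, "sex": "F",
            })
            row = logistic_fit(df, ["x"]).table.set_index("variable").loc["x"]
            covered += row["ci_low"] <= 1.0 <= row["ci_high"]
        assert covered >= 18

    def test_perfect_separation_flagged_not_raised(self):
        df = toy_frame(n=400)  # marker == case exactly
        res = logistic_fit(df, ["marker"])
        assert res.converged is False

    def test_singular_design_names_columns(self):
        df = toy_frame(n=400, signal_strength=0.6)
        df["copy_of_marker"] = df["marker"]
        with pytest.raises(ValueError, match="copy_of_marker|marker"):
            logistic_fit(df, ["marker", "copy_of_marker"])

    def test_duplicate_variables_rejected(self):
        with pytest.raises(ValueError):
            logistic_fit(toy_frame(), ["marker", "marker"])

    def test_missing_age_rows_dropped_and_counted(self):
        df = toy_frame(n=500, signal_strength=0.6)
        df.loc[:49, "age"] = np.nan
        res = logistic_fit(df, ["age", "marker"])
        assert res.n_dropped_missing == 50
        assert res.n_cases + res.n_controls == 450


class TestAucCi:
    def test_perfect_separation_auc_one(self):
        auc, lo, hi = auc_ci([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0 and hi == 1.0

    def test_all_tied_scores_auc_half(self):
        auc, _, _ = auc_ci([0.5] * 10, [1] * 4 + [0] * 6)
        assert auc == pytest.approx(0.5)

    def test_one_class_raises(self):
        with pytest.raises(ValueError):
            auc_ci([0.1, 0.2], [1, 1])

    def test_null_scores_auc_near_half(self):
        """Scores independent of labels: AUC within [0.47, 0.53] at n=5,000
        for each of 10 seeds."""
        for seed in range(10):
            rng = np.random.default_rng(seed)
            scores = rng.random(5000)
            labels = (rng.random(5000) < 0.3).astype(int)
            auc, lo, hi = auc_ci(scores, labels)
            assert 0.47 <= auc <= 0.53
            assert lo <= auc <= hi

    def test_delong_ci_reasonable_width(self):
        rng = np.random.default_rng(1)
        n = 2000
        labels = (rng.random(n) < 0.3).astype(int)
        scores = labels * 0.5 + rng.random(n)
        auc, lo, hi = auc_ci(scores, labels)
        assert 0 < hi - lo < 0.1
        assert lo < auc < hi


class TestRunAllSchemes:
    def test_planted_drugs_in_every_scheme_intersection(self, planted_store):
        results, forest, overlap = run_all_schemes(
            planted_store, seed=0, folds=5, n_lambdas=25)
        assert {"azathioprine", "azacitidine", "filgrastim"} <= overlap
        assert set(forest["scheme"]) == {"main", "sensitivity_A",
                                         "sensitivity_B"}

    def test_refit_auc_at_least_1se_model(self, planted_store):
        """Unpenalized refit of the λ_min selection is at least as
        discriminative in-sample as the sparser λ_1se model."""
        from pvsweet.cohort import build_dataset
        from pvsweet.signals import screen

        sig = screen(planted_store)
        cands = sorted(sig.loc[sig["signal"], "drug"])
        ds = build_dataset(planted_store, "full", cands)
        lasso = lasso_select(ds, folds=5, seed=0, n_lambdas=25)
        fit_min = logistic_fit(ds, lasso.selected_min)
        sel_1se = lasso.selected_1se or lasso.selected_min
        fit_1se = logistic_fit(ds, sel_1se)
        assert fit_min.auc >= fit_1se.auc - 1e-9

    def test_bit_reproducible_given_seed(self, planted_store):
        r1, f1, o1 = run_all_schemes(planted_store, seed=5, folds=5,
                                     n_lambdas=15, schemes=("main",))
        r2, f2, o2 = run_all_schemes(planted_store, seed=5, folds=5,
                                     n_lambdas=15, schemes=("main",))
        pd.testing.assert_frame_equal(f1, f2)
        assert o1 == o2
        assert r1["main"].logistic.auc == r2["main"].logistic.auc
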