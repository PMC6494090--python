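"""Logistic PD-status modelling: fitting, selection, ROC, LOOCV."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from macula.model import (
    FitError,
    LogisticModel,
    correlation_matrix,
    fit_logistic,
    forward_select,
    interaction_screen,
    loocv_roc,
    roc_and_c,
    wald_odds_ratios,
)


def _two_by_two(a=10, b=5, c=5, d=10):
    """Rows for a 2×2 exposure table: a=(x1,y1), b=(x1,y0), c=(x0,y1), d=(x0,y0)."""
    x = [1] * (a + b) + [0] * (c + d)
    y = [1] * a + [0] * b + [1] * c + [0] * d
    return pd.DataFrame({"outcome": y, "exposure": x, "subject_id": range(len(x))})


def _simulated(n=400, betas=None, seed=0, names=("x1", "x2", "x3")):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, len(names)))
    eta = X @ np.array(betas if betas is not None else [0.0] * len(names))
    p = 1 / (1 + np.exp(-eta))
    y = rng.binomial(1, p)
    df = pd.DataFrame(X, columns=list(names))
    df["outcome"] = y
    df["subject_id"] = np.arange(n)
    return df


class TestFitLogistic:
    def test_two_by_two_closed_form(self):
        fit = fit_logistic(_two_by_two(), ["exposure"])
        assert fit.converged
        assert fit.params["exposure"] == pytest.approx(np.log(4.0), abs=1e-6)

    def test_intercept_only_balanced(self):
        df = pd.DataFrame({"outcome": [0] * 20 + [1] * 20, "subject_id": range(40)})
        fit = fit_logistic(df, [])
        assert fit.params["intercept"] == pytest.approx(0.0, abs=1e-8)
        assert fit.llf == pytest.approx(40 * np.log(0.5))
        assert fit.aic == pytest.approx(2 - 2 * 40 * np.log(0.5))

    def test_perfect_separation_flagged(self):
        x = np.concatenate([np.linspace(-5, -1, 6), np.linspace(1, 5, 6)])
        df = pd.DataFrame(
            {"outcome": [0] * 6 + [1] * 6, "x": x, "subject_id": range(12)}
        )
        fit = fit_logistic(df, ["x"])
        assert fit.separation
        assert not fit.converged

    def test_rank_deficient_design_names_columns(self):
        df = _simulated(50, [1.0, 0.0, 0.0])
        df["x_dup"] = df["x1"]
        with pytest.raises(FitError, match="collinear"):
            fit_logistic(df, ["x1", "x_dup"])

    def test_single_class_outcome_rejected(self):
        df = _simulated(30)
        df["outcome"] = 1
        with pytest.raises(FitError, match="classes"):
            fit_logistic(df, ["x1"])

    def test_score_equations_hold_at_optimum(self):
        df = _simulated(200, [0.8, -0.5, 0.0], seed=3)
        fit = fit_logistic(df, ["x1", "x2", "x3"])
        X = np.column_stack([np.ones(len(df)), df[["x1", "x2", "x3"]].to_numpy()])
        grad = X.T @ (df["outcome"].to_numpy() - fit.fittedvalues)
        assert np.abs(grad).max() < 1e-6

    def test_matches_statsmodels_reference(self):
        statsmodels = pytest.importorskip("statsmodels.api")
        df = _simulated(300, [0.7, -0.3, 0.1], seed=5)
        fit = fit_logistic(df, ["x1", "x2", "x3"])
        X = statsmodels.add_constant(df[["x1", "x2", "x3"]])
        ref = statsmodels.Logit(df["outcome"], X).fit(disp=0)
        np.testing.assert_allclose(fit.params.to_numpy(), ref.params.to_numpy(), atol=1e-6)
        np.testing.assert_allclose(fit.bse.to_numpy(), ref.bse.to_numpy(), atol=1e-6)
        assert fit.llf == pytest.approx(ref.llf, abs=1e-8)


class TestForwardSelect:
    def test_trace_starts_at_forced_model(self):
        df = _simulated(200, [1.0, 0.0, 0.0], seed=1)
        df["sex_female"] = np.random.default_rng(1).binomial(1, 0.5, len(df))
        fit, trace = forward_select(df, ["x1", "x2", "x3"], forced=["sex_female"])
        step0 = trace[trace["step"] == 0]
        assert step0["candidate"].iloc[0] == "sex_female"
        assert "sex_female" in fit.params.index

    def test_strong_signal_selected_first(self):
        hits = 0
        for seed in range(10):
            df = _simulated(400, [2.0, 0.0, 0.0], seed=seed)
            _, trace = forward_select(df, ["x1", "x2", "x3"])
            first = trace[(trace["step"] == 1) & trace["selected"]]
            hits += (not first.empty) and first["candidate"].iloc[0] == "x1"
        assert hits >= 9

    def test_pure_noise_selects_nothing_usually(self):
        empty = 0
        for seed in range(10):
            df = _simulated(400, [0.0, 0.0, 0.0], seed=100 + seed)
            fit, _ = forward_select(df, ["x1", "x2", "x3"])
            empty += len(fit.params) == 1  # intercept only
        assert empty >= 6

    def test_aic_decreases_along_accepted_steps(self):
        df = _simulated(400, [1.5, -1.0, 0.0], seed=2)
        _, trace = forward_select(df, ["x1", "x2", "x3"])
        accepted = trace[trace["selected"]]["aic"].to_numpy()
        assert (np.diff(accepted) < 0).all()


class TestCorrelationMatrix:
    def test_diagonal_and_antithetic_columns(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [-1.0, -2, -3, -4]})
        corr = correlation_matrix(df, ["x", "y"])
        assert corr.loc["x", "x"] == 1.0
        assert corr.loc["x", "y"] == pytest.approx(-1.0)

    def test_zero_variance_column_flagged_missing(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "z": [5.0, 5, 5, 5]})
        corr = correlation_matrix(df, ["x", "z"])
        assert np.isnan(corr.loc["x", "z"])
        assert corr.loc["z", "z"] == 1.0

    def test_latent_factor_induces_high_correlations(self):
        rng = np.random.default_rng(0)
        latent = rng.normal(0, 10, 200)
        df = pd.DataFrame(
            {f"s{i}": latent + rng.normal(0, 5, 200) for i in range(9)}
        )
        corr = correlation_matrix(df, list(df.columns))
        off = corr.to_numpy()[~np.eye(9, dtype=bool)]
        assert (off > 0.6).all()


class TestOddsRatios:
    def test_two_by_two_contingency_formula(self):
        a, b, c, d = 10, 5, 5, 10
        fit = fit_logistic(_two_by_two(a, b, c, d), ["exposure"])
        ors = wald_odds_ratios(fit)
        or_ = ors.loc["exposure", "odds_ratio"]
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        assert or_ == pytest.approx(a * d / (b * c), rel=1e-6)
        assert ors.loc["exposure", "ci_low"] == pytest.approx(
            np.exp(np.log(4) - 1.96 * se), rel=1e-6
        )
        assert ors.loc["exposure", "ci_high"] == pytest.approx(
            np.exp(np.log(4) + 1.96 * se), rel=1e-6
        )

    def test_null_coefficient_gives_unit_or(self):
        fit = fit_logistic(_two_by_two(8, 8, 8, 8), ["exposure"])
        ors = wald_odds_ratios(fit)
        assert ors.loc["exposure", "odds_ratio"] == pytest.approx(1.0, abs=1e-6)
        assert ors.loc["exposure", "ci_low"] < 1 < ors.loc["exposure", "ci_high"]


class TestInteractionScreen:
    def test_three_base_predictors_give_three_pairs(self):
        df = _simulated(100, [0.5, 0.5, 0.0], seed=4)
        out = interaction_screen(df, ["x1", "x2", "x3"])
        assert len(out) == 3
        assert set(out["pair"]) == {"x1:x2", "x1:x3", "x2:x3"}

    def test_null_interactions_rarely_significant(self):
        clean = 0
        for seed in range(5):
            df = _simulated(400, [1.0, 1.0, 0.0], seed=10 + seed)
            out = interaction_screen(df, ["x1", "x2", "x3"])
            clean += (out["p_value"].dropna() > 0.05).all()
        assert clean >= 4

    def test_planted_product_effect_detected(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(500, 2))
        eta = 0.5 * X[:, 0] + 0.5 * X[:, 1] + 1.5 * X[:, 0] * X[:, 1]
        y = rng.binomial(1, 1 / (1 + np.exp(-eta)))
        df = pd.DataFrame({"x1": X[:, 0], "x2": X[:, 1], "outcome": y,
                           "subject_id": range(500)})
        out = interaction_screen(df, ["x1", "x2"])
        assert out.loc[out["pair"] == "x1:x2", "p_value"].iloc[0] < 0.01


def _brute_force_c(scores, labels):
    scores, labels = np.asarray(scores), np.asarray(labels)
    pos, neg = scores[labels == 1], scores[labels == 0]
    total = 0.0
    for s in pos:
        total += (s > neg).sum() + 0.5 * (s == neg).sum()
    return total / (len(pos) * len(neg))


class TestRoc:
    def test_perfect_ranking(self):
        res = roc_and_c([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert res.c_statistic == 1.0

    def test_tied_scores_example(self):
        res = roc_and_c([0.2, 0.4, 0.4, 0.9], [0, 0, 1, 1])
        assert res.c_statistic == pytest.approx(0.875)

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(0)
        res = roc_and_c(rng.normal(size=4000), rng.binomial(1, 0.5, 4000))
        assert res.c_statistic == pytest.approx(0.5, abs=0.03)

    def test_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(1)
        res = roc_and_c(rng.normal(size=50), rng.binomial(1, 0.4, 50))
        pts = res.points
        assert tuple(pts[0]) == (0.0, 0.0) and tuple(pts[-1]) == (1.0, 1.0)
        assert (np.diff(pts[:, 0]) >= 0).all() and (np.diff(pts[:, 1]) >= 0).all()

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            n = rng.integers(4, 51)
            scores = np.round(rng.normal(size=n), 1)  # force ties
            labels = rng.binomial(1, 0.5, n)
            if labels.min() == labels.max():
                continue
            assert roc_and_c(scores, labels).c_statistic == pytest.approx(
                _brute_force_c(scores, labels), abs=1e-12
            )

    @given(st.integers(0, 10_000))
    @settings(deadline=None, max_examples=30)
    def test_complement_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=30)
        labels = rng.binomial(1, 0.5, 30)
        if labels.min() == labels.max():
            return
        c1 = roc_and_c(scores, labels).c_statistic
        c2 = roc_and_c(-scores, labels).c_statistic
        assert c1 + c2 == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(FitError):
            roc_and_c([0.1, 0.2], [1, 1])


class TestLoocv:
    def test_one_prediction_per_row_and_pairing_respected(self):
        df = _simulated(60, [1.0], names=("x1",), seed=6)
        df["subject_id"] = np.repeat(np.arange(30), 2)  # paired rows per subject
        res = loocv_roc(df, ["x1"], n_boot=50, seed=0)
        assert res.cross_validated
        assert res.ci is not None and res.ci[0] <= res.c_statistic <= res.ci[1]
        assert len(res.points) >= 3

    def test_strong_signal_cv_close_to_apparent(self):
        df = _simulated(200, [2.0, 0.0], names=("x1", "x2"), seed=7)
        apparent = fit_logistic(df, ["x1", "x2"]).roc().c_statistic
        cv = loocv_roc(df, ["x1", "x2"], n_boot=0).c_statistic
        assert abs(cv - apparent) < 0.05

    def test_null_signal_cv_below_apparent(self):
        worse = 0
        for seed in range(5):
            df = _simulated(80, [0.0, 0.0, 0.0], seed=20 + seed)
            apparent = fit_logistic(df, ["x1", "x2", "x3"]).roc().c_statistic
            cv = loocv_roc(df, ["x1", "x2", "x3"], n_boot=0).c_statistic
            worse += cv <= apparent
        assert worse >= 4

    def test_reselection_mode_runs(self):
        df = _simulated(100, [1.5, 0.0], names=("x1", "x2"), seed=8)
        res = loocv_roc(
            df, [], n_boot=0, reselect_per_fold=True,
            candidates=["x1", "x2"], forced=[],
        )
        assert 0.0 <= res.c_statistic <= 1.0

    def test_model_object_interface(self):
        df = _simulated(50, [1.0], names=("x1",), seed=9)
        model = LogisticModel.from_design(df, ["x1"])
        res = model.fit()
        assert res.converged
        assert "Logistic regression" in res.summary()
        assert res.aic == pytest.approx(2 * 2 - 2 * res.llf)
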