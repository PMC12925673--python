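"""Tests for the survey-weighted logit-polynomial prevalence model."""

import numpy as np
import pandas as pd
import pytest

import idmrates as m
from idmrates.exceptions import ConfigError, EmptyDataError
from idmrates.prevalence import (
    _fit_cells,
    _irls_logit,
    aggregate_cells,
    fit_logit_polynomial,
    select_df_loocv,
)

def _records(ages, cases, weights=None, sex="female", center="C", period=1):
    n = len(ages)
    return pd.DataFrame({
        "age": np.asarray(ages, dtype="int64"),
        "sex": sex, "center": center, "period": period,
        "weight": np.ones(n) if weights is None else np.asarray(weights, float),
        "case_anx": pd.array(cases, dtype="Int64"),
        "case_dep": pd.array(cases, dtype="Int64"),
    })

def _simulate_polynomial(beta, n, seed, period=(1, 2)):
    """Records from a logit-polynomial truth in scaled age."""
    rng = np.random.default_rng(seed)
    frames = []
    for per in np.atleast_1d(period):
        ages = rng.integers(19, 75, size=n)
        x = (ages - 46.5) / 27.5
        eta = sum(b * x**j for j, b in enumerate(beta))
        p = 1 / (1 + np.exp(-eta))
        y = (rng.random(n) < p).astype("int64")
        frames.append(_records(ages, y, period=per))
    return pd.concat(frames, ignore_index=True)

class TestAggregateCells:
    def test_weighted_prevalence_hand_sum(self):
        rec = _records([30, 30, 30], [1, 0, 0], weights=[1, 1, 2])
        cells = aggregate_cells(rec, "anxiety")
        assert len(cells) == 1
        assert cells["w_cases"].iloc[0] / cells["w_total"].iloc[0] == 0.25
        assert cells["n"].iloc[0] == 3

    def test_equal_weights_match_unweighted_proportion(self):
        rec = _records([40] * 10, [1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        cells = aggregate_cells(rec, "anxiety")
        assert cells["w_cases"].iloc[0] / cells["w_total"].iloc[0] == 0.3

    def test_missing_case_excluded(self):
        rec = _records([50, 50], [1, 0])
        rec.loc[1, "case_anx"] = pd.NA
        cells = aggregate_cells(rec, "anxiety")
        assert cells["n"].iloc[0] == 1
        # the other condition keeps both rows
        assert aggregate_cells(rec, "depression")["n"].iloc[0] == 2

    def test_all_missing_raises(self):
        rec = _records([50, 50], [1, 0])
        rec["case_anx"] = pd.NA
        with pytest.raises(EmptyDataError):
            aggregate_cells(rec, "anxiety")

    def test_unknown_condition_rejected(self, small_study):
        with pytest.raises(ConfigError):
            aggregate_cells(small_study, "psychosis")

class TestFitLogitPolynomial:
    def test_flat_truth_recovers_intercept(self):
        rec = _simulate_polynomial([-2.2], 40000, seed=2)
        fit = fit_logit_polynomial(rec, "anxiety", df=3)
        # SE of the intercept is ~0.02 at this n; slopes should be small
        assert fit.params[0] == pytest.approx(-2.2, abs=0.06)
        assert np.all(np.abs(fit.params[1:4]) < 0.25)

    def test_duplicating_records_leaves_fit_unchanged(self, small_study):
        fit1 = fit_logit_polynomial(small_study, "anxiety", df=2)
        doubled = pd.concat([small_study, small_study], ignore_index=True)
        fit2 = fit_logit_polynomial(doubled, "anxiety", df=2)
        assert np.allclose(fit1.params, fit2.params, atol=1e-8)

    def test_weight_rescaling_invariance(self, small_study):
        fit1 = fit_logit_polynomial(small_study, "anxiety", df=2)
        scaled = small_study.copy()
        scaled["weight"] = scaled["weight"] * 7.3
        fit2 = fit_logit_polynomial(scaled, "anxiety", df=2)
        assert np.allclose(fit1.params, fit2.params, atol=1e-8)

    def test_cubic_truth_recovered_within_tolerance(self):
        beta = [-2.2, 0.6, -0.3, 0.4]
        rec = _simulate_polynomial(beta, 100000, seed=3)
        fit = fit_logit_polynomial(rec, "anxiety", df=3)
        ages = np.linspace(19, 74, 200)
        x = (ages - 46.5) / 27.5
        p_true = 1 / (1 + np.exp(-(beta[0] + beta[1] * x + beta[2] * x**2
                                   + beta[3] * x**3)))
        p_fit = fit.prevalence(2017.0, ages, "female", "C")
        assert np.max(np.abs(p_fit - p_true)) < 0.01

    def test_invalid_df_rejected(self, small_study):
        with pytest.raises(ConfigError):
            fit_logit_polynomial(small_study, "anxiety", df=0)

    def test_json_roundtrip(self, small_study, tmp_path):
        fit = fit_logit_polynomial(small_study, "anxiety", df=3)
        fit.to_json(tmp_path / "fit.json")
        back = m.PrevalenceFit.from_json(tmp_path / "fit.json")
        ages = np.linspace(20, 73, 40)
        assert np.allclose(
            back.prevalence(2017.0, ages, "female", "Hamburg"),
            fit.prevalence(2017.0, ages, "female", "Hamburg"),
        )

class TestDerivative:
    def test_zero_slope_coefficients_give_zero_derivative(self):
        fit = m.PrevalenceFit(
            params=np.array([-2.0, 0.0, 0.0]), columns=("const", "age^1", "time"),
            df=1, sexes=("female",), centers=("C",), age_sex_interaction=False,
        )
        _, dp = fit.prevalence_and_derivative(2016.0, np.array([30.0, 50.0]))
        assert np.allclose(dp, 0.0)

    def test_chain_rule_hand_example(self):
        # eta = -2 + 0.05 * a  (slope on the raw age scale), no time term
        slope_scaled = 0.05 * 27.5
        intercept = -2 + 0.05 * 46.5
        fit = m.PrevalenceFit(
            params=np.array([intercept, slope_scaled, 0.0]),
            columns=("const", "age^1", "time"),
            df=1, sexes=("female",), centers=("C",), age_sex_interaction=False,
        )
        a = 46.5  # eta = 0.325 there; pick the age where p works out simply
        p, dp = fit.prevalence_and_derivative(2017.0, a)
        assert dp == pytest.approx(p * (1 - p) * 0.05, rel=1e-12)

    def test_analytic_matches_central_differences(self, small_study, rng):
        """|analytic (d/dt + d/da) p  -  central difference| < 1e-6."""
        fit = fit_logit_polynomial(small_study, "anxiety", df=3)
        h = 1e-4
        for _ in range(100):
            a = rng.uniform(20, 73)
            t = rng.uniform(2015.5, 2018.5)
            sex = rng.choice(["female", "male"])
            p, dp = fit.prevalence_and_derivative(t, a, sex, "Hamburg")
            p_plus = fit.prevalence(t + h, a + h, sex, "Hamburg")
            p_minus = fit.prevalence(t - h, a - h, sex, "Hamburg")
            assert abs(dp - (p_plus - p_minus) / (2 * h)) < 1e-6

    def test_extrapolation_warns(self, small_study):
        fit = fit_logit_polynomial(small_study, "anxiety", df=2)
        with pytest.warns(UserWarning, match="age range"):
            fit.prevalence_and_derivative(2017.0, 80.0, "female", "Hamburg")

class TestIrlsAgainstStatsmodels:
    def test_same_weighted_binomial_mle(self, small_study):
        cells = aggregate_cells(small_study, "anxiety")
        params_sm, X, y = _fit_cells(cells, 3, ("female", "male"), ("Hamburg",),
                                     True, (1, 2))
        w = cells["w_total"].to_numpy(float)
        params_irls = _irls_logit(X, y, w, np.zeros_like(params_sm))
        assert np.allclose(params_irls, params_sm, atol=1e-6)

class TestSelectDfLoocv:
    def test_single_candidate_returned(self, small_study):
        assert select_df_loocv(small_study, "anxiety", candidate_dfs=(3,)) == 3

    def test_cubic_truth_selects_three(self):
        rec = _simulate_polynomial([-2.2, 0.8, 0.5, 0.6], 60000, seed=11)
        assert select_df_loocv(rec, "anxiety") == 3

    def test_flat_truth_selects_one(self):
        rec = _simulate_polynomial([-2.2], 60000, seed=12)
        assert select_df_loocv(rec, "anxiety") == 1

    def test_requires_cells_or_condition(self, small_study):
        with pytest.raises(ConfigError):
            select_df_loocv(small_study)

    def test_too_few_cells_rejected(self):
        rec = _records([30, 30], [1, 0])
        with pytest.raises(EmptyDataError):
            select_df_loocv(rec, "anxiety")
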