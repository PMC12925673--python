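"""Tests for the least-squares Gaussian rate estimator and reporting."""

import numpy as np
import pytest

import idmrates as m
from idmrates.estimation import OptimizerConfig
from idmrates.exceptions import ConfigError, InvalidParameterError


@pytest.fixture(scope="module")
def exact_surface(truth):
    return truth.surface("female", "anxiety")


@pytest.fixture(scope="module")
def truth_curves(female_anxiety):
    """The truth's exact general-mortality and MRR functions."""
    return female_anxiety.general_mortality, female_anxiety.mrr


class _FlatSurface:
    """Constant prevalence with zero derivative (stationary population)."""

    def __init__(self, p):
        self.p = p

    def prevalence_and_derivative(self, t, age, sex=None, center=None):
        age = np.asarray(age, dtype=float)
        return np.full_like(age, self.p), np.zeros_like(age)


class TestEvaluationGrid:
    def test_default_grid_is_interior_integer_ages(self):
        grid = m.EvaluationGrid()
        assert grid.ages[0] == 20 and grid.ages[-1] == 73

    def test_boundary_ages_rejected(self):
        with pytest.raises(ConfigError):
            m.EvaluationGrid(ages=np.array([19.0, 20.0]))
        with pytest.raises(ConfigError):
            m.EvaluationGrid(ages=np.array([73.0, 74.0]))

    def test_non_increasing_rejected(self):
        with pytest.raises(ConfigError):
            m.EvaluationGrid(ages=np.array([30.0, 30.0]))


class TestObjective:
    def test_vanishes_at_generating_truth(self, female_anxiety, exact_surface,
                                          truth_curves):
        obj = m.rate_equation_objective(female_anxiety.rates, m.EvaluationGrid(),
                              exact_surface, *truth_curves)
        assert obj <= 1e-10

    def test_zero_rates_flat_surface_unit_mrr(self):
        params = m.RateParameterSet(
            incidence=m.GaussianRate(0.0, 45, 10),
            remission=m.GaussianRate(0.0, 45, 10),
        )
        obj = m.rate_equation_objective(params, m.EvaluationGrid(), _FlatSurface(0.1),
                              lambda a: 0.01 * np.ones_like(a),
                              lambda a: np.ones_like(a))
        assert obj == 0.0

    def test_amplitude_perturbation_increases_objective(
            self, female_anxiety, exact_surface, truth_curves):
        base = female_anxiety.rates.as_array()
        obj0 = m.rate_equation_objective(m.RateParameterSet.from_array(base),
                               m.EvaluationGrid(), exact_surface, *truth_curves)
        for bump in (1.05, 1.10, 0.90):
            theta = base.copy()
            theta[0] *= bump
            obj = m.rate_equation_objective(m.RateParameterSet.from_array(theta),
                                  m.EvaluationGrid(), exact_surface,
                                  *truth_curves)
            assert obj > obj0

    def test_invalid_width_rejected(self, exact_surface, truth_curves):
        params = m.RateParameterSet(
            incidence=m.GaussianRate(0.004, 20, 18),
            remission=m.GaussianRate(0.04, 72, 20),
        )
        object.__setattr__(params.incidence, "width", -1.0)
        with pytest.raises(InvalidParameterError):
            m.rate_equation_objective(params, m.EvaluationGrid(), exact_surface,
                            *truth_curves)


class TestEstimateRates:
    def test_noiseless_recovery_within_two_percent(
            self, female_anxiety, exact_surface, truth_curves):
        params, report = m.estimate_rates(exact_surface, *truth_curves,
                                          grid=m.EvaluationGrid())
        rel = np.abs(params.as_array() - female_anxiety.rates.as_array()) \
            / np.abs(female_anxiety.rates.as_array())
        assert np.all(rel < 0.02)
        assert report.objective <= 1e-8

    def test_started_at_truth_stays_at_truth(
            self, female_anxiety, exact_surface, truth_curves):
        cfg = OptimizerConfig(start=female_anxiety.rates)
        params, report = m.estimate_rates(exact_surface, *truth_curves,
                                          grid=m.EvaluationGrid(), config=cfg)
        assert report.objective <= 1e-12
        rel = np.abs(params.as_array() - female_anxiety.rates.as_array()) \
            / np.abs(female_anxiety.rates.as_array())
        assert np.all(rel < 1e-3)

    def test_deterministic_given_configuration(
            self, exact_surface, truth_curves):
        a, _ = m.estimate_rates(exact_surface, *truth_curves,
                                grid=m.EvaluationGrid(),
                                config=OptimizerConfig(seed=1))
        b, _ = m.estimate_rates(exact_surface, *truth_curves,
                                grid=m.EvaluationGrid(),
                                config=OptimizerConfig(seed=1))
        assert np.array_equal(a.as_array(), b.as_array())

    def test_sign_pattern_of_recovered_curves(
            self, exact_surface, truth_curves):
        """Incidence decreasing over [30,74], remission increasing over
        [19,65] — the qualitative age pattern of a young-onset remitting
        condition."""
        params, _ = m.estimate_rates(exact_surface, *truth_curves,
                                     grid=m.EvaluationGrid())
        inc = params.incidence(np.arange(30.0, 75.0))
        rem = params.remission(np.arange(19.0, 66.0))
        assert np.all(np.diff(inc) < 0)
        assert np.all(np.diff(rem) > 0)


class TestReporting:
    def test_unit_conversions(self):
        params = m.RateParameterSet(
            incidence=m.GaussianRate(0.004, 30, 15),
            remission=m.GaussianRate(0.03, 60, 15),
        )
        tab = m.rates_table(params, ages=np.array([30.0, 60.0])).table
        assert tab["incidence_per_1000py"].iloc[0] == pytest.approx(4.0)
        assert tab["remission_per_100py"].iloc[1] == pytest.approx(3.0)

    def test_negative_estimates_truncated_and_flagged(self):
        params = m.RateParameterSet(
            incidence=m.GaussianRate(-0.001, 30, 15),
            remission=m.GaussianRate(0.03, 60, 15),
        )
        res = m.rates_table(params)
        assert (res.table["incidence_per_1000py"] == 0).all()
        assert res.table["inc_truncated"].all()
        assert not res.table["rem_truncated"].any()

    def test_ci_bands_truncated_and_ordered(self):
        params = m.RateParameterSet(
            incidence=m.GaussianRate(0.004, 30, 15),
            remission=m.GaussianRate(0.03, 60, 15),
        )
        ages = np.arange(20.0, 74.0)
        bands = {
            "incidence": (np.full(ages.size, -0.001), np.full(ages.size, 0.006)),
            "remission": (np.full(ages.size, 0.01), np.full(ages.size, 0.05)),
        }
        tab = m.rates_table(params, ages=ages, bands=bands).table
        assert (tab["inc_lo"] == 0).all()
        assert tab["inc_ci_truncated"].all()
        assert (tab["inc_lo"] <= tab["inc_hi"]).all()

    def test_table_peak_is_grid_maximum(self):
        params = m.RateParameterSet(
            incidence=m.GaussianRate(0.004, 33.4, 15),
            remission=m.GaussianRate(0.03, 80, 15),
        )
        res = m.rates_table(params)
        assert res.peak_incidence[1] == res.table["incidence_per_1000py"].max()
        assert res.peak_remission[0] == 74.0

    def test_out_of_range_ages_rejected(self):
        params = m.RateParameterSet(
            incidence=m.GaussianRate(0.004, 30, 15),
            remission=m.GaussianRate(0.03, 60, 15),
        )
        with pytest.raises(ConfigError):
            m.rates_table(params, ages=np.array([10.0, 20.0]))


class TestFindPeaks:
    @pytest.mark.parametrize("loc,expected_age", [
        (80.0, 74.0),   # beyond the oldest observable age: boundary clamp
        (20.0, 20.0),   # interior mode reported as-is
        (10.0, 19.0),   # below the youngest observable age
    ])
    def test_peak_age_clamping(self, loc, expected_age):
        params = m.RateParameterSet(
            incidence=m.GaussianRate(0.004, loc, 15),
            remission=m.GaussianRate(0.03, loc, 15),
        )
        peaks = m.find_peaks(params)
        assert peaks["incidence"][0] == expected_age
        assert peaks["remission"][0] == expected_age

    def test_interior_peak_value_is_amplitude(self):
        params = m.RateParameterSet(
            incidence=m.GaussianRate(0.004, 20, 15),
            remission=m.GaussianRate(0.03, 60, 15),
        )
        peaks = m.find_peaks(params)
        assert peaks["incidence"][1] == pytest.approx(0.004)
        assert peaks["remission"][1] == pytest.approx(0.03)
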