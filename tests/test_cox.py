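"""Cox partial-likelihood estimation: analytic fixtures, symmetries,
separation handling, and the dual Standard/Multiple configuration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from svsurv import (CoxPH, EstimationError, ValidationError,
                    fit_standard_and_multiple, hazard_ratio_table, logrank)
from svsurv.cohort import CohortFrame

from .conftest import random_survival

# 4 subjects, all events at distinct times, alternating binary covariate:
# the score equation reduces to 4u^2 + u - 1 = 0 with u = exp(beta)
BETA_ANALYTIC = float(np.log((-1 + np.sqrt(17)) / 8))


class TestCoxFit:
    def test_analytic_four_subject_example(self):
        fit = CoxPH([1, 2, 3, 4], [1, 1, 1, 1], [0, 1, 0, 1]).fit()
        assert fit.converged
        assert fit.params[0] == pytest.approx(BETA_ANALYTIC, abs=1e-9)
        assert fit.hazard_ratios[0] == pytest.approx(np.exp(BETA_ANALYTIC), abs=1e-9)

    def test_grid_search_confirms_maximum(self):
        # independent check: the analytic beta maximizes the partial likelihood
        model = CoxPH([1, 2, 3, 4], [1, 1, 1, 1], [0, 1, 0, 1])
        grid = np.linspace(-3, 1, 2001)
        lls = [model.loglik([b]) for b in grid]
        assert abs(grid[int(np.argmax(lls))] - BETA_ANALYTIC) < 3e-3

    def test_loglik_at_estimate_beats_null(self):
        rng = np.random.default_rng(1)
        t, e = random_survival(rng)
        x = rng.normal(size=len(t))
        fit = CoxPH(t, e, x).fit()
        assert fit.loglik >= fit.loglik0 - 1e-12

    def test_label_swap_negates_beta(self):
        rng = np.random.default_rng(2)
        t, e = random_survival(rng)
        x = rng.integers(0, 2, len(t)).astype(float)
        if np.ptp(x) == 0:
            x[0] = 1 - x[0]
        a = CoxPH(t, e, x).fit()
        b = CoxPH(t, e, 1 - x).fit()
        assert a.params[0] == pytest.approx(-b.params[0], abs=1e-7)

    def test_covariate_rescaling(self):
        rng = np.random.default_rng(3)
        t, e = random_survival(rng)
        x = rng.normal(size=len(t))
        a = CoxPH(t, e, x).fit()
        b = CoxPH(t, e, x / 10).fit()
        assert b.params[0] == pytest.approx(10 * a.params[0], rel=1e-6)
        assert b.loglik == pytest.approx(a.loglik, abs=1e-9)
        assert b.p_values[0] == pytest.approx(a.p_values[0], abs=1e-7)

    def test_monotone_likelihood_flagged_not_raised(self):
        fit = CoxPH([1, 2], [1, 1], [0, 1]).fit()
        assert fit.monotone_likelihood and not fit.converged

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            CoxPH([1, 2, 3], [1, 1, 1], [1, 1, 1])

    def test_collinear_columns_named(self):
        rng = np.random.default_rng(4)
        t, e = random_survival(rng)
        x = rng.normal(size=len(t))
        with pytest.raises(EstimationError, match="collinear"):
            CoxPH(t, e, np.column_stack([x, 2 * x]), names=["a", "b"]).fit()

    def test_breslow_vs_efron_agree_without_ties(self):
        rng = np.random.default_rng(6)
        t = rng.exponential(5, 30)  # continuous: no ties
        e = (rng.random(30) < 0.7).astype(int)
        x = rng.normal(size=30)
        a = CoxPH(t, e, x, ties="efron").fit()
        b = CoxPH(t, e, x, ties="breslow").fit()
        assert a.params[0] == pytest.approx(b.params[0], abs=1e-8)


@given(st.integers(0, 10_000))
@settings(max_examples=40, deadline=None)
def test_score_test_equals_logrank_on_tiefree_data(seed):
    """Cox score test (binary covariate, Breslow) == log-rank chi-square."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(6, 40))
    t = rng.exponential(5.0, n)  # continuous, tie-free
    e = (rng.random(n) < 0.7).astype(int)
    g = rng.integers(0, 2, n)
    if e.sum() == 0 or np.ptp(g) == 0 or min((g == 0).sum(), (g == 1).sum()) == 0:
        return
    chi2, _ = CoxPH(t, e, g.astype(float), ties="breslow").score_test()
    lr = logrank(t[g == 0], e[g == 0], t[g == 1], e[g == 1])
    assert chi2 == pytest.approx(lr.chi_square, abs=1e-9)


def test_lifelines_cross_check():
    """Second, independent implementation agrees on a moderate instance."""
    lifelines = pytest.importorskip("lifelines")
    rng = np.random.default_rng(7)
    n = 120
    x = np.column_stack([rng.integers(0, 2, n), rng.normal(size=n)]).astype(float)
    lam = 0.3 * np.exp(-0.5 * x[:, 0] + 0.3 * x[:, 1])
    lat = rng.exponential(1 / lam)
    t = np.minimum(lat, 8.0)
    e = (lat <= 8.0).astype(int)
    fit = CoxPH(t, e, x, names=["g", "z"]).fit()
    df = pd.DataFrame({"t": t, "e": e, "g": x[:, 0], "z": x[:, 1]})
    cf = lifelines.CoxPHFitter().fit(df, "t", "e")
    assert np.allclose(fit.params, cf.params_.values, atol=1e-4)
    assert np.allclose(fit.bse, cf.standard_errors_.values, atol=1e-4)


def _toy_cohort(sv_counts, seed=0, n=40):
    rng = np.random.default_rng(seed)
    arm = np.arange(n) % 2
    frame = pd.DataFrame({
        "patient_id": [f"P{i}" for i in range(n)],
        "arm": arm,
        "event": (rng.random(n) < 0.8).astype(int),
        "time": rng.exponential(3, n) + 0.01,
        "age": rng.normal(55, 8, n),
        "sv_count": sv_counts,
    })
    frame["carrier"] = frame["sv_count"] >= 1
    frame["excluded"] = False
    if frame["event"].sum() == 0:
        frame.loc[0, "event"] = 1
    return CohortFrame(frame=frame, target_gene="G", time_unit="years",
                       covariates=["age"], min_sv=1)


class TestStandardAndMultiple:
    def test_all_three_configurations_fit(self):
        sv = np.array([0, 0, 1, 3] * 10)
        fits = fit_standard_and_multiple(_toy_cohort(sv), covariates=["age"])
        assert fits["standard"].names == ["arm", "carrier", "age"]
        assert fits["multiple:carrier"].names == ["arm", "age"]
        assert fits["multiple:noncarrier"].names == ["arm", "age"]

    def test_no_carriers_marks_subset_not_estimable(self):
        fits = fit_standard_and_multiple(_toy_cohort(np.zeros(40, dtype=int)))
        assert isinstance(fits["multiple:carrier"], str)
        assert "not estimable" in fits["multiple:carrier"]

    def test_unknown_covariate_lists_available(self):
        with pytest.raises(ValidationError, match="age"):
            fit_standard_and_multiple(_toy_cohort(np.array([0, 1] * 20)),
                                      covariates=["bmi"])


class TestHazardRatioTable:
    def test_percent_effect_of_two_percent_hazard_ratio(self):
        # a fit whose age coefficient is exactly ln(1.02): +2% risk per year
        fit = CoxPH([1, 2, 3, 4], [1, 1, 1, 1], [0, 1, 0, 1], names=["age"]).fit()
        fit.params = np.array([np.log(1.02)])
        fit.hazard_ratios = np.exp(fit.params)
        tab = hazard_ratio_table(fit)
        assert tab.loc[0, "HR"] == 1.02
        assert tab.loc[0, "percent_effect"] == "+2%"

    def test_null_coefficient_renders_as_identity(self):
        fit = CoxPH([1, 2, 3, 4], [1, 1, 1, 1], [0, 1, 0, 1]).fit()
        fit.params = np.array([0.0])
        fit.hazard_ratios = np.array([1.0])
        tab = hazard_ratio_table(fit)
        assert tab.loc[0, "HR"] == 1.0
        assert tab.loc[0, "percent_effect"] == "0%"

    def test_separation_warning_marker(self):
        fit = CoxPH([1, 2], [1, 1], [0, 1]).fit()
        tab = hazard_ratio_table(fit)
        assert (tab["warning"] == "separation").all()
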