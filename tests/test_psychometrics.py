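"""Psychometric fitting, perceptual metrics, and the mixed model."""

import math

import numpy as np
import pandas as pd
import pytest

from _generators import STIMULI_MMS, make_choice_table
from splitbelt.psychometrics import (
    LN3,
    PsychometricFit,
    fit_full_model,
    fit_logistic,
    fit_logistic_subject,
    fit_mixed_logistic,
    jnd,
    perception_metrics,
    pse,
    weber_fraction,
)


def _fit(beta0, beta1, se0=0.05, se1=1.0):
    return PsychometricFit(
        beta0=beta0,
        beta1=beta1,
        cov=np.diag([se0**2, se1**2]),
        loglik=0.0,
        n_trials=100,
    )


class TestMetrics:
    @pytest.mark.parametrize(
        "beta0,beta1,expected_mms",
        [(0.0, 22.1, 0.0), (-0.1, 26.0, 3.846), (-0.136, 24.7, 5.506)],
    )
    def test_pse_arithmetic(self, beta0, beta1, expected_mms):
        est, _ = pse(_fit(beta0, beta1))
        assert 1000 * est == pytest.approx(expected_mms, abs=0.001)

    @pytest.mark.parametrize(
        "beta1,expected_mms",
        [(math.log(3.0), 1000.0), (22.1, 49.71), (26.0, 42.26)],
    )
    def test_jnd_arithmetic(self, beta1, expected_mms):
        est, _ = jnd(_fit(0.0, beta1))
        assert 1000 * est == pytest.approx(expected_mms, abs=0.01)

    def test_pse_ci_propagates_beta0_with_fixed_slope(self):
        fit = _fit(-0.1, 26.0, se0=0.05)
        est, (lo, hi) = pse(fit)
        z = 1.959963984540054
        assert lo == pytest.approx(-(-0.1 + z * 0.05) / 26.0)
        assert hi == pytest.approx(-(-0.1 - z * 0.05) / 26.0)
        assert lo < est < hi

    def test_jnd_ci_is_skewed(self):
        fit = _fit(0.0, 22.1, se1=2.0)
        est, (lo, hi) = jnd(fit)
        z = 1.959963984540054
        assert lo == pytest.approx(LN3 / (22.1 + z * 2.0))
        assert hi == pytest.approx(LN3 / (22.1 - z * 2.0))
        assert (hi - est) > (est - lo)  # skew toward large JND

    def test_jnd_ci_unbounded_when_slope_ci_touches_zero(self):
        _, (_, hi) = jnd(_fit(0.0, 1.0, se1=2.0))
        assert hi == np.inf

    def test_metrics_undefined_for_nonpositive_slope(self):
        for f in (pse, jnd):
            with pytest.raises(ValueError):
                f(_fit(0.0, -1.0))

    @pytest.mark.parametrize(
        "jnd_ms,expected_pct", [(0.0497, 4.7), (0.0444, 4.2), (0.0, 0.0)]
    )
    def test_weber_fraction(self, jnd_ms, expected_pct):
        assert weber_fraction(jnd_ms, 1.05) == pytest.approx(expected_pct, abs=0.05)

    def test_weber_fraction_rejects_nonpositive_speed(self):
        with pytest.raises(ValueError):
            weber_fraction(0.05, 0.0)

    def test_significant_bias_iff_ci_excludes_zero(self):
        biased = perception_metrics(_fit(-1.0, 26.0, se0=0.05))
        unbiased = perception_metrics(_fit(0.01, 26.0, se0=0.05))
        assert biased.significant_bias and not unbiased.significant_bias


class TestFitLogistic:
    def test_parameter_recovery_5000_trials(self):
        rng = np.random.default_rng(42)
        dv = np.tile(STIMULI_MMS / 1000.0, 385)[:5000]
        p = 1.0 / (1.0 + np.exp(-(0.0 + 22.1 * dv)))
        y = (rng.random(5000) < p).astype(float)
        fit = fit_logistic(dv, y)
        assert fit.converged and not fit.separation
        assert fit.beta1 == pytest.approx(22.1, rel=0.10)
        assert abs(fit.beta0) < 0.1

    def test_flat_choices_give_zero_slope(self):
        dv = np.repeat(STIMULI_MMS / 1000.0, 2)
        y = np.tile([0.0, 1.0], STIMULI_MMS.size)
        fit = fit_logistic(dv, y)
        assert abs(fit.beta1) < 1e-6
        assert abs(fit.beta0) < 1e-6

    def test_separation_fallback_keeps_estimates_finite(self):
        dv = np.array([-0.3, -0.2, -0.1, 0.1, 0.2, 0.3])
        y = (dv > 0).astype(float)
        fit = fit_logistic(dv, y)
        assert fit.separation
        assert np.isfinite(fit.beta0) and np.isfinite(fit.beta1)
        assert fit.beta1 > 0

    def test_requires_two_stimulus_levels(self):
        with pytest.raises(ValueError):
            fit_logistic(np.zeros(10), np.ones(10))

    def test_shift_equivariance_of_pse_and_invariance_of_jnd(self):
        rng = np.random.default_rng(3)
        dv = np.tile(STIMULI_MMS / 1000.0, 100)
        p = 1.0 / (1.0 + np.exp(-(0.3 + 20.0 * dv)))
        y = (rng.random(dv.size) < p).astype(float)
        shift = 0.05
        fit0 = fit_logistic(dv, y)
        fit1 = fit_logistic(dv + shift, y)
        assert fit1.beta1 == pytest.approx(fit0.beta1, rel=1e-6)
        assert jnd(fit1)[0] == pytest.approx(jnd(fit0)[0], rel=1e-6)
        assert pse(fit1)[0] == pytest.approx(pse(fit0)[0] + shift, abs=1e-8)

    def test_subject_lookup(self, small_cohort):
        table, _ = small_cohort
        fit = fit_logistic_subject(table, 1)
        assert fit.n_trials > 100
        with pytest.raises(KeyError):
            fit_logistic_subject(table, 999)


class TestMixedLogistic:
    def test_matches_lme4_reference(self):
        """Laplace-ML fit reproduces lme4::glmer (1.1-37, nAGQ=1) on a
        frozen synthetic dataset (reference values computed once with R)."""
        table = make_choice_table(3, 20, beta1_sd=6.0)
        g = fit_mixed_logistic(table)
        b0, se0, _ = g.coef("intercept")
        b1, se1, p1 = g.coef("dv")
        assert b0 == pytest.approx(0.056448, abs=0.002)
        assert b1 == pytest.approx(21.7237, rel=0.005)
        assert se0 == pytest.approx(0.095261, rel=0.05)
        assert se1 == pytest.approx(1.66649, rel=0.05)
        assert g.re_sd[0] == pytest.approx(0.358771, rel=0.02)
        assert g.re_sd[1] == pytest.approx(6.32766, rel=0.02)
        assert g.loglik == pytest.approx(-1214.9109, abs=0.1)
        assert p1 < 1e-10

    def test_homogeneous_subjects_shrink_random_effects(self):
        table = make_choice_table(5, 15, beta0_sd=0.0, beta1_sd=0.0)
        g = fit_mixed_logistic(table)
        assert g.re_sd[0] < 0.15
        assert g.re_sd[1] < 2.0
        # fixed effects agree with the pooled MLE in the no-heterogeneity case
        from splitbelt.psychometrics import _choice_data

        dv, y = _choice_data(table)
        pooled = fit_logistic(dv, y)
        assert abs(g.coef("dv")[0] - pooled.beta1) < 2 * g.coef("dv")[1]
        assert abs(g.coef("intercept")[0] - pooled.beta0) < 2 * g.coef("intercept")[1]

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            fit_mixed_logistic(make_choice_table(0, 1))


class TestFullModel:
    def test_planted_laterality_detected(self):
        """A strong |dv| term (3 logits per m/s) is flagged significant in
        at least 4 of 5 simulated cohorts."""
        hits = 0
        for k in range(5):
            g = fit_full_model(make_choice_table(200 + k, 20, beta4=3.0))
            if g.coef("abs_dv")[2] < 0.05:
                hits += 1
        assert hits >= 4

    def test_missing_columns_rejected(self):
        t = make_choice_table(0, 3).drop(columns=["block"])
        with pytest.raises(ValueError, match="block"):
            fit_full_model(t)

    def test_constant_zero_stimulus_rejected(self):
        t = make_choice_table(0, 3).assign(delta_v_mms=0)
        with pytest.raises(ValueError, match="degenerate"):
            fit_full_model(t)

    def test_reports_all_exogenous_terms(self):
        g = fit_full_model(make_choice_table(1, 8))
        assert g.names == [
            "intercept",
            "dv",
            "dv_prev",
            "dv:block2",
            "dv:block3",
            "abs_dv",
        ]
        assert np.all((g.pvalues >= 0) & (g.pvalues <= 1))
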