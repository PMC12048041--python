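"""Closed-form DDM quantities and the first-passage simulator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import splitbelt.ddm as ddm
from splitbelt.ddm import (
    DDMParams,
    DriftLink,
    SimulationOverflowError,
    choice_probability,
    expected_decision_time,
    expected_rt,
    simulate_trial,
    simulate_trials,
)


class TestChoiceProbability:
    def test_zero_drift_is_chance(self):
        assert choice_probability(DDMParams(r=0.0, sigma=0.5)) == 0.5

    def test_ln3_drift_gives_75_percent(self):
        # drift such that 2|r|/sigma^2 = ln 3, signed toward the left barrier
        r = -0.5 * 0.25 * math.log(3.0)
        assert choice_probability(DDMParams(r=r, sigma=0.5)) == pytest.approx(
            0.75, abs=1e-12
        )

    def test_drift_away_from_left_barrier(self):
        p = choice_probability(DDMParams(r=0.5, sigma=0.5))
        assert p == pytest.approx(1.0 / (1.0 + math.exp(4.0)), rel=1e-12)

    @given(
        z=st.floats(-30, 30),  # 2r/sigma^2; beyond ~36 the float saturates
        sigma=st.floats(0.1, 2.0),
    )
    @settings(deadline=None, max_examples=50)
    def test_left_and_right_sum_to_one(self, z, sigma):
        r = 0.5 * z * sigma**2
        p = choice_probability(DDMParams(r=r, sigma=sigma))
        q = choice_probability(DDMParams(r=-r, sigma=sigma))
        assert 0.0 < p < 1.0
        assert p + q == pytest.approx(1.0, abs=1e-15)

    @given(mu=st.floats(-20, 20))
    @settings(deadline=None, max_examples=100)
    def test_logistic_identity(self, mu):
        """p_left of the walk equals logistic(mu) under the drift link."""
        link = DriftLink(beta0=mu, beta1=0.0, sigma=0.5, t_nd=0.0)
        p = choice_probability(link.params(0.0))
        expected = 1.0 / (1.0 + math.exp(-mu)) if mu > -700 else 0.0
        assert p == pytest.approx(expected, rel=1e-12)

    def test_scale_invariance(self):
        p1 = choice_probability(DDMParams(r=0.3, sigma=0.5, a=1.0))
        p2 = choice_probability(DDMParams(r=0.6, sigma=1.0, a=2.0))
        assert p1 == pytest.approx(p2, rel=1e-14)

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            DDMParams(r=0.0, sigma=0.0)
        with pytest.raises(ValueError):
            DDMParams(r=0.0, sigma=-1.0)


class TestExpectedDecisionTime:
    def test_zero_drift_limit(self):
        assert expected_decision_time(
            DDMParams(r=0.0, sigma=0.5)
        ) == pytest.approx(4.0, rel=1e-12)

    def test_closed_form_value(self):
        got = expected_decision_time(DDMParams(r=0.5, sigma=0.5))
        assert got == pytest.approx(2.0 * math.tanh(2.0), rel=1e-12)

    def test_continuity_at_zero_drift(self):
        near = expected_decision_time(DDMParams(r=1e-8, sigma=0.5))
        assert abs(near - 4.0) < 1e-6

    def test_even_in_drift_sign(self):
        up = expected_decision_time(DDMParams(r=0.7, sigma=0.4))
        dn = expected_decision_time(DDMParams(r=-0.7, sigma=0.4))
        assert up == pytest.approx(dn, rel=1e-14)

    def test_scale_invariance(self):
        t1 = expected_decision_time(DDMParams(r=0.5, sigma=0.5, a=1.0))
        t2 = expected_decision_time(DDMParams(r=1.0, sigma=1.0, a=2.0))
        assert t1 == pytest.approx(t2, rel=1e-14)


class TestExpectedRT:
    LINK = DriftLink(beta0=0.0, beta1=22.1, sigma=0.5, t_nd=0.9)

    def test_null_stimulus_value(self):
        assert expected_rt(self.LINK, 0.0) == pytest.approx(4.9, rel=1e-12)

    def test_even_when_unbiased(self):
        assert expected_rt(self.LINK, 0.3) == pytest.approx(
            expected_rt(self.LINK, -0.3), rel=1e-14
        )

    def test_infinite_evidence_limit(self):
        link = DriftLink(beta0=0.0, beta1=22.1, sigma=0.5, t_nd=0.0)
        assert expected_rt(link, 1e6) < 1e-3

    def test_peak_at_minus_beta0_over_beta1(self):
        link = DriftLink(beta0=-0.12, beta1=22.0, sigma=0.5, t_nd=0.9)
        peak = -link.beta0 / link.beta1
        grid = np.linspace(-0.3, 0.3, 601)
        rts = np.asarray(expected_rt(link, grid))
        assert abs(grid[np.argmax(rts)] - peak) < 2e-3
        # strictly decreasing in |mu|
        mus = np.abs(link.beta0 + link.beta1 * grid)
        order = np.argsort(mus)
        assert np.all(np.diff(rts[order]) <= 1e-12)


class TestSimulator:
    def test_deterministic_drift_limit(self):
        rng = np.random.default_rng(0)
        out = simulate_trial(DDMParams(r=10.0, sigma=1e-6, t_nd=0.0), rng)
        assert out.decision_time == pytest.approx(0.1, abs=2e-3)
        # positive drift runs to the upper barrier, labelled "right"
        assert out.choice == "right"
        assert out.rt == out.decision_time

    def test_zero_drift_hit_fraction(self):
        rng = np.random.default_rng(1)
        n = 20_000
        left, _ = simulate_trials(DDMParams(r=0.0, sigma=0.5), n, rng)
        assert abs(left.mean() - 0.5) < 3.0 * math.sqrt(0.25 / n)

    def test_mean_decision_time_matches_closed_form(self):
        rng = np.random.default_rng(2)
        n = 20_000
        _, td = simulate_trials(DDMParams(r=0.5, sigma=0.5), n, rng)
        se = td.std() / math.sqrt(n)
        assert abs(td.mean() - 2.0 * math.tanh(2.0)) < 3.0 * se

    def test_censoring_returns_nan(self):
        rng = np.random.default_rng(3)
        left, td = simulate_trials(
            DDMParams(r=0.0, sigma=0.5), 500, rng, max_time=1.0
        )
        assert np.isnan(td).any()
        assert np.nanmax(td) <= 1.0 + 1e-12

    def test_step_cap_raises(self, monkeypatch):
        monkeypatch.setattr(ddm, "MAX_STEPS", 100)
        rng = np.random.default_rng(4)
        with pytest.raises(SimulationOverflowError):
            simulate_trials(DDMParams(r=0.0, sigma=0.05), 4, rng)

    def test_invalid_dt_rejected(self):
        with pytest.raises(ValueError):
            simulate_trials(DDMParams(r=0.0, sigma=0.5), 1, np.random.default_rng(0), dt=0.0)


class TestDriftLink:
    def test_drift_sign_convention(self):
        """Positive logit means left is favoured: negative walk drift."""
        link = DriftLink(beta0=0.0, beta1=22.1, sigma=0.5, t_nd=0.9)
        assert link.drift(0.1) < 0
        p = choice_probability(link.params(0.1))
        assert p == pytest.approx(1.0 / (1.0 + math.exp(-2.21)), rel=1e-12)

    def test_validation(self):
        with pytest.raises(ValueError):
            DriftLink(0.0, 22.1, sigma=-0.5)
        with pytest.raises(ValueError):
            DriftLink(0.0, 22.1, sigma=0.5, t_nd=-1.0)
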