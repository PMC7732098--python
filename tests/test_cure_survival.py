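"""Weibull mixture cure model: closed forms, likelihood, fitting, grid,
AIC selection and Kaplan-Meier."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from escapement import (
    FitResult,
    ModelSpec,
    ParameterSet,
    build_survival_data,
    density_function,
    enumerate_grid,
    fit_model,
    kaplan_meier,
    log_likelihood,
    select_by_aic,
    spec_by_id,
    survival_function,
)
from escapement.cure_survival import count_free_parameters


def _survival_frame(rows):
    """rows of (gap_time, event, rank_group, video, fish_id)."""
    return pd.DataFrame(rows, columns=["gap_time", "event", "rank_group",
                                       "video", "fish_id"])


class TestClosedForms:
    def test_survival_at_zero_is_one(self):
        assert survival_function(0.0, 0.6, 1.0, 0.88) == pytest.approx(1.0)
        assert survival_function(0.0, 2.0, 0.7, 0.3) == pytest.approx(1.0)

    def test_point_evaluation(self):
        # 0.12 + 0.88 * exp(-0.6)
        assert survival_function(1.0, 0.6, 1.0, 0.88) == pytest.approx(
            0.12 + 0.88 * math.exp(-0.6), abs=1e-12)

    def test_asymptote_is_cure_fraction(self):
        assert survival_function(1e3, 0.6, 1.0, 0.88) == pytest.approx(
            0.12, abs=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            survival_function(-0.1, 0.6, 1.0, 0.88)

    def test_density_exponential_case(self):
        assert density_function(1.0, 1.0, 1.0, 1.0) == pytest.approx(
            math.exp(-1.0), abs=1e-12)

    def test_density_zero_when_fully_cured(self):
        assert density_function(3.0, 0.6, 1.3, 0.0) == 0.0

    def test_density_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            density_function(0.0, 1.0, 1.0, 1.0)

    @pytest.mark.parametrize("alpha,gamma,pi", [
        (0.6, 1.0, 0.88), (0.29, 1.5, 0.5), (2.0, 0.7, 1.0)])
    def test_density_integrates_to_attempting_fraction(self, alpha, gamma, pi):
        val, err = quad(density_function, 0, 100, args=(alpha, gamma, pi),
                        limit=200)
        assert val == pytest.approx(pi, abs=1e-6)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(t=st.floats(0.0, 50.0), dt=st.floats(1e-3, 5.0),
           alpha=st.floats(0.05, 5.0), gamma=st.floats(0.3, 3.0),
           pi=st.floats(0.0, 1.0))
    def test_survival_monotone_and_bounded(self, t, dt, alpha, gamma, pi):
        s0 = survival_function(t, alpha, gamma, pi)
        s1 = survival_function(t + dt, alpha, gamma, pi)
        assert 1.0 - pi - 1e-12 <= s1 <= s0 <= 1.0 + 1e-12

    def test_gamma_one_is_exponential_to_machine_precision(self):
        t = np.linspace(0, 20, 101)
        np.testing.assert_allclose(
            survival_function(t, 0.37, 1.0, 1.0), np.exp(-0.37 * t),
            rtol=0, atol=1e-15)

    def test_density_is_negative_survival_derivative(self):
        # central finite difference of S vs f on a grid
        alpha, gamma, pi = 0.6, 1.4, 0.88
        t = np.linspace(0.1, 10, 50)
        h = 1e-5
        num = -(survival_function(t + h, alpha, gamma, pi)
                - survival_function(t - h, alpha, gamma, pi)) / (2 * h)
        np.testing.assert_allclose(
            num, density_function(t, alpha, gamma, pi), atol=1e-6)


class TestLogLikelihood:
    def test_censored_row_under_zero_pi_contributes_nothing(self):
        data = _survival_frame([(5.0, 0, "R1", "V1", "f1")])
        params = ParameterSet.from_values(1.0, 1.0, 1e-12)
        spec = spec_by_id("M10")
        # pi ~ 0 => S(T) ~ 1 => logL ~ 0 (to the logit guard's resolution)
        assert log_likelihood(data, spec, params) == pytest.approx(0.0,
                                                                   abs=1e-6)

    def test_single_exponential_event(self):
        data = _survival_frame([(1.0, 1, "R1", "V1", "f1")])
        params = ParameterSet.from_values(1.0, 1.0, 1.0)
        spec = spec_by_id("M11")
        # pi at the logit guard is 1 - 2e-9; log f = -1 + log(pi)
        assert log_likelihood(data, spec, params) == pytest.approx(-1.0,
                                                                   abs=1e-6)

    def test_mixed_rows_equal_per_row_arithmetic(self):
        # independent brute-force oracle, term by term in plain math
        alpha, gamma, pi = 0.55, 1.3, 0.8
        rows = [(0.7, 1, "R1", "V1", "f1"), (1.9, 0, "R2", "V1", "f1"),
                (0.3, 1, "R1", "V1", "f2"), (2.5, 1, "R2", "V1", "f2"),
                (4.0, 0, "R3plus", "V1", "f2")]
        expected = 0.0
        for t, event, *_ in rows:
            z = (alpha * t) ** gamma
            if event:
                expected += math.log(
                    pi * gamma * alpha ** gamma * t ** (gamma - 1)
                    * math.exp(-z))
            else:
                expected += math.log(1 - pi + pi * math.exp(-z))
        data = _survival_frame(rows)
        params = ParameterSet.from_values(alpha, gamma, pi)
        got = log_likelihood(data, spec_by_id("M10"), params)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_event_under_zero_pi_is_minus_infinity(self):
        data = _survival_frame([(1.0, 1, "R1", "V1", "f1")])
        params = ParameterSet(
            {"alpha": {"baseline": 0.0}, "gamma": {"baseline": 0.0},
             "pi": {"baseline": -1e9}})
        ll = log_likelihood(data, spec_by_id("M10"), params)
        # guard keeps pi > 0 so the result is finite but dominated by log pi
        assert ll < -15

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            log_likelihood(_survival_frame([]), spec_by_id("M10"),
                           ParameterSet.from_values(1, 1, 1))


class TestGrid:
    def test_grid_has_32_distinct_specs(self):
        specs = enumerate_grid()
        assert len(specs) == 32
        assert len({s.id for s in specs}) == 32
        assert len({(s.rank_on, s.video_on, s.gamma_fixed_one)
                    for s in specs}) == 32

    def test_named_rows(self):
        m8 = spec_by_id("M8")
        assert m8.rank_on == {"alpha"}
        assert m8.gamma_fixed_one and not m8.video_on
        m10 = spec_by_id("M10")
        assert not m10.rank_on and not m10.video_on
        assert not m10.gamma_fixed_one
        m20 = spec_by_id("M20")
        assert m20.video_on == {"alpha"} and m20.gamma_fixed_one
        m26 = spec_by_id("M26")
        assert m26.rank_on == m26.video_on == {"alpha"}
        assert not m26.gamma_fixed_one

    def test_gamma_fixed_excludes_gamma_covariates(self):
        with pytest.raises(ValueError):
            ModelSpec("bad", rank_on=frozenset({"gamma"}),
                      gamma_fixed_one=True)

    @pytest.mark.parametrize("mid,k", [
        ("M10", 3),   # alpha, gamma, pi baselines
        ("M11", 2),   # gamma fixed
        ("M8", 4),    # 3 alpha (rank) + pi
        ("M0", 9),    # rank on all three: 3 * 3
        ("M22", 12),  # rank + video on all three: 3 * 4
        ("M20", 3),   # alpha base + V2, pi
        ("M30", 5),   # alpha base + R2 + R3plus + V2, pi
    ])
    def test_free_parameter_counts(self, mid, k):
        assert count_free_parameters(spec_by_id(mid)) == k


class TestFitting:
    def test_closed_form_exponential_mle(self):
        # uncensored exponential gaps, gamma = 1, pi driven to its
        # boundary: alpha_hat must equal events / sum(gaps)
        rng = np.random.default_rng(11)
        t = rng.exponential(1 / 0.7, size=500)
        data = _survival_frame(
            [(x, 1, "R1", "V1", f"f{i}") for i, x in enumerate(t)])
        fit = fit_model(data, spec_by_id("M11"), n_starts=3, seed=0,
                        epsilon=1e-12)
        alpha_hat, gamma_hat, pi_hat = fit.estimates.effective()
        mle = len(t) / t.sum()
        assert alpha_hat == pytest.approx(mle, rel=1e-3)
        assert gamma_hat == 1.0
        assert pi_hat > 0.999

    def test_aic_and_k_invariants(self, fixture_survival):
        fit = fit_model(fixture_survival, spec_by_id("M8"), n_starts=3,
                        seed=0)
        assert fit.k == 4
        assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.log_likelihood)
        assert fit.converged

    def test_degenerate_level_flagged(self):
        data = _survival_frame(
            [(1.0, 1, "R1", "V1", "f1"), (2.0, 0, "R2", "V1", "f1"),
             (1.5, 0, "R1", "V1", "f2")])
        with pytest.warns(UserWarning, match="no events"):
            fit = fit_model(data, spec_by_id("M8"), n_starts=1, seed=0)
        assert fit.degenerate

    def test_rank_effect_recovery_single_seed(self):
        # simulation from the rank-on-alpha exponential truth with
        # realistic short-window censoring
        from escapement import SimulationConfig, simulate_ethogram
        cfg = SimulationConfig(n_fish=1200, sequence_duration=3600.0,
                               simulate_states=False)
        obs, _, attempts = simulate_ethogram(cfg, seed=41)
        data = build_survival_data(obs, attempts)
        assert len(data) >= 2000
        fit = fit_model(data, spec_by_id("M8"), n_starts=5, seed=0)
        truth = {"R1": 0.6, "R2": 0.29, "R3plus": 0.38}
        for rank, alpha_true in truth.items():
            alpha_hat, _, pi_hat = fit.estimates.effective(rank)
            assert alpha_hat == pytest.approx(alpha_true, rel=0.15)
        assert pi_hat == pytest.approx(0.88, rel=0.15)


class TestSelection:
    def test_aic_definition(self):
        spec = spec_by_id("M10")
        f = FitResult(spec, ParameterSet.from_values(1, 1, 1), -100.0, 4,
                      208.0, True, 1)
        assert f.aic == 2 * f.k - 2 * f.log_likelihood

    def test_ordering_and_ties(self):
        spec = spec_by_id("M10")
        ps = ParameterSet.from_values(1, 1, 1)
        a = FitResult(spec, ps, -367.415, 4, 742.83, True, 1)
        b = FitResult(spec_by_id("M4"), ps, -367.415, 5, 744.83, True, 1)
        ranked = select_by_aic([b, a])
        assert ranked[0].aic == pytest.approx(742.83)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            select_by_aic([])


class TestKaplanMeier:
    def test_uncensored_equals_empirical(self):
        data = _survival_frame(
            [(1.0, 1, "R1", "V1", "a"), (2.0, 1, "R1", "V1", "b"),
             (3.0, 1, "R1", "V1", "c")])
        curve = kaplan_meier(data)["all"]
        got = dict(zip(curve.times, curve.survival))
        assert got[0.0] == pytest.approx(1.0)
        assert got[1.0] == pytest.approx(2 / 3)
        assert got[2.0] == pytest.approx(1 / 3)
        assert got[3.0] == pytest.approx(0.0)

    def test_all_censored_stays_at_one(self):
        data = _survival_frame(
            [(1.0, 0, "R1", "V1", "a"), (2.0, 0, "R1", "V1", "b")])
        curve = kaplan_meier(data)["all"]
        assert np.allclose(curve.survival, 1.0)
        assert list(curve.censor_times) == [1.0, 2.0]

    def test_hand_product_limit_with_censoring(self):
        # times {1+, 2, 3}: S(2) = 1 * (1 - 1/2), S(3) = 0
        data = _survival_frame(
            [(1.0, 0, "R1", "V1", "a"), (2.0, 1, "R1", "V1", "b"),
             (3.0, 1, "R1", "V1", "c")])
        curve = kaplan_meier(data)["all"]
        got = dict(zip(curve.times, curve.survival))
        assert got[2.0] == pytest.approx(0.5)
        assert got[3.0] == pytest.approx(0.0)

    def test_monotone_from_one_with_at_risk(self, fixture_survival):
        curves = kaplan_meier(fixture_survival, group_by="rank_group")
        assert set(curves) == {"R1", "R2", "R3plus"}
        for curve in curves.values():
            assert curve.survival[0] == pytest.approx(1.0)
            assert np.all(np.diff(curve.survival) <= 1e-12)
            assert np.all(np.diff(curve.at_risk) <= 0)

    def test_large_sample_matches_model_survival(self):
        # uncensored exponential sample: KM tracks S(t) = exp(-alpha t)
        rng = np.random.default_rng(5)
        t = rng.exponential(1 / 0.6, size=4000)
        data = _survival_frame(
            [(x, 1, "R1", "V1", f"f{i}") for i, x in enumerate(t)])
        curve = kaplan_meier(data)["all"]
        grid_idx = np.searchsorted(curve.times, [0.5, 1.0, 2.0])
        for i, tq in zip(grid_idx, [0.5, 1.0, 2.0]):
            assert curve.survival[i] == pytest.approx(
                math.exp(-0.6 * tq), abs=0.03)
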