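"""Frailty density, conditional/marginal likelihood oracles, fit behaviour."""

import numpy as np
import pytest
from scipy.special import gammaln

from jointpredict.cohort import Cohort
from jointpredict.joint_model import (
    FitConfig,
    JointParams,
    QuadratureRule,
    fit_joint_model,
    gamma_frailty_density,
    lcv,
    log_frailty_integral,
    marginal_loglik,
    posterior_frailty_mean,
    subject_conditional_loglik,
)
from jointpredict.simulate import SimulationConfig, simulate_cohort
from conftest import constant_joint_params, make_subject, recovery_truth


def closed_form_log_integral(theta, p, c):
    """log int u^p e^{-c u} g(u; theta) du, by the gamma integral."""
    inv = 1.0 / theta
    return gammaln(inv + p) - gammaln(inv) - inv * np.log(theta) - (inv + p) * np.log(inv + c)


class TestGammaFrailtyDensity:
    def test_exponential_special_case(self):
        assert gamma_frailty_density(1.0, 1.0) == pytest.approx(np.exp(-1.0))

    @pytest.mark.parametrize("theta", [0.25, 1.0, 4.0])
    def test_moments_by_quadrature(self, theta):
        rule = QuadratureRule(theta)
        assert rule.integrate(lambda u: np.ones_like(u)) == pytest.approx(1.0, abs=1e-8)
        assert rule.integrate(lambda u: u) == pytest.approx(1.0, abs=1e-7)
        assert rule.integrate(lambda u: (u - 1) ** 2) == pytest.approx(theta, rel=1e-6)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            gamma_frailty_density(1.0, -0.5)
        with pytest.raises(ValueError):
            gamma_frailty_density(-1.0, 0.5)


class TestConditionalLoglik:
    def test_pure_survival(self, base_cov):
        # no events, u=1, constant hazards a, b, follow-up t -> -(a+b) t
        params = constant_joint_params(rate_rec=0.12, rate_death=0.07)
        s = make_subject("x", (), 9.0, 0)
        assert subject_conditional_loglik(s, params, 1.0) == pytest.approx(
            -(0.12 + 0.07) * 9.0, rel=1e-9
        )

    def test_equals_poisson_plus_cox_pieces_at_u1(self):
        # u=1, alpha=1: contribution is the sum of the two independent
        # conditional log-likelihoods (recurrent Poisson-process + death)
        params = constant_joint_params(rate_rec=0.3, rate_death=0.1)
        s = make_subject("x", (1.0, 4.0), 7.5, 1)
        rec_ll = 2 * np.log(0.3) - 0.3 * 7.5
        death_ll = np.log(0.1) - 0.1 * 7.5
        assert subject_conditional_loglik(s, params, 1.0) == pytest.approx(
            rec_ll + death_ll, rel=1e-9
        )

    @pytest.mark.parametrize("alpha", [0.5, 1.0, 2.0])
    def test_frailty_scaling_pattern(self, alpha):
        params = constant_joint_params(rate_rec=0.3, rate_death=0.1, alpha=alpha)
        s = make_subject("x", (2.0,), 6.0, 1)
        l1 = subject_conditional_loglik(s, params, 1.0)
        l2 = subject_conditional_loglik(s, params, 2.0)
        lam_r, lam_d = 0.3 * 6.0, 0.1 * 6.0
        expected = 1 * np.log(2) - lam_r + alpha * np.log(2) - (2**alpha - 1) * lam_d
        assert l2 - l1 == pytest.approx(expected, rel=1e-9)

    def test_invalid_frailty(self, constant_params):
        with pytest.raises(ValueError):
            subject_conditional_loglik(make_subject("x"), constant_params, 0.0)


class TestMarginalLoglik:
    @pytest.mark.parametrize("theta", [0.25, 0.5, 1.0, 2.0])
    def test_closed_form_alpha_one(self, theta):
        # quadrature path vs analytic gamma integral on random subjects
        rng = np.random.default_rng(8)
        p = rng.integers(0, 6, 25).astype(float)
        c = rng.uniform(0, 4, 25)
        d = rng.uniform(0, 4, 25)
        quad = log_frailty_integral(theta, p, c, d, 1.0, 128, exact_gamma=False)
        ref = closed_form_log_integral(theta, p, c + d)
        np.testing.assert_allclose(quad, ref, rtol=0, atol=1e-6)

    def test_degenerate_frailty_matches_no_frailty_likelihood(self):
        params_tiny = constant_joint_params(rate_rec=0.3, rate_death=0.1, theta=1e-6)
        cohort = Cohort(
            [
                make_subject("a", (1.0, 3.0), 8.0, 1),
                make_subject("b", (), 12.0, 0),
                make_subject("c", (2.5,), 5.0, 1),
            ]
        )
        got = marginal_loglik(cohort, params_tiny)
        # u == 1 likelihood
        want = sum(subject_conditional_loglik(s, params_tiny, 1.0) for s in cohort)
        assert got == pytest.approx(want, abs=1e-4)

    def test_monte_carlo_oracle_alpha_2p5(self, base_cov):
        params = constant_joint_params(rate_rec=0.25, rate_death=0.08, alpha=2.5, theta=1.0)
        cohort = Cohort(
            [make_subject("a", (1.5, 4.0), 9.0, 1), make_subject("b", (), 11.0, 0)]
        )
        got = marginal_loglik(cohort, params)
        rng = np.random.default_rng(123)
        u = rng.gamma(1.0, 1.0, 1_000_000)
        want = 0.0
        for s in cohort:
            lam_r, lam_d = 0.25 * s.followup_time, 0.08 * s.followup_time
            N, delta = s.n_relapses, s.death_indicator
            vals = (
                u ** (N + delta * 2.5)
                * 0.25**N
                * 0.08**delta
                * np.exp(-u * lam_r - u**2.5 * lam_d)
            )
            m, se = vals.mean(), vals.std() / 1000.0
            want += np.log(m)
            per = marginal_loglik(Cohort([s]), params)
            assert abs(np.exp(per) - m) < 3 * se
        assert got == pytest.approx(want, abs=1e-2)

    def test_mismatched_rule_theta_rejected(self, constant_params, toy_cohort):
        with pytest.raises(ValueError):
            marginal_loglik(toy_cohort, constant_params, QuadratureRule(theta=3.0))


class TestFit:
    def test_refit_is_deterministic(self):
        cohort = simulate_cohort(recovery_truth(), SimulationConfig(n_subjects=250, seed=9))
        cfg = FitConfig(n_knots=5, compute_se=False, n_nodes=16)
        f1 = fit_joint_model(cohort, cfg)
        f2 = fit_joint_model(cohort, cfg)
        assert np.array_equal(f1.beta_rec, f2.beta_rec)
        assert np.array_equal(f1.hazard_rec.eta, f2.hazard_rec.eta)
        assert f1.theta == f2.theta and f1.alpha == f2.alpha

    def test_recovery_within_three_se(self, recovery_cohort):
        truth = recovery_truth()
        fit = fit_joint_model(recovery_cohort, FitConfig())
        assert fit.converged
        for est, tru, se in zip(fit.beta_rec, truth.beta_rec, fit.se["beta_rec"]):
            assert abs(est - tru) < 3 * se
        for est, tru, se in zip(fit.beta_death, truth.beta_death, fit.se["beta_death"]):
            assert abs(est - tru) < 3 * se
        assert abs(fit.theta - truth.theta) < 3 * fit.se["theta"]
        assert abs(fit.alpha - truth.alpha) < 3 * fit.se["alpha"]

    def test_posterior_frailty_mean_monotone_in_relapse_count(self, recovery_cohort):
        fit = fit_joint_model(
            recovery_cohort, FitConfig(compute_se=False, n_knots=5, n_nodes=16)
        )
        assert fit.alpha > 0
        means = [
            posterior_frailty_mean(
                make_subject("x", tuple(np.linspace(1, 7, j)), 10.0, 0), fit
            )
            for j in range(4)
        ]
        assert all(b > a for a, b in zip(means, means[1:]))

    def test_warns_without_events(self, base_cov):
        cohort = Cohort([make_subject("a", (), 5.0, 0), make_subject("b", (), 7.0, 0)])
        with pytest.warns(UserWarning, match="identified"):
            fit_joint_model(cohort, FitConfig(n_knots=4, compute_se=False, max_iter=5, n_nodes=8))


class TestLcv:
    def test_zero_penalty_is_aic_like(self):
        cohort = simulate_cohort(recovery_truth(), SimulationConfig(n_subjects=150, seed=10))
        cfg = FitConfig(n_knots=4, kappa_rec=0.0, kappa_death=0.0, compute_se=False,
                        n_nodes=16)
        fit = fit_joint_model(cohort, cfg)
        val = lcv(fit)
        n_params = 2 * 4 + 2 * 7 + 2
        expected = (n_params - fit.loglik) / len(cohort)
        assert val == pytest.approx(expected, rel=1e-3)

    def test_invariant_to_subject_order(self):
        cohort = simulate_cohort(recovery_truth(), SimulationConfig(n_subjects=120, seed=12))
        cfg = FitConfig(n_knots=4, compute_se=False, n_nodes=16)
        fit = fit_joint_model(cohort, cfg)
        v1 = lcv(fit)
        shuffled = Cohort(list(reversed(cohort.subjects)))
        fit2 = fit_joint_model(shuffled, cfg)
        v2 = lcv(fit2)
        assert v1 == pytest.approx(v2, rel=1e-5)
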