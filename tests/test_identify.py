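"""KKT-residual identification, closed-form effort ratio, regressions, AICc."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from oie import (
    EffectiveNoise,
    IdentificationConfig,
    aicc,
    aicc_compare,
    alternate_fit,
    fit_haptic_regression,
    fit_noise_pso,
    fit_visual_regression,
    kkt_residual,
    optimal_coactivation,
    prediction_error_gradient,
    solve_gamma,
)

FAST = IdentificationConfig(seed=0, restarts=2, iterations=150, swarm_size=40,
                            grid_points=6)


def make_table(noise: EffectiveNoise, gamma: float, u_max: float = 4.0) -> np.ndarray:
    return np.array(
        [
            [optimal_coactivation(sv, sh, gamma, u_max=u_max) for sh in noise.sigma_h]
            for sv in noise.sigma_v
        ]
    )


class TestKktResidual:
    def test_zero_at_generating_parameters(self, identified_noise, gamma_star,
                                           stationary_table):
        res = kkt_residual(identified_noise.as_vector(), gamma_star, stationary_table)
        assert res == pytest.approx(0.0, abs=1e-15)

    def test_positive_after_perturbation(self, identified_noise, gamma_star,
                                         stationary_table):
        xi = identified_noise.as_vector()
        xi[3] *= 1.1
        assert kkt_residual(xi, gamma_star, stationary_table) > 1e-8

    def test_matches_term_by_term_oracle(self, identified_noise, stationary_table):
        # independent 9-term evaluation at an off-optimum point
        xi = identified_noise.as_vector() * 0.9
        gamma = 1.7
        total = 0.0
        for i, sv in enumerate(xi[:3]):
            for j, sh in enumerate(xi[3:]):
                u = stationary_table[i, j]
                total += (float(prediction_error_gradient(u, sv, sh)) + gamma * u) ** 2
        assert kkt_residual(xi, gamma, stationary_table) == pytest.approx(
            total, rel=1e-12
        )

    def test_rejects_out_of_bounds(self, stationary_table):
        with pytest.raises(ValueError):
            kkt_residual(np.full(6, 80.0), 2.26, stationary_table)


class TestSolveGamma:
    def test_single_condition_ratio(self):
        u = 0.4
        sv, sh = 30.0, 6.0
        table = np.full((3, 3), u)
        noise = EffectiveNoise((sv,) * 3, (sh,) * 3)
        expected = -float(prediction_error_gradient(u, sv, sh)) / u
        assert solve_gamma(table, noise) == pytest.approx(expected, rel=1e-12)

    def test_recovers_generating_effort_ratio(self, identified_noise, gamma_star,
                                              stationary_table):
        assert solve_gamma(stationary_table, identified_noise) == pytest.approx(
            gamma_star, abs=1e-6
        )

    def test_noise_bias_is_first_order(self, identified_noise, gamma_star,
                                       stationary_table, rng):
        # the bias from a fixed zero-mean perturbation direction scales
        # linearly with its amplitude
        direction = rng.normal(size=(3, 3))
        direction -= direction.mean()
        g0 = solve_gamma(stationary_table, identified_noise)
        d1 = solve_gamma(stationary_table + 1e-3 * direction, identified_noise) - g0
        d2 = solve_gamma(stationary_table + 5e-4 * direction, identified_noise) - g0
        assert d1 == pytest.approx(2 * d2, rel=0.05)

    def test_all_zero_table_rejected(self, identified_noise):
        with pytest.raises(ValueError):
            solve_gamma(np.zeros((3, 3)), identified_noise)


class TestNoisePso:
    def test_round_trip_recovers_noise(self, identified_noise, gamma_star,
                                       stationary_table):
        noise, info = fit_noise_pso(
            stationary_table, gamma_star, IdentificationConfig(seed=1)
        )
        rel = np.abs(noise.as_vector() - identified_noise.as_vector()) / (
            identified_noise.as_vector()
        )
        assert np.all(rel < 0.02)
        assert info["consistent"]

    def test_matches_one_dimensional_golden_section(self, identified_noise,
                                                    gamma_star, stationary_table):
        # fix five parameters at truth: the remaining problem is 1-D and
        # solvable by scalar minimization
        truth = identified_noise.as_vector()

        def objective(x):
            xi = truth.copy()
            xi[2] = x
            return float(kkt_residual(xi, gamma_star, stationary_table))

        oracle = minimize_scalar(objective, bounds=(0, 70), method="bounded",
                                 options={"xatol": 1e-10}).x
        noise, _ = fit_noise_pso(stationary_table, gamma_star,
                                 IdentificationConfig(seed=2, restarts=3))
        assert noise.as_vector()[2] == pytest.approx(oracle, abs=1e-3)

    def test_stays_inside_bounds_and_reproducible(self, stationary_table, gamma_star):
        a, ia = fit_noise_pso(stationary_table, gamma_star, FAST)
        b, ib = fit_noise_pso(stationary_table, gamma_star, FAST)
        assert np.array_equal(a.as_vector(), b.as_vector())
        assert ia["residual"] == ib["residual"]
        for x, _ in ia["restarts"]:
            assert np.all(np.asarray(x) >= 0.0) and np.all(np.asarray(x) <= 70.0)

    def test_consistent_relabeling_permutes_recovery(self, identified_noise,
                                                     gamma_star, stationary_table):
        flipped = stationary_table[::-1].copy()
        noise, _ = fit_noise_pso(flipped, gamma_star, FAST)
        assert np.allclose(
            noise.sigma_v, identified_noise.sigma_v[::-1], rtol=1e-3
        )


class TestAlternateFit:
    def test_joint_round_trip_on_identified_values(self, identified_noise,
                                                   gamma_star, stationary_table):
        result = alternate_fit(stationary_table, IdentificationConfig(seed=3))
        assert result.gamma_star == pytest.approx(gamma_star, rel=0.02)
        rel = np.abs(
            result.effective_noise.as_vector() - identified_noise.as_vector()
        ) / identified_noise.as_vector()
        assert np.all(rel < 0.02)
        assert result.converged
        assert result.kkt_residual < 1e-10

    @pytest.mark.parametrize("draw", range(8))
    def test_round_trip_identifiability_random_parameters(self, draw):
        # random generating parameters with distinct levels; the fit must
        # recover them from the noise-free stationary-point table
        rng = np.random.default_rng(1000 + draw)
        sv = np.sort(rng.uniform(5, 70, 3))
        sh = np.sort(rng.uniform(5, 70, 3))
        while np.any(np.diff(sv) < 2) or np.any(np.diff(sh) < 2):
            sv = np.sort(rng.uniform(5, 70, 3))
            sh = np.sort(rng.uniform(5, 70, 3))
        gamma = rng.uniform(0.5, 5.0)
        noise = EffectiveNoise(tuple(sv), tuple(sh))
        table = make_table(noise, gamma)
        result = alternate_fit(table, IdentificationConfig(seed=draw, restarts=3))
        assert result.gamma_star == pytest.approx(gamma, rel=0.02)
        rel = np.abs(result.effective_noise.as_vector() - np.r_[sv, sh]) / np.r_[sv, sh]
        assert np.all(rel < 0.02)

    def test_sequential_mode_with_known_gamma(self, identified_noise, gamma_star,
                                              stationary_table):
        result = alternate_fit(
            stationary_table, FAST, gamma0=gamma_star, sequential=True
        )
        assert result.rounds == 1
        assert result.gamma_star == pytest.approx(gamma_star, rel=1e-4)


class TestNoiseRegressions:
    def test_visual_logistic_exact_recovery(self):
        sigma_c = np.array([0.0, 0.5, 1.5, 3.0])
        true = (2.0, 50.0)
        sigma_v = -true[0] + true[1] / (1 + np.exp(-sigma_c))
        alpha_v, beta_v, rss = fit_visual_regression(sigma_c, sigma_v)
        assert alpha_v == pytest.approx(true[0], abs=1e-6)
        assert beta_v == pytest.approx(true[1], abs=1e-6)
        assert rss < 1e-12

    def test_visual_fit_on_identified_deviations(self, identified_noise):
        # mm-scale cloud deviations saturate the logistic, so the best
        # fit is reported with its residual; it must be at least as good
        # as any other positive parameter pair, and monotone data give
        # beta_v > alpha_v
        sigma_c = np.array([0.0, 21.32, 52.78])
        sigma_v = np.array(identified_noise.sigma_v)
        alpha_v, beta_v, rss = fit_visual_regression(sigma_c, sigma_v)
        assert beta_v > alpha_v > 0
        reference = -1.21 + 66.18 / (1 + np.exp(-sigma_c))
        assert rss <= np.sum((reference - sigma_v) ** 2) + 1e-9

    def test_haptic_quadratic_exact_interpolation(self):
        sigma_p = np.array([0.0, 0.1, 0.2])
        sigma_h = 4.0 + 5.0 * sigma_p + 30.0 * sigma_p**2
        coeffs = fit_haptic_regression(sigma_p, sigma_h)
        assert coeffs == pytest.approx((4.0, 5.0, 30.0), rel=1e-9)

    def test_haptic_interpolation_of_identified_levels(self, identified_noise):
        # interpolating the three rounded effective deviations lands near,
        # but not exactly on, the separately identified coefficients
        sigma_p = np.array([0.0, 0.08, 0.19])
        alpha_p, beta_p, delta_p = fit_haptic_regression(
            sigma_p, np.array(identified_noise.sigma_h)
        )
        assert alpha_p == pytest.approx(5.06, abs=1e-9)
        assert beta_p == pytest.approx(6.84, rel=0.1)
        assert delta_p == pytest.approx(41.68, rel=0.1)


class TestAicc:
    def test_fewer_parameters_win_at_equal_rss(self):
        cmp = aicc_compare(rss_oie=0.05, k_oie=7, rss_tem=0.05, k_tem=2, n=9)
        assert cmp.aicc_tem < cmp.aicc_oie
        assert cmp.preferred == "TEM"

    def test_vanishing_rss_dominates(self):
        cmp = aicc_compare(rss_oie=1e-12, k_oie=7, rss_tem=0.5, k_tem=2, n=9)
        assert cmp.preferred == "OIE"

    def test_hand_computed_value(self):
        # n ln(rss/n) + 2k + 2k(k+1)/(n-k-1) at n=9, k=2, rss=0.05
        expected = 9 * np.log(0.05 / 9) + 4 + 12 / 6
        assert aicc(0.05, 2, 9) == pytest.approx(expected, rel=1e-12)
        assert aicc(0.0, 2, 9) == -np.inf

    def test_small_sample_guard(self):
        with pytest.raises(ValueError):
            aicc(0.1, 8, 9)
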