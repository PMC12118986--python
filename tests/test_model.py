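"""Core OIE model: noise laws, fused prediction error, cost and optimum."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oie import (
    ComplianceNoiseCoeffs,
    EffectiveNoise,
    NoiseMapParams,
    adapt_coactivation,
    blind_haptic_prediction,
    cost,
    cost_gradient,
    haptic_noise_map,
    optimal_coactivation,
    predict_surface,
    prediction_error,
    prediction_error_gradient,
    sigma_kappa,
    sigma_t_squared,
    visual_noise_map,
)

NOISE_LATTICE = [
    (sv, sh) for sv in (5.0, 30.64, 63.66, 65.30) for sh in (3.0, 5.06, 7.85, 20.0)
]


class TestNoiseLaws:
    def test_compliance_noise_reference_values(self):
        # u = 0 gives c0 + c1; u = 0.5 frozen from direct evaluation of
        # 5.18 + 49.65 * exp(-3.055)
        assert sigma_kappa(0.0) == pytest.approx(54.83)
        assert sigma_kappa(0.5) == pytest.approx(7.5196430862, rel=1e-9)

    def test_compliance_noise_is_decreasing_with_asymptote(self):
        u = np.linspace(0, 5, 200)
        sk = sigma_kappa(u)
        assert np.all(np.diff(sk) < 0)
        assert sigma_kappa(100.0) == pytest.approx(5.18, abs=1e-12)

    def test_compliance_noise_rejects_negative_u(self):
        with pytest.raises(ValueError):
            sigma_kappa(-0.1)

    def test_sigma_t_squared_components(self):
        # sigma_v = 0 leaves only the compliance term; the V0 value at
        # u = 0 is 30.64^2 + 54.83^2
        assert sigma_t_squared(0.3, 0.0) == pytest.approx(sigma_kappa(0.3) ** 2)
        assert sigma_t_squared(0.0, 30.64) == pytest.approx(
            30.64**2 + 54.83**2, rel=1e-12
        )
        assert sigma_t_squared(50.0, 10.0) == pytest.approx(10.0**2 + 5.18**2, rel=1e-6)

    def test_visual_map_logistic_shape(self):
        p = NoiseMapParams()
        assert visual_noise_map(0.0, p) == pytest.approx(-p.alpha_v + p.beta_v / 2)
        # saturation: for mm-scale deviations the logistic is flat
        assert visual_noise_map(21.32, p) == pytest.approx(
            p.beta_v - p.alpha_v, abs=1e-6
        )
        assert visual_noise_map(1000.0, p) == pytest.approx(p.beta_v - p.alpha_v)

    @pytest.mark.parametrize(
        "sigma_p,expected",
        [(0.0, 5.05), (0.08, 5.86), (0.19, 7.85)],
    )
    def test_haptic_map_reproduces_identified_levels(self, sigma_p, expected):
        # the identified quadratic evaluated at the physical perturbation
        # amplitudes reproduces the effective haptic deviations to 2 dp
        assert round(float(haptic_noise_map(sigma_p)), 2) == expected


class TestPredictionError:
    @pytest.mark.parametrize("sv,sh", NOISE_LATTICE)
    def test_gamma_bounds(self, sv, sh):
        u = np.linspace(0.0, 2.0, 50)
        g = prediction_error(u, sv, sh)
        assert np.all(g >= 0)
        assert np.all(g <= np.minimum(sigma_t_squared(u, sv), sh**2) + 1e-12)

    def test_symmetric_channels_halve_variance(self):
        # sigma_t = sigma_h = sigma gives fused variance sigma^2 / 2
        u = 0.4
        sh = float(np.sqrt(sigma_t_squared(u, 20.0)))
        assert prediction_error(u, 20.0, sh) == pytest.approx(sh**2 / 2)

    def test_monotone_in_both_noises(self):
        u = 0.3
        g_v = [prediction_error(u, sv, 6.0) for sv in (10, 20, 40, 60)]
        g_h = [prediction_error(u, 30.0, sh) for sh in (3, 5, 8, 12)]
        assert np.all(np.diff(g_v) > 0)
        assert np.all(np.diff(g_h) > 0)

    @pytest.mark.parametrize("sv,sh", NOISE_LATTICE)
    def test_gradient_is_negative(self, sv, sh):
        u = np.geomspace(1e-4, 2.0, 30)
        assert np.all(prediction_error_gradient(u, sv, sh) < 0)


class TestCost:
    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        u=st.floats(0.01, 1.9),
        sv=st.floats(5.0, 70.0),
        sh=st.floats(1.0, 20.0),
        gamma=st.floats(0.3, 8.0),
    )
    def test_gradient_matches_central_difference(self, u, sv, sh, gamma):
        h = 1e-6 * max(u, 1.0)
        numeric = (cost(u + h, sv, sh, gamma) - cost(u - h, sv, sh, gamma)) / (2 * h)
        analytic = cost_gradient(u, sv, sh, gamma)
        scale = max(abs(numeric), abs(analytic), 1e-3)
        assert abs(analytic - numeric) / scale < 1e-5

    def test_cost_at_zero_is_prediction_error(self):
        assert cost(0.0, 30.0, 6.0, 2.0) == pytest.approx(
            prediction_error(0.0, 30.0, 6.0)
        )

    def test_large_gamma_makes_gradient_positive(self):
        assert cost_gradient(0.5, 30.0, 6.0, 1e4) > 0


class TestOptimum:
    def test_matches_dense_grid_oracle(self, identified_noise, gamma_star):
        # independent oracle: brute-force minimization of the cost on a
        # 1e-4-step grid
        for sv in identified_noise.sigma_v:
            for sh in identified_noise.sigma_h:
                grid = np.arange(0.0, 2.0, 1e-4)
                oracle = grid[np.argmin(cost(grid, sv, sh, gamma_star))]
                assert optimal_coactivation(sv, sh, gamma_star) == pytest.approx(
                    oracle, abs=1e-3
                )

    def test_stationary_point_has_zero_gradient(self):
        u = optimal_coactivation(30.64, 5.06, 2.26)
        assert abs(cost_gradient(u, 30.64, 5.06, 2.26)) < 1e-8

    def test_unique_sign_change_on_lattice(self):
        u = np.geomspace(1e-6, 2.0, 400)
        for sv, sh in NOISE_LATTICE:
            for gamma in (0.5, 2.26, 5.0):
                signs = np.sign(cost_gradient(u, sv, sh, gamma))
                changes = np.sum(np.abs(np.diff(signs)) > 0)
                assert changes <= 1

    def test_large_gamma_drives_optimum_to_zero(self):
        assert optimal_coactivation(30.0, 6.0, 1e6) < 1e-4

    def test_raises_when_interval_too_small(self):
        with pytest.raises(ValueError):
            optimal_coactivation(30.0, 6.0, 1e-9, u_max=0.5)

    def test_adaptation_converges_to_stationary_point(self):
        sv, sh, gamma, lr = 30.64, 5.86, 2.26, 0.01
        u_star = optimal_coactivation(sv, sh, gamma)
        for u0 in (0.0, 1.5):
            traj = adapt_coactivation(u0, sv, sh, gamma, lr, n_steps=3000)
            assert traj[-1] == pytest.approx(u_star, abs=10 * lr)
            # monotone approach from either side
            tail = traj[traj != u0]
            assert np.all(np.diff(np.abs(tail - u_star)) <= 1e-12)

    def test_adaptation_starting_at_optimum_stays(self):
        u_star = optimal_coactivation(30.64, 5.86, 2.26)
        traj = adapt_coactivation(u_star, 30.64, 5.86, 2.26, 0.01, n_steps=100)
        assert np.allclose(traj, u_star, atol=1e-8)

    def test_adaptation_rejects_bad_learning_rate(self):
        with pytest.raises(ValueError):
            adapt_coactivation(0.1, 30.0, 6.0, 2.26, learning_rate=0.0)


class TestSurface:
    def test_monotone_in_visual_and_haptic_noise(self, identified_noise, gamma_star):
        table = predict_surface(identified_noise, gamma_star).values
        assert np.all(np.diff(table, axis=0) < 0)  # decreasing with visual noise
        assert np.all(np.diff(table, axis=1) > 0)  # increasing with haptic noise

    def test_normalized_surface_spans_unit_interval(self, identified_noise, gamma_star):
        table = predict_surface(identified_noise, gamma_star, normalize=True).values
        assert table.min() == pytest.approx(0.0)
        assert table.max() == pytest.approx(1.0)
        assert np.all(table >= 0)

    def test_partial_derivative_signs_by_finite_differences(self, gamma_star):
        sv_axis = np.linspace(20, 70, 6)
        sh_axis = np.linspace(3, 10, 6)
        u = np.array(
            [[optimal_coactivation(sv, sh, gamma_star) for sh in sh_axis] for sv in sv_axis]
        )
        assert np.all(np.diff(u, axis=0) <= 0)
        assert np.all(np.diff(u, axis=1) >= 0)


class TestBlindLimit:
    @pytest.mark.parametrize("sh", [3.0, 5.06, 7.85, 15.0])
    def test_zero_for_any_haptic_noise(self, sh):
        assert blind_haptic_prediction(sh) == 0.0
        assert blind_haptic_prediction(sh, gamma=0.7) == 0.0

    def test_agrees_with_numeric_large_visual_noise_limit(self):
        for sh in (5.06, 7.85):
            assert optimal_coactivation(1e6, sh, 2.26) == pytest.approx(0.0, abs=1e-3)


class TestParameterValidation:
    def test_positive_constraints(self):
        with pytest.raises(ValueError):
            ComplianceNoiseCoeffs(c0=-1.0)
        with pytest.raises(ValueError):
            EffectiveNoise((0.0, 1.0, 2.0), (1.0, 2.0, 3.0))
        with pytest.raises(ValueError):
            NoiseMapParams(alpha_v=-0.5)
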