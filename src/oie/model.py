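"""Optimal information and effort (OIE) model of muscle coactivation.

During tracking with visual and haptic feedback the central nervous
system can raise joint stiffness by coactivating antagonist muscles.
Stiffening couples the hand more tightly to the internally planned
trajectory, which helps when the visual target is sharp but injects
visual noise into the movement when it is blurry; relaxing instead
filters the visual channel and lets accurate haptic guidance dominate.

The model formalizes this trade-off. The hand's deviation from the
motion plan has standard deviation

    sigma_t(u)^2 = sigma_v^2 + sigma_kappa(u)^2,

where ``sigma_v`` is the effective visual noise and ``sigma_kappa(u)``
the compliance-related deviation, decreasing exponentially with
coactivation ``u``. Fusing this visually guided estimate with a haptic
channel of deviation ``sigma_h`` by maximum-likelihood weighting gives
the prediction error (fused variance)

    Gamma(u) = sigma_t(u)^2 sigma_h^2 / (sigma_t(u)^2 + sigma_h^2),

and coactivation adapts by gradient descent on the cost

    V(u) = Gamma(u) + (gamma / 2) u^2,

with effort ratio ``gamma > 0``. The stationary point ``u*`` of V is
the model's predicted coactivation for a noise condition: it decreases
with visual noise and increases with haptic noise, and vanishes in the
blind limit (sigma_v -> infinity) for any haptic noise level.

Units: ``u`` is normalized coactivation (the per-participant min-max
rescaled trial mean, dimensionless); noise deviations are in the
effective model units in which the compliance-noise law was identified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .containers import CoactivationTable

__all__ = [
    "ComplianceNoiseCoeffs",
    "EffectiveNoise",
    "NoiseMapParams",
    "OieParams",
    "IDENTIFIED_NOISE",
    "IDENTIFIED_GAMMA",
    "sigma_kappa",
    "sigma_t_squared",
    "visual_noise_map",
    "haptic_noise_map",
    "prediction_error",
    "prediction_error_gradient",
    "cost",
    "cost_gradient",
    "adapt_coactivation",
    "optimal_coactivation",
    "predict_surface",
    "predict_grid",
    "blind_haptic_prediction",
]


@dataclass(frozen=True)
class ComplianceNoiseCoeffs:
    """Coefficients of the compliance-noise law
    sigma_kappa(u) = c0 + c1 * exp(-c2 * u).

    Defaults are the values identified for wrist tracking: the
    deviation falls from c0 + c1 at full relaxation to the asymptote c0
    at high coactivation, with rate c2 per unit of normalized
    coactivation.
    """

    c0: float = 5.18
    c1: float = 49.65
    c2: float = 6.11

    def __post_init__(self) -> None:
        if min(self.c0, self.c1, self.c2) <= 0:
            raise ValueError("compliance-noise coefficients must be positive")


@dataclass(frozen=True)
class EffectiveNoise:
    """Effective noise deviations per level, sharp -> weak -> strong.

    These are the deviations as experienced internally, identified from
    behaviour rather than set physically.
    """

    sigma_v: tuple[float, float, float]
    sigma_h: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.sigma_v) != 3 or len(self.sigma_h) != 3:
            raise ValueError("three visual and three haptic levels required")
        if min(*self.sigma_v, *self.sigma_h) <= 0:
            raise ValueError("effective noise deviations must be positive")

    def as_vector(self) -> np.ndarray:
        """Pack as (sv0, sv1, sv2, sh0, sh1, sh2)."""
        return np.array([*self.sigma_v, *self.sigma_h], dtype=float)

    @classmethod
    def from_vector(cls, xi: np.ndarray) -> "EffectiveNoise":
        xi = np.asarray(xi, dtype=float)
        if xi.shape != (6,):
            raise ValueError("expected six noise parameters")
        return cls(tuple(xi[:3]), tuple(xi[3:]))


#: Effective noise deviations identified from the nine-condition
#: wrist-tracking study (visual: sharp/weak/strong cloud; haptic:
#: none/weak/strong perturbation) and the matching effort ratio.
IDENTIFIED_NOISE = EffectiveNoise(
    sigma_v=(30.64, 63.66, 65.30), sigma_h=(5.06, 5.86, 7.85)
)
IDENTIFIED_GAMMA = 2.26


@dataclass(frozen=True)
class NoiseMapParams:
    """Parameters mapping physical to effective noise.

    Visual: logistic saturation sigma_v = -alpha_v + beta_v / (1 + exp(-sigma_c))
    of the cloud angular deviation sigma_c (mm). Haptic: quadratic
    sigma_h = alpha_p + beta_p * sigma_p + delta_p * sigma_p^2 of the
    perturbation amplitude sigma_p (Nm). Defaults are the regression
    coefficients identified from the study's effective noise values.
    """

    alpha_v: float = 1.21
    beta_v: float = 66.18
    alpha_p: float = 5.05
    beta_p: float = 6.84
    delta_p: float = 41.68

    def __post_init__(self) -> None:
        if min(self.alpha_v, self.beta_v, self.alpha_p, self.beta_p, self.delta_p) <= 0:
            raise ValueError("noise-map parameters must be positive")


@dataclass(frozen=True)
class OieParams:
    """Free parameters of the OIE model.

    gamma weights quadratic effort against fused prediction error.
    learning_rate scales the gradient step of :func:`adapt_coactivation`
    (the stationary point does not depend on it). u_max bounds the
    coactivation search interval; 2.0 leaves room above the normalized
    range [0, 1].
    """

    gamma: float = IDENTIFIED_GAMMA
    learning_rate: float = 0.01
    u_max: float = 2.0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("effort ratio gamma must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.u_max <= 0:
            raise ValueError("u_max must be positive")


def _check_nonneg_u(u) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    if np.any(u < 0):
        raise ValueError("coactivation u must be non-negative")
    return u


def sigma_kappa(u, coeffs: ComplianceNoiseCoeffs = ComplianceNoiseCoeffs()):
    """Compliance-noise deviation c0 + c1*exp(-c2*u).

    Strictly decreasing in u with asymptote c0.
    """
    u = _check_nonneg_u(u)
    return coeffs.c0 + coeffs.c1 * np.exp(-coeffs.c2 * u)


def sigma_t_squared(u, sigma_v, coeffs: ComplianceNoiseCoeffs = ComplianceNoiseCoeffs()):
    """Variance of hand deviation from the motion plan: sigma_v^2 + sigma_kappa(u)^2."""
    return np.square(sigma_v) + np.square(sigma_kappa(u, coeffs))


def visual_noise_map(sigma_c, params: NoiseMapParams = NoiseMapParams()):
    """Effective visual noise from cloud angular deviation (mm).

    Logistic in sigma_c, saturating at beta_v - alpha_v.
    """
    sigma_c = np.asarray(sigma_c, dtype=float)
    return -params.alpha_v + params.beta_v / (1.0 + np.exp(-sigma_c))


def haptic_noise_map(sigma_p, params: NoiseMapParams = NoiseMapParams()):
    """Effective haptic noise from perturbation amplitude (Nm), quadratic."""
    sigma_p = np.asarray(sigma_p, dtype=float)
    return params.alpha_p + params.beta_p * sigma_p + params.delta_p * sigma_p**2


def prediction_error(
    u, sigma_v, sigma_h, coeffs: ComplianceNoiseCoeffs = ComplianceNoiseCoeffs()
):
    """Fused visuo-haptic prediction error Gamma(u).

    Variance of the maximum-likelihood combination of the visually
    guided estimate (variance sigma_t^2(u)) and the haptic channel
    (variance sigma_h^2); bounded by min(sigma_t^2, sigma_h^2).
    """
    st2 = sigma_t_squared(u, sigma_v, coeffs)
    sh2 = np.square(sigma_h)
    return st2 * sh2 / (st2 + sh2)


def prediction_error_gradient(
    u, sigma_v, sigma_h, coeffs: ComplianceNoiseCoeffs = ComplianceNoiseCoeffs()
):
    """d(Gamma)/du, negative for all valid inputs.

    Uses d(sigma_t^2)/du = -2 sigma_kappa c1 c2 exp(-c2 u).
    """
    u = _check_nonneg_u(u)
    st2 = sigma_t_squared(u, sigma_v, coeffs)
    sh2 = np.square(sigma_h)
    weight = sh2 / (st2 + sh2)
    dst2 = -2.0 * sigma_kappa(u, coeffs) * coeffs.c1 * coeffs.c2 * np.exp(-coeffs.c2 * u)
    return np.square(weight) * dst2


def cost(
    u,
    sigma_v,
    sigma_h,
    gamma: float,
    coeffs: ComplianceNoiseCoeffs = ComplianceNoiseCoeffs(),
):
    """OIE cost V(u) = Gamma(u) + (gamma/2) u^2."""
    u = _check_nonneg_u(u)
    return prediction_error(u, sigma_v, sigma_h, coeffs) + 0.5 * gamma * np.square(u)


def cost_gradient(
    u,
    sigma_v,
    sigma_h,
    gamma: float,
    coeffs: ComplianceNoiseCoeffs = ComplianceNoiseCoeffs(),
):
    """dV/du = dGamma/du + gamma*u."""
    return prediction_error_gradient(u, sigma_v, sigma_h, coeffs) + gamma * np.asarray(
        u, dtype=float
    )


def adapt_coactivation(
    u0: float,
    sigma_v: float,
    sigma_h: float,
    gamma: float,
    learning_rate: float = 0.01,
    n_steps: int = 1000,
    coeffs: ComplianceNoiseCoeffs = ComplianceNoiseCoeffs(),
) -> np.ndarray:
    """Gradient-descent trajectory u_{k+1} = max(u_k - lr * dV/du, 0).

    Returns the length ``n_steps + 1`` iterate sequence starting at
    ``u0``. For a small enough step the iterates converge monotonically
    to the stationary point of the cost.
    """
    if learning_rate <= 0:
        raise ValueError("learning_rate must be positive")
    u = float(_check_nonneg_u(u0))
    traj = np.empty(n_steps + 1)
    traj[0] = u
    for k in range(n_steps):
        u = max(u - learning_rate * float(cost_gradient(u, sigma_v, sigma_h, gamma, coeffs)), 0.0)
        traj[k + 1] = u
    return traj


def optimal_coactivation(
    sigma_v: float,
    sigma_h: float,
    gamma: float,
    u_max: float = 2.0,
    coeffs: ComplianceNoiseCoeffs = ComplianceNoiseCoeffs(),
) -> float:
    """Stationary coactivation u*: the root of dV/du on (0, u_max].

    The gradient at u = 0 is dGamma/du(0) < 0, so u* > 0 always; the
    bracket is scanned at 64 log-spaced points for the sign change and
    refined by Brent's method. Raises if the gradient is still negative
    at ``u_max`` (interval too small).
    """
    if min(sigma_v, sigma_h, gamma) <= 0:
        raise ValueError("sigma_v, sigma_h and gamma must be positive")

    def g(u: float) -> float:
        return float(cost_gradient(u, sigma_v, sigma_h, gamma, coeffs))

    lo = 0.0
    g_lo = g(lo)
    if g_lo >= 0:  # effort dominates everywhere (possible only numerically)
        return 0.0
    # log-spaced scan guards against the exponential's flatness at large u
    grid = np.concatenate(([0.0], np.geomspace(1e-6, u_max, 64)))
    vals = cost_gradient(grid, sigma_v, sigma_h, gamma, coeffs)
    sign_change = np.nonzero((vals[:-1] < 0) & (vals[1:] >= 0))[0]
    if len(sign_change) == 0:
        raise ValueError(
            f"cost gradient negative on the whole interval [0, {u_max}]; "
            "increase u_max"
        )
    i = sign_change[0]
    return float(brentq(g, grid[i], grid[i + 1], xtol=1e-10, rtol=1e-12))


def predict_surface(
    noise: EffectiveNoise,
    gamma: float,
    normalize: bool = False,
    u_max: float = 2.0,
    coeffs: ComplianceNoiseCoeffs = ComplianceNoiseCoeffs(),
) -> CoactivationTable:
    """Predicted coactivation u* for the 3x3 noise conditions.

    With ``normalize=True`` the nine predictions are min-max rescaled
    onto [0, 1] for comparison with normalized observations.
    """
    values = np.array(
        [
            [
                optimal_coactivation(sv, sh, gamma, u_max, coeffs)
                for sh in noise.sigma_h
            ]
            for sv in noise.sigma_v
        ]
    )
    table = CoactivationTable(values, value_name="u_star")
    return table.normalized() if normalize else table


def predict_grid(
    sigma_v_grid,
    sigma_h_grid,
    gamma: float,
    u_max: float = 2.0,
    coeffs: ComplianceNoiseCoeffs = ComplianceNoiseCoeffs(),
) -> np.ndarray:
    """u* on a dense (sigma_v, sigma_h) grid for surface visualization."""
    sigma_v_grid = np.atleast_1d(np.asarray(sigma_v_grid, dtype=float))
    sigma_h_grid = np.atleast_1d(np.asarray(sigma_h_grid, dtype=float))
    return np.array(
        [
            [optimal_coactivation(sv, sh, gamma, u_max, coeffs) for sh in sigma_h_grid]
            for sv in sigma_v_grid
        ]
    )


def blind_haptic_prediction(sigma_h: float, gamma: float = IDENTIFIED_GAMMA) -> float:
    """Predicted coactivation without vision: always zero.

    As sigma_v -> infinity the fused error Gamma(u) -> sigma_h^2, which
    no longer depends on coactivation, so only the effort term remains
    and the optimum is u* = 0 regardless of the haptic noise level.
    Implemented analytically rather than via a huge sigma_v to avoid
    overflow.
    """
    if sigma_h <= 0 or gamma <= 0:
        raise ValueError("sigma_h and gamma must be positive")
    return 0.0
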