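"""Synthetic generator for the wrist-tracking visuo-haptic experiment.

Emulates the study's tracking task so every downstream stage can be
exercised without recorded data: a pseudo-random multi-sine target, a
dual-sine haptic torque perturbation, a dot-cloud visual target with
Gaussian offsets, a compliant spring coupling to a scripted partner
controller, antagonist EMG envelopes with a constant coactivation floor
plus target-correlated reciprocal drive, and per-condition coactivation
observations drawn around the OIE stationary point.

The generative assumption for the condition table is that behaviour has
converged: the mean normalized coactivation of each condition equals
the optimum of the OIE cost for that condition's effective noise, plus
truncated Gaussian observation noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .containers import (
    CoactivationTable,
    NoiseCondition,
    TrialSeries,
    all_conditions,
)
from .model import (
    ComplianceNoiseCoeffs,
    EffectiveNoise,
    IDENTIFIED_NOISE,
    OieParams,
    optimal_coactivation,
    prediction_error,
)

#: Multi-sine target parameters: amplitude (deg) and the two angular
#: frequencies (rad/s) whose product generates the pseudo-random path.
TARGET_AMPLITUDE_DEG = 18.5
TARGET_OMEGA_1 = 2.031
TARGET_OMEGA_2 = 1.093

#: Haptic perturbation carrier frequencies (rad/s).
PERTURB_OMEGA_1 = 25.0
PERTURB_OMEGA_2 = 30.0

#: Dot-cloud statistics: vertical offset SD (mm), velocity offset SD
#: (mm/s), number of dots, refresh period (s).
CLOUD_VERTICAL_SD_MM = 15.0
CLOUD_VELOCITY_SD_MM_S = 101.6
CLOUD_N_DOTS = 8
CLOUD_REFRESH_S = 0.1

#: Virtual spring stiffness coupling wrist and controller (Nm/deg).
COUPLING_STIFFNESS = 0.03


@dataclass(frozen=True)
class TrialConfig:
    """Timing of one tracking trial.

    ``t0`` is the random trajectory offset; it must be a zero of the
    multi-sine so every trial starts with the target centred. Leave it
    ``None`` to have the generator draw one from the zero-crossing set.
    """

    duration: float = 20.0
    sample_rate: float = 100.0
    t0: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.sample_rate <= 0:
            raise ValueError("duration and sample_rate must be positive")
        if self.t0 is not None:
            if abs(target_angle(self.t0)) > 1e-6:
                raise ValueError("t0 must be a zero-crossing of the target")

    def time_grid(self) -> np.ndarray:
        n = int(round(self.duration * self.sample_rate))
        return np.arange(n) / self.sample_rate


@dataclass
class CloudFrame:
    """One 100 ms refresh step of the eight-dot visual cloud.

    Offsets are the Gaussian draws assigned at each dot's birth:
    vertical and angular in mm on screen, velocity in mm/s. A separate
    rendering step applies the velocity drift over a dot's lifetime.
    """

    timestamp: float
    dot_angular_offsets: np.ndarray
    dot_vertical_offsets: np.ndarray
    dot_velocity_offsets: np.ndarray
    dot_ages: np.ndarray

    def __post_init__(self) -> None:
        for name in ("dot_angular_offsets", "dot_vertical_offsets",
                     "dot_velocity_offsets", "dot_ages"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (CLOUD_N_DOTS,):
                raise ValueError(f"{name} must have exactly {CLOUD_N_DOTS} entries")
            setattr(self, name, arr)

    def rendered_angular_positions(self) -> np.ndarray:
        """Angular offsets with the per-dot velocity drift applied (mm)."""
        return self.dot_angular_offsets + self.dot_velocity_offsets * self.dot_ages


@dataclass
class SyntheticStudy:
    """A full 9-condition synthetic experiment."""

    conditions: list[NoiseCondition]
    trials_per_condition: int
    trials: dict[str, list[TrialSeries]]
    coactivation_truth: CoactivationTable
    coactivation_observed: CoactivationTable
    effective_noise: EffectiveNoise
    gamma: float
    seed: int

    def __post_init__(self) -> None:
        labels = sorted(c.label for c in self.conditions)
        if labels != sorted(c.label for c in all_conditions()):
            raise ValueError("all nine visual x haptic conditions required exactly once")


def target_zero_crossings(duration: float = 20.0) -> np.ndarray:
    """Zeros of the multi-sine target on [0, duration].

    The target is a product of two sines, so its zero set is the union
    of each factor's zeros: {k*pi/omega_1} and {k*pi/omega_2}.
    """
    zeros = []
    for omega in (TARGET_OMEGA_1, TARGET_OMEGA_2):
        k_max = int(np.floor(duration * omega / np.pi))
        zeros.append(np.arange(k_max + 1) * np.pi / omega)
    return np.unique(np.concatenate(zeros))


def draw_offset(rng: np.random.Generator, duration: float = 20.0) -> float:
    """Draw a trial offset t0 uniformly from the zero-crossing set."""
    zeros = target_zero_crossings(duration)
    return float(rng.choice(zeros))


def target_angle(t_star) -> np.ndarray:
    """Multi-sine target angle (deg) at shifted time t* = t + t0."""
    t_star = np.asarray(t_star, dtype=float)
    return (
        TARGET_AMPLITUDE_DEG
        * np.sin(TARGET_OMEGA_1 * t_star)
        * np.sin(TARGET_OMEGA_2 * t_star)
    )


def target_trajectory(config: TrialConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Target angle series (deg) on the trial's time grid."""
    t0 = config.t0
    if t0 is None:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        t0 = draw_offset(rng, config.duration)
    return target_angle(config.time_grid() + t0)


def haptic_perturbation(sigma_p: float, time: np.ndarray) -> np.ndarray:
    """Dual-sine torque perturbation sigma_p*sin(25t)*sin(30t) (Nm).

    By the product-to-sum identity the spectrum has lines at
    (30-25)/(2 pi) ~ 0.80 Hz and (30+25)/(2 pi) ~ 8.75 Hz.
    """
    if sigma_p < 0:
        raise ValueError("sigma_p must be non-negative")
    time = np.asarray(time, dtype=float)
    return sigma_p * np.sin(PERTURB_OMEGA_1 * time) * np.sin(PERTURB_OMEGA_2 * time)


def visual_cloud(
    duration: float,
    sigma_c: float,
    seed: int | np.random.Generator | None = None,
) -> list[CloudFrame]:
    """Dot-cloud frames for one trial.

    Eight dots; each refresh step (100 ms) retires the oldest dot
    (round-robin by index) and redraws its offsets: vertical
    ~ N(0, 15^2) mm, angular ~ N(0, sigma_c^2) mm, velocity
    ~ N(0, 101.6^2) mm/s. With ``sigma_c = 0`` (sharp target) the
    angular offsets are exactly zero while the other statistics remain
    non-degenerate.
    """
    if sigma_c < 0:
        raise ValueError("sigma_c must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_frames = int(round(duration / CLOUD_REFRESH_S))
    angular = rng.normal(0.0, sigma_c, CLOUD_N_DOTS) if sigma_c > 0 else np.zeros(CLOUD_N_DOTS)
    vertical = rng.normal(0.0, CLOUD_VERTICAL_SD_MM, CLOUD_N_DOTS)
    velocity = rng.normal(0.0, CLOUD_VELOCITY_SD_MM_S, CLOUD_N_DOTS)
    ages = np.arange(CLOUD_N_DOTS, dtype=float)[::-1] * CLOUD_REFRESH_S
    frames = []
    for k in range(n_frames):
        frames.append(
            CloudFrame(
                timestamp=k * CLOUD_REFRESH_S,
                dot_angular_offsets=angular.copy(),
                dot_vertical_offsets=vertical.copy(),
                dot_velocity_offsets=velocity.copy(),
                dot_ages=ages.copy(),
            )
        )
        i = k % CLOUD_N_DOTS  # round-robin replacement
        angular[i] = rng.normal(0.0, sigma_c) if sigma_c > 0 else 0.0
        vertical[i] = rng.normal(0.0, CLOUD_VERTICAL_SD_MM)
        velocity[i] = rng.normal(0.0, CLOUD_VELOCITY_SD_MM_S)
        ages += CLOUD_REFRESH_S
        ages[i] = 0.0
    return frames


def coupling_torque(controller_angle: np.ndarray, wrist_angle: np.ndarray) -> np.ndarray:
    """Spring coupling torque 0.03*(q_c - q) in Nm (angles in deg)."""
    controller_angle = np.asarray(controller_angle, dtype=float)
    wrist_angle = np.asarray(wrist_angle, dtype=float)
    if controller_angle.shape != wrist_angle.shape:
        raise ValueError("controller and wrist series must be aligned")
    return COUPLING_STIFFNESS * (controller_angle - wrist_angle)


def synth_emg_pair(
    target: np.ndarray,
    perturbation: np.ndarray,
    coactivation_level: float,
    reciprocal_gain: float = 0.02,
    perturbation_gain: float = 2.0,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Antagonist envelope pair with a set coactivation floor.

    The reciprocal drive r tracks the target (plus a scaled
    perturbation response); the flexor takes the positive part, the
    extensor the negative part, both riding on a constant coactivation
    floor:

        flexor   = floor + max(r, 0) + noise
        extensor = floor + max(-r, 0) + noise

    so the pointwise minimum recovers the floor exactly in the
    noiseless case. Envelopes are clipped at zero.
    """
    if coactivation_level < 0:
        raise ValueError("coactivation_level must be non-negative")
    target = np.asarray(target, dtype=float)
    perturbation = np.asarray(perturbation, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    r = reciprocal_gain * (target + perturbation_gain * perturbation)
    flexor = coactivation_level + np.maximum(r, 0.0)
    extensor = coactivation_level + np.maximum(-r, 0.0)
    if noise_sd > 0:
        flexor = flexor + rng.normal(0.0, noise_sd, len(target))
        extensor = extensor + rng.normal(0.0, noise_sd, len(target))
    return np.clip(flexor, 0.0, None), np.clip(extensor, 0.0, None)


def _wrist_angle(
    target: np.ndarray,
    sigma_v: float,
    sigma_h: float,
    u_star: float,
    sample_rate: float,
    rng: np.random.Generator,
    coeffs: ComplianceNoiseCoeffs,
    deviation_gain: float = 0.1,
) -> np.ndarray:
    """Target plus smooth tracking deviation.

    The deviation SD is ``deviation_gain * sqrt(Gamma(u*))`` so that
    synthetic tracking error inherits the fused-noise structure: it
    grows with both visual and haptic noise. The gain (deg per model
    deviation unit) sets a realistic sub-degree RMS error scale.
    """
    n = len(target)
    gamma_u = float(prediction_error(u_star, sigma_v, sigma_h, coeffs))
    white = rng.normal(0.0, 1.0, n)
    sos = sps.butter(2, 2.0, btype="low", fs=sample_rate, output="sos")
    smooth = sps.sosfilt(sos, white)
    sd = float(np.std(smooth))
    if sd > 0:
        smooth = smooth / sd
    return target + deviation_gain * np.sqrt(gamma_u) * smooth


def generate_trial(
    condition: NoiseCondition,
    coactivation_level: float,
    sigma_v: float,
    sigma_h: float,
    config: TrialConfig = TrialConfig(),
    rng: np.random.Generator | None = None,
    controller_lag: float = 0.0,
    emg_noise_sd: float = 0.01,
    coeffs: ComplianceNoiseCoeffs = ComplianceNoiseCoeffs(),
) -> TrialSeries:
    """One synthetic tracking trial for a noise condition.

    The partner controller is the noiseless target delayed by
    ``controller_lag`` seconds (a scripted stand-in for the study's
    predictive tracking controller; the spring law itself is exact).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    time = config.time_grid()
    t0 = config.t0 if config.t0 is not None else draw_offset(rng, config.duration)
    target = target_angle(time + t0)
    q_c = target_angle(time + t0 - controller_lag)
    wrist = _wrist_angle(
        target, sigma_v, sigma_h, coactivation_level, config.sample_rate, rng, coeffs
    )
    perturb = haptic_perturbation(condition.sigma_p, time)
    coupling = coupling_torque(q_c, wrist) + perturb
    flexor, extensor = synth_emg_pair(
        target, perturb, coactivation_level, noise_sd=emg_noise_sd, seed=rng
    )
    return TrialSeries(
        time=time,
        target_angle=target,
        wrist_angle=wrist,
        coupling_torque=coupling,
        perturbation_torque=perturb,
        flexor_envelope=flexor,
        extensor_envelope=extensor,
    )


def generate_study(
    oie_params: OieParams = OieParams(),
    effective_noise: EffectiveNoise = IDENTIFIED_NOISE,
    trials_per_condition: int = 9,
    observation_noise_sd: float = 0.02,
    seed: int = 0,
    trial_config: TrialConfig = TrialConfig(),
    coeffs: ComplianceNoiseCoeffs = ComplianceNoiseCoeffs(),
) -> SyntheticStudy:
    """Full nine-condition synthetic study.

    Per condition (i, j): the true coactivation is the OIE stationary
    point u*(sigma_v_i, sigma_h_j, gamma); the observed condition mean
    adds truncated Gaussian noise (SD ``observation_noise_sd``, clipped
    at zero); ``trials_per_condition`` trial time-series are generated
    with the true value as the envelope coactivation floor.

    Identical seeds give bit-identical studies.
    """
    rng = np.random.default_rng(seed)
    conditions = all_conditions()
    truth = np.empty((3, 3))
    for i, sv in enumerate(effective_noise.sigma_v):
        for j, sh in enumerate(effective_noise.sigma_h):
            truth[i, j] = optimal_coactivation(
                sv, sh, oie_params.gamma, oie_params.u_max, coeffs
            )
    observed = truth.copy()
    if observation_noise_sd > 0:
        observed = np.clip(
            truth + rng.normal(0.0, observation_noise_sd, (3, 3)), 0.0, None
        )
    trials: dict[str, list[TrialSeries]] = {}
    for cond in conditions:
        i = ["V0", "V1", "V2"].index(cond.visual_level)
        j = ["H0", "H1", "H2"].index(cond.haptic_level)
        trials[cond.label] = [
            generate_trial(
                cond,
                truth[i, j],
                effective_noise.sigma_v[i],
                effective_noise.sigma_h[j],
                config=trial_config,
                rng=rng,
                coeffs=coeffs,
            )
            for _ in range(trials_per_condition)
        ]
    return SyntheticStudy(
        conditions=conditions,
        trials_per_condition=trials_per_condition,
        trials=trials,
        coactivation_truth=CoactivationTable(truth, "u_true"),
        coactivation_observed=CoactivationTable(observed, "u_n"),
        effective_noise=effective_noise,
        gamma=oie_params.gamma,
        seed=seed,
    )
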