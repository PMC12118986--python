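"""EMG and kinematic processing into trial metrics.

Raw EMG is turned into an envelope (high-pass, rectify, low-pass),
calibrated into torque-equivalent activation by linear regression
against known torques, and decomposed into reciprocal activation
(flexor minus extensor: net joint torque) and coactivation (pointwise
minimum: joint stiffening without net torque). Trial summaries are the
RMS tracking error, the time-averaged coactivation, and its
per-participant min-max normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .containers import TrialSeries

EMG_HIGHPASS_HZ = 20.0
EMG_LOWPASS_HZ = 15.0


class CalibrationError(ValueError):
    """Raised for degenerate or sign-violating EMG-torque calibrations."""


@dataclass(frozen=True)
class CalibrationModel:
    """Linear EMG-envelope -> torque map: tau = alpha0 * u + alpha1.

    Both coefficients must be positive (activation raises torque and a
    relaxed muscle retains a small positive baseline).
    """

    alpha0: float
    alpha1: float

    def __post_init__(self) -> None:
        if self.alpha0 <= 0 or self.alpha1 <= 0:
            raise CalibrationError("calibration coefficients must be positive")

    def __call__(self, envelope) -> np.ndarray:
        return self.alpha0 * np.asarray(envelope, dtype=float) + self.alpha1


@dataclass
class TrialMetrics:
    """Per-trial summary: RMS tracking error (deg), mean coactivation
    (Nm), and the underlying reciprocal/coactivation series."""

    tracking_error: float
    mean_coactivation: float
    reciprocal: np.ndarray
    coactivation: np.ndarray

    def __post_init__(self) -> None:
        if self.tracking_error < 0 or self.mean_coactivation < 0:
            raise ValueError("metrics must be non-negative")


def emg_envelope(
    raw: np.ndarray, sample_rate: float, zero_phase: bool = False
) -> np.ndarray:
    """EMG envelope: 20 Hz 2nd-order Butterworth high-pass, full-wave
    rectification, 15 Hz 2nd-order Butterworth low-pass.

    Causal (forward-only) by default, matching real-time acquisition;
    ``zero_phase=True`` applies each filter forward-backward instead.
    Output is clipped at zero since the low-pass can undershoot.
    """
    if sample_rate <= 2 * EMG_HIGHPASS_HZ:
        raise ValueError(
            f"sample_rate must exceed {2 * EMG_HIGHPASS_HZ} Hz for the "
            f"{EMG_HIGHPASS_HZ} Hz high-pass corner"
        )
    raw = np.asarray(raw, dtype=float)
    hp = sps.butter(2, EMG_HIGHPASS_HZ, btype="high", fs=sample_rate, output="sos")
    lp = sps.butter(2, EMG_LOWPASS_HZ, btype="low", fs=sample_rate, output="sos")
    apply = sps.sosfiltfilt if zero_phase else sps.sosfilt
    rectified = np.abs(apply(hp, raw))
    return np.clip(apply(lp, rectified), 0.0, None)


def calibrate_torque(envelope: np.ndarray, torque: np.ndarray) -> CalibrationModel:
    """Least-squares fit of the linear envelope -> torque model.

    Raises :class:`CalibrationError` on a rank-deficient design
    (constant envelope) or when a fitted coefficient is non-positive.
    """
    envelope = np.asarray(envelope, dtype=float)
    torque = np.asarray(torque, dtype=float)
    if envelope.shape != torque.shape:
        raise ValueError("envelope and torque samples must be aligned")
    if np.ptp(envelope) < 1e-12 * max(1.0, np.abs(envelope).max()):
        raise CalibrationError("constant envelope: calibration design is degenerate")
    alpha0, alpha1 = np.polyfit(envelope, torque, 1)
    if alpha0 <= 0 or alpha1 <= 0:
        raise CalibrationError(
            f"fitted coefficients alpha0={alpha0:.4g}, alpha1={alpha1:.4g} "
            "violate the positivity constraint"
        )
    return CalibrationModel(float(alpha0), float(alpha1))


def activation_decomposition(
    flexor_torque: np.ndarray, extensor_torque: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Split antagonist activations into (reciprocal, coactivation).

    reciprocal = flexor - extensor (net torque, flexion positive);
    coactivation = pointwise min. The map is a bijection on
    non-negative pairs: flexor = u + max(tau, 0), extensor =
    u + max(-tau, 0).
    """
    flexor_torque = np.asarray(flexor_torque, dtype=float)
    extensor_torque = np.asarray(extensor_torque, dtype=float)
    if flexor_torque.shape != extensor_torque.shape:
        raise ValueError("flexor and extensor series must be aligned")
    if np.any(flexor_torque < 0) or np.any(extensor_torque < 0):
        raise ValueError("activations must be non-negative")
    return flexor_torque - extensor_torque, np.minimum(flexor_torque, extensor_torque)


def mean_coactivation(coactivation: np.ndarray, time: np.ndarray) -> float:
    """Trapezoidal time average of the coactivation series over the trial."""
    coactivation = np.asarray(coactivation, dtype=float)
    time = np.asarray(time, dtype=float)
    duration = time[-1] - time[0]
    if duration <= 0:
        raise ValueError("trial duration must be positive")
    return float(np.trapezoid(coactivation, time) / duration)


def normalize_coactivation(trial_means) -> np.ndarray:
    """Per-participant min-max normalization onto [0, 1].

    Applied over all of a participant's interaction trials; the
    smallest trial mean maps to 0 and the largest to 1. Invariant to
    positive affine rescaling of the input.
    """
    trial_means = np.asarray(trial_means, dtype=float)
    lo, hi = trial_means.min(), trial_means.max()
    if hi == lo:
        raise ValueError("all trial means equal: normalization is degenerate")
    return (trial_means - lo) / (hi - lo)


def tracking_error(target: np.ndarray, wrist: np.ndarray, time: np.ndarray) -> float:
    """RMS deviation between target and wrist angle over the trial (deg)."""
    target = np.asarray(target, dtype=float)
    wrist = np.asarray(wrist, dtype=float)
    time = np.asarray(time, dtype=float)
    duration = time[-1] - time[0]
    if duration <= 0:
        raise ValueError("trial duration must be positive")
    return float(np.sqrt(np.trapezoid((target - wrist) ** 2, time) / duration))


def activation_spectrum(
    series: np.ndarray, sample_rate: float, window: str | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided magnitude spectrum of the mean-removed series.

    A single un-windowed FFT of the whole trial (resolution 1/T;
    0.05 Hz for a 20 s trial); pass ``window="hann"`` for a Hann taper.
    Returns (frequencies in Hz, amplitude per sinusoidal component).
    """
    series = np.asarray(series, dtype=float)
    n = len(series)
    detrended = series - series.mean()
    if window is not None:
        detrended = detrended * sps.get_window(window, n)
    spectrum = np.abs(np.fft.rfft(detrended)) * 2.0 / n
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    return freqs, spectrum


def trial_metrics(
    trial: TrialSeries,
    flexor_cal: CalibrationModel | None = None,
    extensor_cal: CalibrationModel | None = None,
) -> TrialMetrics:
    """Compute a trial's metrics from its series.

    Calibration models map envelopes to torque-equivalent units; pass
    ``None`` when the envelopes are already calibrated (as in the
    synthetic generator).
    """
    tf = flexor_cal(trial.flexor_envelope) if flexor_cal else trial.flexor_envelope
    te = extensor_cal(trial.extensor_envelope) if extensor_cal else trial.extensor_envelope
    reciprocal, coact = activation_decomposition(tf, te)
    return TrialMetrics(
        tracking_error=tracking_error(trial.target_angle, trial.wrist_angle, trial.time),
        mean_coactivation=mean_coactivation(coact, trial.time),
        reciprocal=reciprocal,
        coactivation=coact,
    )
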