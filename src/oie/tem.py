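"""Tracking-error-minimization (TEM) comparison model.

The established alternative to the information-and-effort account:
coactivation grows in proportion to tracking error and decays through
an effort-forgetting term,

    u_new = alpha * e + (1 - gamma) * u,   0 < alpha, 0 < gamma < 1.

For constant error the iteration contracts geometrically to the
equilibrium u_inf = alpha * e / gamma, which is linear and *increasing*
in the error. Because tracking error grows with both visual and haptic
noise, TEM predicts coactivation increasing along both noise axes —
the failure mode that distinguishes it from the OIE prediction of
decreasing coactivation with visual noise.

Only the ratio alpha / gamma is identifiable from equilibrium data, so
the fit is one-parameter least squares on that ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import CoactivationTable


@dataclass(frozen=True)
class TemParams:
    """Error gain alpha > 0 and forgetting rate gamma_tem in (0, 1)."""

    alpha: float
    gamma_tem: float

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not 0 < self.gamma_tem < 1:
            raise ValueError("gamma_tem must lie in (0, 1)")

    @property
    def equilibrium_ratio(self) -> float:
        return self.alpha / self.gamma_tem


def tem_update(u: float, e: float, params: TemParams) -> float:
    """One adaptation step u_new = alpha*e + (1 - gamma)*u."""
    if u < 0 or e < 0:
        raise ValueError("coactivation and error must be non-negative")
    return params.alpha * e + (1.0 - params.gamma_tem) * u


def tem_trajectory(u0: float, e: float, params: TemParams, n_steps: int) -> np.ndarray:
    """Iterate the update for constant error; returns n_steps + 1 values."""
    traj = np.empty(n_steps + 1)
    traj[0] = u0
    for k in range(n_steps):
        traj[k + 1] = tem_update(traj[k], e, params)
    return traj


def tem_equilibrium(e, params: TemParams):
    """Fixed point u_inf = alpha * e / gamma for constant error."""
    return params.equilibrium_ratio * np.asarray(e, dtype=float)


def tem_equilibrium_table(
    error_table: np.ndarray, params: TemParams
) -> CoactivationTable:
    """Equilibrium coactivation per condition from a 3x3 error table."""
    error_table = np.asarray(error_table, dtype=float)
    if np.any(error_table < 0):
        raise ValueError("tracking errors must be non-negative")
    return CoactivationTable(tem_equilibrium(error_table, params), "u_tem")


def fit_tem_ratio(error_table: np.ndarray, u_table: np.ndarray) -> tuple[float, float]:
    """Least-squares equilibrium fit u ~ (alpha/gamma) * e.

    Returns (ratio, residual sum of squares). Only the ratio is
    identifiable from final-trial levels.
    """
    e = np.asarray(error_table, dtype=float).ravel()
    u = np.asarray(u_table, dtype=float).ravel()
    denom = float(np.sum(e * e))
    if denom == 0:
        raise ValueError("all tracking errors are zero")
    ratio = float(np.sum(e * u)) / denom
    rss = float(np.sum((u - ratio * e) ** 2))
    return ratio, rss
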