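"""Static figure export for the predicted coactivation surface."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .model import ComplianceNoiseCoeffs, EffectiveNoise, predict_grid


def plot_surface(
    noise: EffectiveNoise,
    gamma: float,
    path: str | Path,
    n_grid: int = 25,
    coeffs: ComplianceNoiseCoeffs = ComplianceNoiseCoeffs(),
) -> None:
    """Save a 3-D surface of u*(sigma_v, sigma_h) spanning the study's
    noise range, with the nine fitted conditions marked."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sv_axis = np.linspace(min(noise.sigma_v) * 0.8, max(noise.sigma_v) * 1.1, n_grid)
    sh_axis = np.linspace(min(noise.sigma_h) * 0.8, max(noise.sigma_h) * 1.1, n_grid)
    surface = predict_grid(sv_axis, sh_axis, gamma, coeffs=coeffs)
    sv_mesh, sh_mesh = np.meshgrid(sv_axis, sh_axis, indexing="ij")

    fig = plt.figure(figsize=(7, 5))
    ax = fig.add_subplot(projection="3d")
    ax.plot_surface(sv_mesh, sh_mesh, surface, cmap="viridis", alpha=0.8)
    from .model import optimal_coactivation

    for sv in noise.sigma_v:
        for sh in noise.sigma_h:
            ax.scatter(sv, sh, optimal_coactivation(sv, sh, gamma, coeffs=coeffs),
                       color="red", s=25)
    ax.set_xlabel(r"visual noise $\sigma_v$")
    ax.set_ylabel(r"haptic noise $\sigma_h$")
    ax.set_zlabel(r"predicted coactivation $u^*$")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
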