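"""Plot helpers: log-log strong-error plot and trajectory fans."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless
import matplotlib.pyplot as plt
import numpy as np

from .diagnostics import ConvergenceResult
from .schemes import Trajectory


def plot_convergence(result: ConvergenceResult, path: str | Path) -> None:
    """Log-log RMS terminal error vs step size with the fitted order line."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.loglog(result.dts, result.rms_errors, "o-", label="measured")
    if np.isfinite(result.fitted_order):
        ref = np.exp(result.intercept) * result.dts ** result.fitted_order
        ax.loglog(result.dts, ref, "--",
                  label=f"fit: order {result.fitted_order:.2f}")
    ax.set_xlabel(r"step size $\Delta t$")
    ax.set_ylabel("RMS terminal error")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_trajectories(trajectories: list[Trajectory], path: str | Path,
                      component: str = "C") -> None:
    """Overlay the C (or N) component of several trajectories."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for traj in trajectories:
        y = traj.C if component == "C" else traj.N
        ax.plot(traj.times, y, lw=0.8,
                label=f"x0=({traj.params.x0.C:g}, {traj.params.x0.N:g})")
    ax.set_xlabel("t [years]")
    ax.set_ylabel(component)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
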