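"""Model/results front end tying calibration, simulation and diagnostics together.

Typical use::

    import diabsde

    model = diabsde.DiabetesSDE()            # packaged Fujian table
    res = model.fit()                        # through-origin rate calibration
    print(res.summary())
    traj = res.simulate(T=40.0, dt=0.01, seed=1)
    conv = res.convergence_study(n_paths=200, seed=1)

``DiabetesSDE`` is built from a surveillance table (a DataFrame, a CSV path,
or the packaged one); ``fit()`` returns a :class:`DiabetesSDEResults` holding
the fitted slopes, their residual sums of squares, and the simulation-ready
parameter set.  Simulation, stability and convergence diagnostics hang off
the results object.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import calibration as _cal
from . import diagnostics as _diag
from .brownian import Mesh, sample_path
from .calibration import CalibrationResult, SurveillanceTable
from .model import (
    HypothesisReport,
    LinearCoefficients,
    ModelParams,
    NoiseSpec,
    StateVec,
    equilibrium,
    lipschitz_bound,
)
from .schemes import Trajectory, integrate, ode_reference

__all__ = ["DiabetesSDE", "DiabetesSDEResults"]

#: rate slopes of the canonical published model (per year^2); the nu+delta
#: and mu entries are canonical conventions, not reproducible from the
#: packaged table by a through-origin fit (see docs/methods.md)
CANONICAL_SLOPES = LinearCoefficients(
    lam_slope=0.02, theta_slope=0.01, inc_slope=0.05,
    nu_delta_slope=0.007, mu_slope=0.002,
)


class DiabetesSDE:
    """Stochastic diabetes-with-complications model bound to a rate table.

    Parameters
    ----------
    table : SurveillanceTable, pandas.DataFrame, path, or None
        Yearly surveillance rates.  ``None`` selects the packaged
        Fujian-province 2012-2016 table.
    baseline_year : int
        Calendar year mapped to model time t = 0.
    K3 : float
        Additive noise amplitude of the periodic diffusion
        ``(K3 sin t, K3 cos t)``.
    x0 : tuple of float
        Initial state (C0, N0).
    """

    def __init__(self, table=None, baseline_year: int = 2011,
                 K3: float = 5.0, x0: tuple[float, float] = (0.65, 0.10)):
        if table is None:
            table = _cal.table1()
        elif isinstance(table, pd.DataFrame):
            table = SurveillanceTable(table)
        elif not isinstance(table, SurveillanceTable):
            table = _cal.load_table(table)
        self.table = table
        self.baseline_year = int(baseline_year)
        self.K3 = float(K3)
        self.x0 = StateVec(*x0)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "DiabetesSDE":
        return cls(table=df, **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "DiabetesSDE":
        return cls(table=_cal.load_table(path), **kwargs)

    @classmethod
    def canonical(cls, K3: float = 5.0,
                  x0: tuple[float, float] = (0.65, 0.10)) -> "DiabetesSDEResults":
        """Results object with the published reference slopes, no fitting."""
        params = ModelParams(coeffs=CANONICAL_SLOPES, noise=NoiseSpec(K3),
                             x0=StateVec(*x0))
        return DiabetesSDEResults(model=None, calibration=None, params=params)

    def fit(self) -> "DiabetesSDEResults":
        """Calibrate the five linear-in-time rate slopes from the table."""
        cal = _cal.calibrate(self.table, self.baseline_year)
        params = ModelParams(coeffs=cal.slopes, noise=NoiseSpec(self.K3),
                             x0=self.x0)
        return DiabetesSDEResults(model=self, calibration=cal, params=params)


@dataclass(frozen=True)
class DiabetesSDEResults:
    """Fitted (or canonical) parameter set with simulation and diagnostics.

    ``params`` is simulation-ready; ``calibration`` carries the fitted
    slopes, residual sums of squares and year-to-t mapping (``None`` for the
    canonical parameter set).
    """

    model: DiabetesSDE | None
    calibration: CalibrationResult | None
    params: ModelParams

    # ---- estimates & diagnostics ---------------------------------------
    @property
    def slopes(self) -> LinearCoefficients:
        return self.params.coeffs

    def equilibrium(self) -> StateVec:
        return equilibrium(self.params)

    def hypothesis_report(self, horizon: float) -> HypothesisReport:
        """Coefficient/noise bounds and Lipschitz constant on [0, horizon]."""
        return lipschitz_bound(self.params, horizon)

    def mean(self, t: float) -> StateVec:
        """Exact mean of the stochastic solution at time t (closed form)."""
        return ode_reference(t, self.params)

    def summary(self) -> str:
        """Plain-text summary table of slopes, fit quality and stability."""
        p = self.params
        lines = [
            "Stochastic diabetes-complication model (2-D linear SDE)",
            "=" * 58,
            f"{'rate':<12}{'slope [1/yr^2]':>16}{'RSS':>14}{'canonical':>12}",
            "-" * 58,
        ]
        rss = (self.calibration.residual_sum_squares
               if self.calibration else {})
        for col, fname in _cal.RATE_COLUMNS.items():
            r = rss.get(fname)
            lines.append(
                f"{col:<12}{getattr(p.coeffs, fname):>16.5f}"
                f"{(f'{r:.3e}' if r is not None else '--'):>14}"
                f"{getattr(CANONICAL_SLOPES, fname):>12.3f}")
        lines.append("-" * 58)
        xstar = self.equilibrium()
        eig = np.linalg.eigvals(
            np.array([[-(p.coeffs.lam_slope + p.coeffs.theta_slope),
                       p.coeffs.lam_slope],
                      [-p.coeffs.nu_delta_slope, -p.coeffs.mu_slope]]))
        lines += [
            f"noise amplitude K3 = {p.noise.K3:g}   "
            f"x0 = ({p.x0.C:g}, {p.x0.N:g})",
            f"equilibrium (C*, N*) = ({xstar.C:.4f}, {xstar.N:.4f})",
            "eigenvalues of M: "
            + ", ".join(f"{v.real:.5f}" + (f"{v.imag:+.5f}j"
                        if abs(v.imag) > 1e-12 else "") for v in eig)
            + f"  ({'mean-square stable' if np.all(eig.real < 0) else 'UNSTABLE'})",
        ]
        rep = self.hypothesis_report(horizon=40.0)
        for v in rep.violations:
            lines.append(f"warning: {v}")
        return "\n".join(lines)

    # ---- simulation ----------------------------------------------------
    def simulate(self, t0: float = 0.0, T: float = 40.0, dt: float = 0.01,
                 seed: int = 42, scheme: str = "em") -> Trajectory:
        """Integrate one trajectory on a seeded Brownian path."""
        mesh = Mesh(t0, T, dt)
        path = sample_path(mesh, seed)
        return integrate(scheme, self.params, mesh, path)

    def with_(self, **param_updates) -> "DiabetesSDEResults":
        """Copy with modified parameters, e.g. ``with_(noise=NoiseSpec(0.0))``."""
        return replace(self, params=replace(self.params, **param_updates))

    # ---- diagnostics ----------------------------------------------------
    def convergence_study(self, **kwargs) -> _diag.ConvergenceResult:
        return _diag.strong_error_study(self.params, **kwargs)

    def pullback(self, x0: tuple[float, float], x0_hat: tuple[float, float],
                 t_fixed: float, taus, **kwargs) -> _diag.StabilityResult:
        return _diag.pullback_experiment(
            self.params, StateVec(*x0), StateVec(*x0_hat), t_fixed, taus,
            **kwargs)

    def coalescence(self, starts, t0: float = 0.0, T: float = 40.0,
                    dt: float = 0.01, seed: int = 42):
        return _diag.trajectory_coalescence(
            self.params, [StateVec(*s) for s in starts], Mesh(t0, T, dt),
            seed=seed)

    def ensemble(self, t0: float = 0.0, T: float = 5.0, dt: float = 0.01,
                 n_paths: int = 200, seed: int = 42):
        return _diag.ensemble_summary(self.params, Mesh(t0, T, dt),
                                      n_paths=n_paths, seed=seed)
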