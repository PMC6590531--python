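"""Two-compartment diabetes SDE with time-varying linear rates and additive noise.

The state is ``X(t) = (C(t), N(t))`` where ``C`` counts diabetics with
complications and ``N`` all diabetics (``D = N - C`` are the complication-free
diabetics).  Each epidemiological rate grows linearly in time,
``rate(t) = slope * t`` with ``t`` in years since a calibration baseline, and
the system is driven by a single scalar Brownian motion through the additive
diffusion ``B(t) = (K3 sin t, K3 cos t)``:

    dC = [-(lambda(t) + theta(t)) C + lambda(t) N] dt + K3 sin(t) dW
    dN = [I(t) - (nu+delta)(t) C - mu(t) N] dt      + K3 cos(t) dW

The drift is affine, ``b(x, t) = A(t) x + (0, I(t))`` with ``A(t) = t * M``
for a constant matrix ``M``, which gives the model a closed-form zero-noise
solution (see :func:`diabsde.schemes.ode_reference`) and makes the difference
of two solutions driven by the same noise exactly deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StateVec",
    "LinearCoefficients",
    "NoiseSpec",
    "ModelParams",
    "HypothesisReport",
    "drift",
    "diffusion",
    "coefficient_matrix",
    "constant_matrix",
    "equilibrium",
    "lipschitz_bound",
]


class InvalidInputError(ValueError):
    """Non-finite or out-of-domain input to a model operation."""


class DegenerateModelError(ValueError):
    """The constant coefficient matrix is singular; no unique equilibrium."""


@dataclass(frozen=True)
class StateVec:
    """State ``(C, N)``; ``D = N - C`` is derived, may be negative (reported,
    not enforced -- additive Gaussian noise does not preserve ordering)."""

    C: float
    N: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.C) and math.isfinite(self.N)):
            raise InvalidInputError(f"non-finite state ({self.C}, {self.N})")

    @property
    def D(self) -> float:
        return self.N - self.C

    def as_array(self) -> np.ndarray:
        return np.array([self.C, self.N], dtype=float)

    @property
    def ordering_ok(self) -> bool:
        """Soft invariant N >= C (D >= 0)."""
        return self.N >= self.C


@dataclass(frozen=True)
class LinearCoefficients:
    """Slopes of the five linear-in-time rates, units 1/year^2.

    ``lam``: complication rate lambda(t); ``theta``: combined removal rate
    theta(t) = gamma + mu + nu + delta (gamma never appears on its own);
    ``inc``: incidence I(t); ``nu_delta``: severe-disability plus
    complication-mortality rate; ``mu``: background mortality.
    """

    lam_slope: float = 0.02
    theta_slope: float = 0.01
    inc_slope: float = 0.05
    nu_delta_slope: float = 0.007
    mu_slope: float = 0.002

    def __post_init__(self) -> None:
        vals = (self.lam_slope, self.theta_slope, self.inc_slope,
                self.nu_delta_slope, self.mu_slope)
        if not all(math.isfinite(v) for v in vals):
            raise InvalidInputError("non-finite slope")
        for name in ("lam_slope", "inc_slope", "mu_slope", "nu_delta_slope"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be >= 0")

    def lam(self, t: float) -> float:
        return self.lam_slope * t

    def theta(self, t: float) -> float:
        return self.theta_slope * t

    def inc(self, t: float) -> float:
        return self.inc_slope * t

    def nu_delta(self, t: float) -> float:
        return self.nu_delta_slope * t

    def mu(self, t: float) -> float:
        return self.mu_slope * t


@dataclass(frozen=True)
class NoiseSpec:
    """Additive periodic noise ``g1(t) = K3 sin t``, ``g2(t) = K3 cos t``.

    The vector ``(g1, g2)`` has constant Euclidean norm K3, so the noise
    intensity never grows with time even though the drift coefficients do.
    """

    K3: float = 5.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.K3) or self.K3 < 0:
            raise InvalidInputError("K3 must be finite and >= 0")

    def g1(self, t: float) -> float:
        return self.K3 * math.sin(t)

    def g2(self, t: float) -> float:
        return self.K3 * math.cos(t)


@dataclass(frozen=True)
class ModelParams:
    coeffs: LinearCoefficients = field(default_factory=LinearCoefficients)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    x0: StateVec = field(default_factory=lambda: StateVec(0.65, 0.10))

    @property
    def K1(self) -> float:
        """Smallest bound with max(C0, D0) <= K1 (initial-value hypothesis)."""
        return max(self.x0.C, self.x0.D)

    # -- flat config round trip -------------------------------------------
    _KEYS = ("lam_slope", "theta_slope", "inc_slope", "nu_delta_slope",
             "mu_slope", "K3", "C0", "N0")

    def to_dict(self) -> dict:
        c = self.coeffs
        return {
            "lam_slope": c.lam_slope,
            "theta_slope": c.theta_slope,
            "inc_slope": c.inc_slope,
            "nu_delta_slope": c.nu_delta_slope,
            "mu_slope": c.mu_slope,
            "K3": self.noise.K3,
            "C0": self.x0.C,
            "N0": self.x0.N,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        base = cls().to_dict()
        unknown = set(d) - set(base)
        if unknown:
            raise InvalidInputError(f"unknown config keys: {sorted(unknown)}")
        base.update(d)
        return cls(
            coeffs=LinearCoefficients(
                lam_slope=float(base["lam_slope"]),
                theta_slope=float(base["theta_slope"]),
                inc_slope=float(base["inc_slope"]),
                nu_delta_slope=float(base["nu_delta_slope"]),
                mu_slope=float(base["mu_slope"]),
            ),
            noise=NoiseSpec(K3=float(base["K3"])),
            x0=StateVec(float(base["C0"]), float(base["N0"])),
        )


@dataclass(frozen=True)
class HypothesisReport:
    """Finite-horizon check of the existence/stability hypotheses.

    ``J`` bounds max(theta(t), lambda(t)) on [0, horizon]; ``K2`` bounds
    max(|g1|, |g2|) (equal to K3, since the envelope is exact); ``L`` is the
    Lipschitz constant sqrt(7)*J derived from the entry-wise bound on the
    coefficient matrix.  ``violations`` names hypotheses that cannot hold
    globally: linear-growing rates are never bounded on all of R+, and the
    default initial pair has N0 < C0.
    """

    horizon: float
    J: float
    K2: float
    L: float
    K1: float
    violations: tuple[str, ...] = ()


def drift(x: StateVec | np.ndarray, t: float, p: ModelParams) -> np.ndarray:
    """Drift b(x, t) = ( -(lam+theta) C + lam N, I - (nu+delta) C - mu N )."""
    if isinstance(x, StateVec):
        C, N = x.C, x.N
    else:
        C, N = float(x[0]), float(x[1])
        if not (math.isfinite(C) and math.isfinite(N)):
            raise InvalidInputError(f"non-finite state ({C}, {N})")
    if not math.isfinite(t):
        raise InvalidInputError(f"non-finite time {t}")
    # computed through the exact affine decomposition t*(M x + k); the
    # vectorised ensemble driver orders its arithmetic identically, so the
    # two code paths agree bitwise
    M = constant_matrix(p)
    k = np.array([0.0, p.coeffs.inc_slope])
    return t * (M @ np.array([C, N]) + k)


def diffusion(t: float, p: ModelParams) -> np.ndarray:
    """Additive diffusion B(t) = (K3 sin t, K3 cos t); state-independent."""
    if not math.isfinite(t):
        raise InvalidInputError(f"non-finite time {t}")
    return np.array([p.noise.g1(t), p.noise.g2(t)])


def constant_matrix(p: ModelParams) -> np.ndarray:
    """Constant M with A(t) = t*M: [[-(lam+theta), lam], [-(nu+delta), -mu]]."""
    c = p.coeffs
    return np.array([
        [-(c.lam_slope + c.theta_slope), c.lam_slope],
        [-c.nu_delta_slope, -c.mu_slope],
    ])


def coefficient_matrix(t: float, p: ModelParams) -> np.ndarray:
    """A(t) such that drift(x, t) = A(t) @ x + (0, I(t))."""
    return t * constant_matrix(p)


def equilibrium(p: ModelParams) -> StateVec:
    """Stationary state of the zero-noise system: M x* + (0, inc_slope) = 0.

    Because A(t) = t*M and I(t) = t*inc_slope share the factor t, the drift
    vanishes at x* for *every* t, not just one instant.
    """
    M = constant_matrix(p)
    k = np.array([0.0, p.coeffs.inc_slope])
    try:
        xstar = np.linalg.solve(M, -k)
    except np.linalg.LinAlgError as exc:
        raise DegenerateModelError("constant coefficient matrix is singular") from exc
    if not np.all(np.isfinite(xstar)):
        raise DegenerateModelError("constant coefficient matrix is singular")
    return StateVec(float(xstar[0]), float(xstar[1]))


def lipschitz_bound(p: ModelParams, horizon: float) -> HypothesisReport:
    """Finite-horizon coefficient bounds and the Lipschitz constant L.

    For linear rates the supremum over [0, horizon] sits at t=horizon, so
    J = horizon * max(theta_slope, lam_slope).  L = sqrt(7) * J comes from
    bounding the coefficient-matrix norm by the root of the sum of squared
    entries, each at most J.  ``violations`` flags hypotheses that only hold
    on the finite horizon (global boundedness fails whenever a slope > 0)
    and the soft initial-ordering condition N0 >= C0.
    """
    if not (math.isfinite(horizon) and horizon > 0):
        raise InvalidInputError(f"horizon must be positive and finite, got {horizon}")
    c = p.coeffs
    J = horizon * max(c.theta_slope, c.lam_slope)
    K2 = p.noise.K3
    L = math.sqrt(7.0) * J
    violations = []
    if max(c.theta_slope, c.lam_slope) > 0:
        violations.append(
            "global_boundedness: lambda(t), theta(t) grow linearly and are "
            f"only bounded on the declared horizon [0, {horizon}]"
        )
    if not p.x0.ordering_ok:
        violations.append(
            f"initial_ordering: N0={p.x0.N} < C0={p.x0.C} implies D0 < 0"
        )
    return HypothesisReport(horizon=horizon, J=J, K2=K2, L=L, K1=p.K1,
                            violations=tuple(violations))
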