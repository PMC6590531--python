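"""Seeded Wiener paths on uniform meshes, with reflection and dyadic coarsening.

Increments are i.i.d. N(0, dt) drawn from a named generator per path, and the
path values are their cumulative sums anchored at the left mesh endpoint.
Negative-time paths are produced by reflecting a positive-time path through
the origin, ``W(-t) = -W(t)`` (the construction used for pullback runs; an
``independent`` mode substitutes a fresh path for a statistically correct
two-sided Wiener process).  ``coarsen`` collapses blocks of fine increments so
that convergence studies can couple every step size to one Brownian path.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["Mesh", "BrownianPath", "sample_path", "reflect", "coarsen"]


@dataclass(frozen=True)
class Mesh:
    """Uniform time grid: t_k = t0 + k*dt, k = 0..n_steps.

    ``dt`` must tile [t0, T] exactly (to a 1e-9 relative tolerance); the
    number of steps is derived from the endpoints, never supplied.
    """

    t0: float
    T: float
    dt: float

    def __post_init__(self) -> None:
        if not (self.dt > 0 and np.isfinite(self.dt)):
            raise ValueError(f"dt must be positive, got {self.dt}")
        if not self.T > self.t0:
            raise ValueError(f"need T > t0, got [{self.t0}, {self.T}]")
        n = round((self.T - self.t0) / self.dt)
        if n < 1 or abs(n * self.dt - (self.T - self.t0)) >= self.dt * 1e-9:
            raise ValueError(
                f"dt={self.dt} does not tile [{self.t0}, {self.T}] exactly"
            )

    @property
    def n_steps(self) -> int:
        return round((self.T - self.t0) / self.dt)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_steps + 1)


@dataclass(frozen=True)
class BrownianPath:
    """Wiener path on a mesh: values W(t_k) and increments dW_k.

    Invariant: ``values[k+1] - values[k] == increments[k]`` exactly (values
    are cumulative sums of the increments).  Freshly sampled paths are
    anchored with ``values[0] = 0``; reflected paths are anchored at time 0
    instead, so their left endpoint need not vanish.
    """

    mesh: Mesh
    increments: np.ndarray
    values: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.increments) != self.mesh.n_steps:
            raise ValueError("increments length must equal mesh.n_steps")
        if len(self.values) != self.mesh.n_steps + 1:
            raise ValueError("values length must equal mesh.n_steps + 1")
        if not np.array_equal(np.diff(self.values), self.increments):
            raise ValueError("values must be cumulative sums of increments")

    def to_csv(self, path: str | Path) -> None:
        np.savetxt(path, np.column_stack([self.mesh.times, self.values]),
                   delimiter=",", header="t,W", comments="")


def sample_path(mesh: Mesh, seed: int) -> BrownianPath:
    """Draw a path with i.i.d. N(0, dt) increments; deterministic given seed."""
    rng = np.random.default_rng(seed)
    inc = rng.normal(0.0, np.sqrt(mesh.dt), size=mesh.n_steps)
    values = np.concatenate([[0.0], np.cumsum(inc)])
    # re-derive increments from the stored values so the telescoping
    # invariant values[k+1]-values[k] == increments[k] holds bit-exactly
    return BrownianPath(mesh=mesh, increments=np.diff(values), values=values,
                        seed=seed)


def reflect(path: BrownianPath, mode: str = "reflect",
            seed: int | None = None) -> BrownianPath:
    """Mirror a path through time zero.

    ``reflect`` mode sets ``W(-t) = -W(t)`` (an involution: reflecting twice
    restores the original path).  ``independent`` mode instead returns
    ``W(-t) = W~(t)`` for an independent path ``W~`` -- the correct two-sided
    Wiener construction; it requires a ``seed``.  The input must have one
    mesh endpoint at time 0.
    """
    m = path.mesh
    if not (abs(m.t0) < 1e-12 or abs(m.T) < 1e-12):
        raise ValueError("path must be anchored at time 0 to reflect")
    new_mesh = Mesh(t0=-m.T, T=-m.t0, dt=m.dt)
    if mode == "reflect":
        # W'(s) = -W(-s): reverse the grid and negate.
        values = -path.values[::-1].copy()
    elif mode == "independent":
        if seed is None:
            raise ValueError("independent mode requires a seed")
        indep = sample_path(Mesh(0.0, m.T - m.t0, m.dt), seed)
        values = indep.values[::-1].copy()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return BrownianPath(mesh=new_mesh, increments=np.diff(values),
                        values=values, seed=path.seed)


def coarsen(path: BrownianPath, factor: int) -> BrownianPath:
    """Sum consecutive increments in blocks of ``factor``.

    The coarse path agrees with the fine one *exactly* at shared grid points
    (block sums telescope), which is what couples all levels of a strong-
    convergence study to a single noise realization.
    """
    if factor < 2 or int(factor) != factor:
        raise ValueError(f"factor must be an integer >= 2, got {factor}")
    n = path.mesh.n_steps
    if n % factor:
        raise ValueError(f"factor {factor} does not divide n_steps={n}")
    m = path.mesh
    coarse_mesh = Mesh(t0=m.t0, T=m.T, dt=m.dt * factor)
    # shared-grid values are kept bit-identical to the fine path; the coarse
    # increments are then the telescoped block sums of the fine ones
    values = path.values[::factor].copy()
    return BrownianPath(mesh=coarse_mesh, increments=np.diff(values),
                        values=values, seed=path.seed)
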