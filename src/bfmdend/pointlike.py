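"""Continuum Metropolis Monte Carlo of point-like dendrimers.

Each molecule is reduced to its centre of mass; pairs interact through
the fitted effective potential w(R) = exp(c0 + c1 R² + c2 R⁴) (zero
beyond R_cut) under periodic minimum-image boundaries.  A move displaces
one particle along a uniformly random direction by a magnitude uniform
on [0, 0.5] lattice units (a per-coordinate cube displacement is
available as an option).  Sampled COM sets feed the same g(R)/S(q)
machinery used for the full lattice systems, which is the point of the
model: it reproduces centre-of-mass structure at a fraction of the cost,
while it cannot describe unit-level scattering intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import run_pointlike_kernel
from .potential import PotentialFit, evaluate_potential

__all__ = ["PointParticleSystem", "run_pointlike", "pair_energy", "total_energy"]


@dataclass
class PointParticleSystem:
    """n_t point particles in a periodic cube with a fitted pair potential."""

    L: float
    positions: np.ndarray  # float64[n_t, 3] in [0, L)
    potential: PotentialFit
    energy: float = field(init=False, default=0.0)

    def __post_init__(self) -> None:
        self.positions = np.mod(
            np.asarray(self.positions, dtype=np.float64), self.L
        )
        self.energy = total_energy(self)

    @property
    def n_t(self) -> int:
        return int(self.positions.shape[0])

    @classmethod
    def random(cls, n_t: int, L: float, potential: PotentialFit,
               rng: np.random.Generator) -> "PointParticleSystem":
        return cls(L=L, positions=rng.uniform(0.0, L, size=(n_t, 3)),
                   potential=potential)

    @classmethod
    def lattice_start(cls, n_t: int, L: float,
                      potential: PotentialFit) -> "PointParticleSystem":
        """Particles on a regular sublattice (maximal initial spacing)."""
        k = 1
        while k**3 < n_t:
            k += 1
        s = L / k
        pts = [(i * s, j * s, m * s) for i in range(k) for j in range(k)
               for m in range(k)][:n_t]
        return cls(L=L, positions=np.array(pts), potential=potential)


def _min_image_distance(a: np.ndarray, b: np.ndarray, L: float) -> float:
    d = np.mod(a - b, L)
    d = np.where(d > L / 2.0, d - L, d)
    return float(np.sqrt((d * d).sum()))


def pair_energy(system: PointParticleSystem, i: int, j: int) -> float:
    """w at the minimum-image distance of particles i and j (k_B T)."""
    if i == j:
        raise ValueError("pair energy requires two distinct particles")
    r = _min_image_distance(system.positions[i], system.positions[j], system.L)
    return float(evaluate_potential(system.potential, r))


def total_energy(system: PointParticleSystem) -> float:
    """Full pairwise sum (k_B T); the incremental cache's oracle."""
    n = system.n_t
    e = 0.0
    for i in range(n - 1):
        for j in range(i + 1, n):
            r = _min_image_distance(
                system.positions[i], system.positions[j], system.L
            )
            e += float(evaluate_potential(system.potential, r))
    return e


def run_pointlike(
    system: PointParticleSystem,
    n_moves: int,
    sample_every: int = 1000,
    seed: int = 0,
    max_disp: float = 0.5,
    move_style: str = "sphere",
) -> np.ndarray:
    """Run ``n_moves`` displacement attempts; return sampled COM sets.

    Samples are taken every ``sample_every`` attempts, giving an array of
    shape (n_samples, n_t, 3) with wrapped coordinates.  The system's
    positions and cached energy are updated in place;
    ``system.acceptance`` holds the acceptance ratio of the run.
    """
    if move_style not in ("sphere", "cube"):
        raise ValueError("move_style must be 'sphere' or 'cube'")
    fit = system.potential
    n_samples = n_moves // sample_every
    samples = np.empty((n_samples, system.n_t, 3), dtype=np.float64)
    kernel_seed = int(
        np.random.SeedSequence(seed).generate_state(1, np.uint32)[0]
    )
    accepted, stored, etot = run_pointlike_kernel(
        system.positions, float(system.L),
        fit.c0, fit.c1, fit.c2, fit.R_cut**2,
        int(n_moves), float(max_disp), kernel_seed,
        int(sample_every), samples, move_style == "cube",
    )
    system.energy = float(etot)
    system.acceptance = accepted / max(1, n_moves)
    return samples[:stored]
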