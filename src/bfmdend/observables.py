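"""Conformational and mobility observables.

Shape is characterised through the gyration tensor
T = (1/N) Σ_k (r_k − r_cm)(r_k − r_cm)ᵀ with eigenvalues
λ1 ≥ λ2 ≥ λ3 (lattice units²):

* squared radius of gyration  Rg² = λ1 + λ2 + λ3,
* asphericity  A = ⟨Σ_{i>j} (λi − λj)²⟩ / ⟨2 (Σ λi)²⟩,

with the numerator and denominator ensemble-averaged separately.  A = 0
for spherically symmetric mass distributions and A = 1 for a rod.  The
centre-to-end distance Rce is the rms distance from the centroid to the
outermost-generation branching units.  Mobility comes from the
mean-squared displacement of molecular centres of mass (unwrapped
coordinates), with an apparent diffusion coefficient D = slope/6 fitted
over the linear regime.

A lattice unit maps to 1.45 Å (half the 2.9 Å bead overlap distance of
coarse-grained PAMAM-EDA models, matched to the BFM minimal distance 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LATTICE_UNIT_ANGSTROM",
    "RATIO_COMPACT_SPHERE",
    "RATIO_UNPERTURBED_COIL",
    "gyration_eigenvalues",
    "radius_of_gyration",
    "asphericity_terms",
    "asphericity",
    "center_to_end",
    "mean_branch_distance",
    "msd_com",
    "apparent_diffusion",
    "scale_to_angstrom",
    "ShapeSummary",
    "MobilitySummary",
]

#: Å per lattice unit (2.9 Å overlap distance / BFM minimal distance 2).
LATTICE_UNIT_ANGSTROM = 2.9 / 2.0

#: Rce/Rg of a uniformly filled compact sphere, (5/3)^1/2.
RATIO_COMPACT_SPHERE = float(np.sqrt(5.0 / 3.0))

#: Rce/Rg of an unperturbed polymer coil, 3^1/2.
RATIO_UNPERTURBED_COIL = float(np.sqrt(3.0))


def gyration_eigenvalues(coords: np.ndarray) -> np.ndarray:
    """Eigenvalues λ1 ≥ λ2 ≥ λ3 of the gyration tensor (lattice units²)."""
    coords = np.asarray(coords, dtype=np.float64)
    if coords.ndim != 2 or coords.shape[0] < 1:
        raise ValueError("need at least one unit")
    d = coords - coords.mean(axis=0)
    tensor = d.T @ d / coords.shape[0]
    return np.linalg.eigvalsh(tensor)[::-1]


def radius_of_gyration(coords: np.ndarray) -> float:
    """Squared radius of gyration of one configuration."""
    coords = np.asarray(coords, dtype=np.float64)
    if coords.ndim != 2 or coords.shape[0] < 1:
        raise ValueError("need at least one unit")
    d = coords - coords.mean(axis=0)
    return float(np.mean(np.sum(d * d, axis=1)))


def asphericity_terms(eigenvalues: np.ndarray) -> tuple[float, float]:
    """(numerator, denominator) contribution of one configuration:
    Σ_{i>j}(λi−λj)² and 2(Σλi)²."""
    l1, l2, l3 = np.asarray(eigenvalues, dtype=np.float64)
    num = (l1 - l2) ** 2 + (l1 - l3) ** 2 + (l2 - l3) ** 2
    den = 2.0 * (l1 + l2 + l3) ** 2
    return float(num), float(den)


def asphericity(configs) -> float:
    """Ensemble asphericity from configurations or precomputed terms.

    Accepts an iterable of coordinate arrays, or an (S, 2) array of
    (numerator, denominator) per-configuration terms.  Numerator and
    denominator are averaged separately before the ratio is taken.
    Degenerate (zero-extent) configurations raise ``ValueError``.
    """
    if isinstance(configs, np.ndarray) and configs.ndim == 2 and configs.shape[1] == 2:
        pairs = np.asarray(configs, dtype=np.float64)
    else:
        rows = []
        for c in configs:
            rows.append(asphericity_terms(gyration_eigenvalues(c)))
        pairs = np.array(rows, dtype=np.float64)
    if pairs.shape[0] == 0:
        raise ValueError("empty ensemble")
    den = pairs[:, 1].mean()
    if den == 0.0:
        raise ValueError("degenerate ensemble: all configurations have zero extent")
    return float(pairs[:, 0].mean() / den)


def center_to_end(coords: np.ndarray, outer_ids: np.ndarray) -> float:
    """Squared centre-to-end distance Rce² of one configuration.

    Mean squared distance from the molecular centroid to the
    outermost-generation branching units identified by ``outer_ids``.
    """
    coords = np.asarray(coords, dtype=np.float64)
    outer_ids = np.asarray(outer_ids, dtype=np.int64)
    if outer_ids.size == 0 or outer_ids.max() >= coords.shape[0]:
        raise ValueError("outer unit ids do not match the coordinate array")
    d = coords[outer_ids] - coords.mean(axis=0)
    return float(np.mean(np.sum(d * d, axis=1)))


def mean_branch_distance(coords: np.ndarray, segments: np.ndarray) -> float:
    """Mean Euclidean distance between directly bonded branching points.

    ``segments`` rows are (parent, intermediate, child); the distance is
    taken between parent and child of each two-bond segment.
    """
    coords = np.asarray(coords, dtype=np.float64)
    seg = np.asarray(segments, dtype=np.int64)
    if seg.shape[0] == 0:  # segment-free topologies (e.g. plain chains)
        return float("nan")
    d = coords[seg[:, 2]] - coords[seg[:, 0]]
    return float(np.mean(np.linalg.norm(d, axis=1)))


def msd_com(com: np.ndarray, max_lag: int | None = None) -> np.ndarray:
    """Mean-squared displacement of molecular centres of mass.

    ``com`` has shape (S, n_t, 3) with samples at a fixed cadence
    (unwrapped coordinates).  Averages over molecules and over all time
    origins at each lag; returns shape (n_lags,) with msd[0] = 0.
    """
    com = np.asarray(com, dtype=np.float64)
    S = com.shape[0]
    if max_lag is None:
        max_lag = S - 1
    max_lag = min(max_lag, S - 1)
    out = np.zeros(max_lag + 1)
    for lag in range(1, max_lag + 1):
        d = com[lag:] - com[:-lag]
        out[lag] = np.mean(np.sum(d * d, axis=2))
    return out


def apparent_diffusion(
    steps: np.ndarray, msd: np.ndarray, fit_window: tuple[int, int] | None = None
) -> float:
    """Apparent diffusion coefficient D = slope/6 of the MSD curve.

    ``fit_window`` is a (lo, hi) range in the units of ``steps``; by
    default the last half of the curve is used (the late, linear regime).
    At least two samples must fall inside the window.
    """
    steps = np.asarray(steps, dtype=np.float64)
    msd = np.asarray(msd, dtype=np.float64)
    if steps.shape != msd.shape:
        raise ValueError("steps and msd must have matching shapes")
    if fit_window is None:
        lo = steps[0] + 0.5 * (steps[-1] - steps[0])
        fit_window = (lo, steps[-1])
    mask = (steps >= fit_window[0]) & (steps <= fit_window[1])
    if mask.sum() < 2:
        raise ValueError("fit window must contain at least two samples")
    slope = np.polyfit(steps[mask], msd[mask], 1)[0]
    return float(slope / 6.0)


def scale_to_angstrom(x_lattice) -> float | np.ndarray:
    """Convert a lattice-unit length to Å (1 lattice unit = 1.45 Å)."""
    return np.multiply(x_lattice, LATTICE_UNIT_ANGSTROM)


@dataclass(frozen=True)
class ShapeSummary:
    """Ensemble shape summary (rms sizes in lattice units)."""

    Rg: float
    Rce: float
    A: float
    eigenvalues: tuple[float, float, float]

    @property
    def rce_over_rg(self) -> float:
        return self.Rce / self.Rg


@dataclass(frozen=True)
class MobilitySummary:
    """COM mobility summary: MSD series and apparent D (lattice units²/step)."""

    steps: np.ndarray
    msd: np.ndarray
    D: float
    fit_window: tuple[float, float]
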