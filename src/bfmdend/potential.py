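"""Effective pair potential between dendrimer centres of mass.

For purely repulsive (excluded-volume) interactions the Boltzmann factor
of the intermolecular energy is an overlap indicator, so the
conformation- and orientation-averaged Mayer function reduces to

    f_M(R) = −P(any intermolecular unit overlap | COM separation R),

estimated by translating pairs of equilibrated single-molecule
conformations to a COM separation R along a uniformly random direction
and testing for any unit pair within Chebyshev distance 2.  The
effective potential follows as w_eff(R)/k_BT = −ln[1 + f_M(R)]; its
logarithm against R² is well described by a quadratic, giving the
analytic interpolation  w(R) = exp(c0 + c1 R² + c2 R⁴)  used by the
point-particle Monte Carlo.  A pure Gaussian repulsion corresponds to
c2 = 0; higher generations need the quartic term because their
interactions are harder.

Default sampling budget: 1e5 tries spread over 200 separation bins, at
least 26 tries per bin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from ._kernels import any_intermolecular_overlap

__all__ = [
    "MayerEstimate",
    "EffectivePotential",
    "PotentialFit",
    "sample_mayer",
    "effective_potential",
    "fit_potential",
    "evaluate_potential",
]


@dataclass(frozen=True)
class MayerEstimate:
    """Binned Mayer function estimate from binary-interaction sampling."""

    r_edges: np.ndarray
    f_M: np.ndarray        # −overlaps/tries per bin; in [−1, 0]
    tries: np.ndarray
    overlaps: np.ndarray
    min_tries: int
    low_stat_bins: np.ndarray  # bool mask: fewer than min_tries tries

    @property
    def r_centers(self) -> np.ndarray:
        return 0.5 * (self.r_edges[:-1] + self.r_edges[1:])

    def stderr(self) -> np.ndarray:
        """Binomial standard error of f_M per bin."""
        p = -self.f_M
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.sqrt(p * (1 - p) / np.maximum(self.tries, 1))


@dataclass(frozen=True)
class EffectivePotential:
    """Binned effective potential w_eff(R) (k_B T units).

    ``hardcore`` marks bins where every try overlapped (f_M = −1,
    infinite w); those are excluded from the logarithmic fit but kept as
    hard-core markers.
    """

    r_centers: np.ndarray
    w_eff: np.ndarray
    hardcore: np.ndarray
    mayer: MayerEstimate | None = None


@dataclass(frozen=True)
class PotentialFit:
    """Quadratic-in-R² fit: ln w(R) = c0 + c1 R² + c2 R⁴, cut at R_cut."""

    c0: float
    c1: float
    c2: float
    stderr: tuple[float, float, float]
    residuals: np.ndarray
    r_used: np.ndarray
    R_cut: float
    tail_threshold: float

    @property
    def coefficients(self) -> tuple[float, float, float]:
        return (self.c0, self.c1, self.c2)

    def to_json(self, **metadata) -> str:
        return json.dumps({
            "c0": self.c0, "c1": self.c1, "c2": self.c2,
            "stderr": list(self.stderr), "R_cut": self.R_cut,
            "tail_threshold": self.tail_threshold,
            "metadata": metadata,
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PotentialFit":
        d = json.loads(text)
        return cls(
            c0=d["c0"], c1=d["c1"], c2=d["c2"],
            stderr=tuple(d.get("stderr", (np.nan,) * 3)),
            residuals=np.array([]), r_used=np.array([]),
            R_cut=d["R_cut"], tail_threshold=d.get("tail_threshold", 1e-3),
        )


def _centered(conf: np.ndarray) -> np.ndarray:
    conf = np.asarray(conf, dtype=np.float64)
    return conf - conf.mean(axis=0)


def sample_mayer(
    conformation_library,
    r_max: float,
    n_tries: int = 100_000,
    n_bins: int = 200,
    rng: np.random.Generator | None = None,
    min_tries: int = 26,
    r_min: float = 0.0,
) -> MayerEstimate:
    """Estimate f_M(R) from random binary interactions.

    Each try draws two conformations from the library (COM-centred,
    kept in their native lattice frames), a uniformly random separation
    direction, and a separation magnitude uniform within the bin; the
    pair counts as interacting when any intermolecular unit pair is
    within Chebyshev distance 2 in the displaced continuum frame.
    Tries are distributed evenly over the ``n_bins`` separation bins;
    bins left with fewer than ``min_tries`` tries are flagged.
    """
    rng = rng if rng is not None else np.random.default_rng()
    library = [_centered(c) for c in conformation_library]
    if not library:
        raise ValueError("empty conformation library")
    extents = [float(np.linalg.norm(c, axis=1).max()) if len(c) else 0.0
               for c in library]
    edges = np.linspace(r_min, r_max, n_bins + 1)
    tries = np.zeros(n_bins, dtype=np.int64)
    overlaps = np.zeros(n_bins, dtype=np.int64)

    base, extra = divmod(int(n_tries), n_bins)
    per_bin = np.full(n_bins, base, dtype=np.int64)
    per_bin[:extra] += 1

    n_lib = len(library)
    for b in range(n_bins):
        lo, hi = edges[b], edges[b + 1]
        for _ in range(int(per_bin[b])):
            i = int(rng.integers(0, n_lib))
            j = int(rng.integers(0, n_lib))
            R = float(rng.uniform(lo, hi))
            z = 1.0 - 2.0 * rng.random()
            phi_angle = 2.0 * np.pi * rng.random()
            s = np.sqrt(max(0.0, 1.0 - z * z))
            dx = R * s * np.cos(phi_angle)
            dy = R * s * np.sin(phi_angle)
            dz = R * z
            tries[b] += 1
            # bounding-sphere prefilter: no overlap possible beyond the
            # summed extents plus the interaction range
            if R > extents[i] + extents[j] + 2.0 * np.sqrt(3.0):
                continue
            if any_intermolecular_overlap(library[i], library[j], dx, dy, dz):
                overlaps[b] += 1

    with np.errstate(invalid="ignore"):
        f_M = -overlaps / np.maximum(tries, 1)
    return MayerEstimate(
        r_edges=edges, f_M=f_M, tries=tries, overlaps=overlaps,
        min_tries=min_tries, low_stat_bins=tries < min_tries,
    )


def effective_potential(mayer: MayerEstimate) -> EffectivePotential:
    """w_eff(R)/k_BT = −ln[1 + f_M(R)]; f_M = −1 bins marked hard-core."""
    hardcore = mayer.f_M <= -1.0
    with np.errstate(divide="ignore"):
        w = -np.log1p(np.where(hardcore, 0.0, mayer.f_M))
    w = np.where(hardcore, np.inf, w)
    return EffectivePotential(
        r_centers=mayer.r_centers, w_eff=w, hardcore=hardcore, mayer=mayer
    )


def fit_potential(
    potential: EffectivePotential,
    w_floor: float = 1e-4,
    tail_threshold: float = 1e-3,
    bin_filter: np.ndarray | None = None,
) -> PotentialFit:
    """Least squares of ln w_eff against (1, R², R⁴).

    Uses bins with finite w_eff above ``w_floor`` (hard-core and
    flagged low-statistics bins excluded); needs at least three.
    ``R_cut`` is where the fitted curve first drops below
    ``tail_threshold`` (k_B T) — the potential is defined as zero
    beyond it.
    """
    usable = np.isfinite(potential.w_eff) & (potential.w_eff > w_floor)
    usable &= ~potential.hardcore
    if potential.mayer is not None:
        usable &= ~potential.mayer.low_stat_bins
    if bin_filter is not None:
        usable &= np.asarray(bin_filter, dtype=bool)
    if usable.sum() < 3:
        raise ValueError(
            f"need >= 3 usable bins for the quadratic fit, have {int(usable.sum())}"
        )
    R = potential.r_centers[usable]
    y = np.log(potential.w_eff[usable])
    X = np.column_stack([np.ones_like(R), R**2, R**4])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = max(1, len(y) - 3)
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    stderr = tuple(np.sqrt(np.diag(cov)))

    # locate the tail cut on a dense grid past the sampled range
    r_dense = np.linspace(0.0, 2.0 * potential.r_centers[-1], 4000)
    w_dense = np.exp(coef[0] + coef[1] * r_dense**2 + coef[2] * r_dense**4)
    above = np.where(w_dense >= tail_threshold)[0]
    R_cut = float(r_dense[above[-1]]) if len(above) else 0.0

    return PotentialFit(
        c0=float(coef[0]), c1=float(coef[1]), c2=float(coef[2]),
        stderr=stderr, residuals=resid, r_used=R,
        R_cut=R_cut, tail_threshold=tail_threshold,
    )


def evaluate_potential(fit: PotentialFit, R) -> np.ndarray:
    """w(R) = exp(c0 + c1 R² + c2 R⁴) for R <= R_cut, else 0 (k_B T)."""
    R = np.asarray(R, dtype=np.float64)
    r2 = R**2
    w = np.exp(fit.c0 + fit.c1 * r2 + fit.c2 * r2 * r2)
    return np.where(R <= fit.R_cut, w, 0.0)
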