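"""Scattering intensity, form factor, structure factor and g(R).

On a periodic box of edge L only wavevectors q = (2π/L)(h,k,l) with
integer (h,k,l) are exact; profiles are spherically binned in |q| with
bin width δq = 2π/L.

The lattice intensity uses an occupation contrast f = 1 − Φ/8 on sites
holding a unit centre and f = −Φ/8 elsewhere, so that Σ_sites f = 0
exactly.  For q ≠ 0 on the commensurate grid the uniform background
contributes nothing and the full L³-site sum reduces to a sum over the
n_t·N centre sites:

    I(q) = (8/L³) |Σ_centres e^{iq·R}|².

For a single molecule I(q) = Φ N P(q) defines the form factor, and the
generalisation I(q) = Φ N P(q) S(q) is the factorization approximation
whose breakdown at high concentration this package probes.  The COM
structure factor is S(q) = (1/n_t)⟨|Σ_j e^{iq·R_j^cm}|²⟩ and g(R) is the
minimum-image pair histogram normalised by the ideal-gas shell
expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "QGrid",
    "ScatteringProfile",
    "RadialDistribution",
    "intensity",
    "intensity_direct_sum",
    "form_factor",
    "structure_factor_com",
    "smooth_profile",
    "rdf",
    "sq_from_gr",
    "factorized_intensity",
    "apparent_structure_factor",
]


@dataclass(frozen=True)
class QGrid:
    """Box-commensurate wavevectors, spherically binned with δq = 2π/L."""

    L: int
    hkl: np.ndarray      # int64[nq, 3], q = (2π/L)·hkl, excludes (0,0,0)
    bin_index: np.ndarray  # int64[nq]: round(|hkl|) − 1
    n_bins: int

    @classmethod
    def build(
        cls,
        L: int,
        qmax: float,
        max_per_shell: int | None = None,
        rng: np.random.Generator | None = None,
    ) -> "QGrid":
        """All integer (h,k,l) with 0 < |q| <= qmax.

        ``max_per_shell`` caps the number of vectors kept per |q| bin
        (uniformly subsampled, seeded) to bound the cost of dense shells
        at large |q|; averages per bin are unaffected within noise.
        """
        hmax = int(np.floor(qmax * L / (2 * np.pi)))
        if hmax < 1:
            raise ValueError(f"qmax={qmax} below the smallest box mode 2π/{L}")
        ax = np.arange(-hmax, hmax + 1)
        h, k, l = np.meshgrid(ax, ax, ax, indexing="ij")
        hkl = np.stack([h.ravel(), k.ravel(), l.ravel()], axis=1)
        norm = np.sqrt((hkl**2).sum(axis=1))
        keep = (norm > 0) & (norm <= hmax + 1e-12)
        hkl = hkl[keep]
        norm = norm[keep]
        bins = np.round(norm).astype(np.int64) - 1
        n_bins = int(bins.max()) + 1
        if max_per_shell is not None:
            rng = rng if rng is not None else np.random.default_rng(0)
            sel = np.zeros(len(hkl), dtype=bool)
            for b in range(n_bins):
                idx = np.where(bins == b)[0]
                if len(idx) > max_per_shell:
                    idx = rng.choice(idx, size=max_per_shell, replace=False)
                sel[idx] = True
            hkl, bins = hkl[sel], bins[sel]
        return cls(L=L, hkl=hkl, bin_index=bins, n_bins=n_bins)

    @property
    def qvecs(self) -> np.ndarray:
        return (2 * np.pi / self.L) * self.hkl.astype(np.float64)

    @property
    def bin_centers(self) -> np.ndarray:
        return (2 * np.pi / self.L) * (np.arange(self.n_bins) + 1.0)


@dataclass(frozen=True)
class ScatteringProfile:
    """Spherically binned profile: |q| bin centres, values, vector counts."""

    q: np.ndarray
    value: np.ndarray
    counts: np.ndarray
    kind: str = "I"

    def __post_init__(self) -> None:
        if not (len(self.q) == len(self.value) == len(self.counts)):
            raise ValueError("q, value and counts must have equal length")

    def _check_bins(self, other: "ScatteringProfile") -> None:
        if len(self.q) != len(other.q) or not np.allclose(self.q, other.q):
            raise ValueError("profiles are binned on different |q| grids")


@dataclass(frozen=True)
class RadialDistribution:
    """g(R): bin edges (lattice units), values, raw pair counts per bin."""

    edges: np.ndarray
    g: np.ndarray
    pair_counts: np.ndarray
    n_configs: int
    n_t: int
    L: int

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def _binned_mean(per_vec: np.ndarray, qgrid: QGrid) -> tuple[np.ndarray, np.ndarray]:
    counts = np.bincount(qgrid.bin_index, minlength=qgrid.n_bins)
    sums = np.bincount(qgrid.bin_index, weights=per_vec, minlength=qgrid.n_bins)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return mean, counts


def _coherent_sq_modulus(points: np.ndarray, qgrid: QGrid) -> np.ndarray:
    """|Σ_j e^{iq·R_j}|² for every grid vector (one configuration)."""
    phase = points.astype(np.float64) @ qgrid.qvecs.T  # (n, nq)
    re = np.cos(phase).sum(axis=0)
    im = np.sin(phase).sum(axis=0)
    return re * re + im * im


def intensity(configs, qgrid: QGrid) -> ScatteringProfile:
    """Lattice scattering intensity averaged over configurations.

    ``configs``: iterable of wrapped unit-centre coordinate arrays.
    Uses the centre-site reduction of the full-lattice contrast sum,
    exact for all q ≠ 0 of the commensurate grid.
    """
    acc = np.zeros(len(qgrid.hkl))
    n_cfg = 0
    for pts in configs:
        acc += _coherent_sq_modulus(np.asarray(pts), qgrid)
        n_cfg += 1
    if n_cfg == 0:
        raise ValueError("no configurations given")
    per_vec = (8.0 / qgrid.L**3) * acc / n_cfg
    value, counts = _binned_mean(per_vec, qgrid)
    return ScatteringProfile(q=qgrid.bin_centers, value=value, counts=counts, kind="I")


def intensity_direct_sum(occupied_sites: np.ndarray, L: int, qgrid: QGrid) -> ScatteringProfile:
    """Literal full-L³ contrast sum (oracle; O(L³) per q-vector).

    Builds f over every lattice site (1 − Φ/8 on occupied centre sites,
    −Φ/8 elsewhere) and evaluates the defining sum directly.
    """
    if qgrid.L != L:
        raise ValueError("q-grid is not commensurate with this box")
    occ = np.zeros((L, L, L), dtype=np.float64)
    pts = np.mod(np.asarray(occupied_sites, dtype=np.int64), L)
    occ[pts[:, 0], pts[:, 1], pts[:, 2]] = 1.0
    phi = 8.0 * len(pts) / L**3
    f = occ - phi / 8.0
    ax = np.arange(L)
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    sites = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1).astype(np.float64)
    fvals = f.ravel()
    phase = sites @ qgrid.qvecs.T
    re = (fvals[:, None] * np.cos(phase)).sum(axis=0)
    im = (fvals[:, None] * np.sin(phase)).sum(axis=0)
    per_vec = (8.0 / L**3) * (re * re + im * im)
    value, counts = _binned_mean(per_vec, qgrid)
    return ScatteringProfile(q=qgrid.bin_centers, value=value, counts=counts, kind="I")


def form_factor(single_molecule_profile: ScatteringProfile, phi: float, N: int) -> ScatteringProfile:
    """Form factor P(q) = I(q)/(ΦN) from a single-molecule intensity."""
    if phi == 0 or N == 0:
        raise ValueError("Φ and N must be nonzero")
    return replace(
        single_molecule_profile,
        value=single_molecule_profile.value / (phi * N),
        kind="P",
    )


def structure_factor_com(com_configs, qgrid: QGrid) -> ScatteringProfile:
    """COM structure factor S(q) = (1/n_t)⟨|Σ_j e^{iq·R_j^cm}|²⟩ >= 0."""
    acc = np.zeros(len(qgrid.hkl))
    n_cfg = 0
    n_t = None
    for coms in com_configs:
        coms = np.asarray(coms, dtype=np.float64)
        n_t = coms.shape[0]
        acc += _coherent_sq_modulus(coms, qgrid)
        n_cfg += 1
    if n_cfg == 0 or not n_t:
        raise ValueError("no COM configurations given")
    per_vec = acc / (n_cfg * n_t)
    value, counts = _binned_mean(per_vec, qgrid)
    return ScatteringProfile(q=qgrid.bin_centers, value=value, counts=counts, kind="S")


def smooth_profile(profile: ScatteringProfile, window: int) -> ScatteringProfile:
    """Centred moving average over |q| bins (window odd; 1 = identity)."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if window == 1:
        return profile
    half = window // 2
    v = profile.value
    out = np.empty_like(v)
    for i in range(len(v)):
        lo, hi = max(0, i - half), min(len(v), i + half + 1)
        seg = v[lo:hi]
        out[i] = np.nanmean(seg) if np.any(np.isfinite(seg)) else np.nan
    return replace(profile, value=out)


def rdf(com_configs, L: float, bin_width: float) -> RadialDistribution:
    """Radial distribution of molecular centres of mass.

    Minimum-image pair distances up to L/2, histogram normalised per
    configuration by the ideal-gas expectation n_t(n_t−1)/2 · V_shell/L³
    (exact spherical-shell volumes).
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    edges = np.arange(0.0, L / 2.0 + bin_width, bin_width)
    edges = edges[edges <= L / 2.0 + 1e-9]
    counts = np.zeros(len(edges) - 1)
    n_cfg = 0
    n_t = None
    for coms in com_configs:
        coms = np.mod(np.asarray(coms, dtype=np.float64), L)
        n_t = coms.shape[0]
        if n_t < 2:
            raise ValueError("need at least two molecules for g(R)")
        d = coms[:, None, :] - coms[None, :, :]
        d = np.mod(d, L)
        d = np.where(d > L / 2.0, d - L, d)
        r = np.sqrt((d**2).sum(axis=2))
        iu = np.triu_indices(n_t, k=1)
        counts += np.histogram(r[iu], bins=edges)[0]
        n_cfg += 1
    if n_cfg == 0:
        raise ValueError("no configurations given")
    shell_vol = (4.0 * np.pi / 3.0) * (edges[1:] ** 3 - edges[:-1] ** 3)
    ideal = n_cfg * (n_t * (n_t - 1) / 2.0) * shell_vol / L**3
    g = counts / ideal
    return RadialDistribution(
        edges=edges, g=g, pair_counts=counts, n_configs=n_cfg, n_t=n_t, L=int(L)
    )


def sq_from_gr(dist: RadialDistribution, number_density: float,
               q: np.ndarray) -> ScatteringProfile:
    """S(q) = 1 + 4πρ ∫ (g(R)−1) R² sinc(qR) dR over the binned g.

    Trapezoidal quadrature over bin centres up to R = L/2.
    """
    q = np.asarray(q, dtype=np.float64)
    R = dist.centers
    h = dist.g - 1.0
    qR = np.outer(q, R)
    with np.errstate(invalid="ignore", divide="ignore"):
        sinc = np.where(qR != 0.0, np.sin(qR) / qR, 1.0)
    integrand = h * R**2 * sinc
    S = 1.0 + 4.0 * np.pi * number_density * np.trapezoid(integrand, R, axis=1)
    return ScatteringProfile(
        q=q, value=S, counts=np.ones_like(q, dtype=np.int64), kind="S"
    )


def factorized_intensity(P: ScatteringProfile, S: ScatteringProfile,
                         phi: float, N: int) -> ScatteringProfile:
    """I(q) = ΦN·P(q)·S(q) — the factorization approximation."""
    P._check_bins(S)
    return ScatteringProfile(
        q=P.q, value=phi * N * P.value * S.value,
        counts=np.minimum(P.counts, S.counts), kind="I",
    )


def apparent_structure_factor(I: ScatteringProfile, P: ScatteringProfile,
                              phi: float, N: int,
                              p_floor: float = 1e-9) -> ScatteringProfile:
    """Apparent S(q) = I(q)/(ΦN·P(q)); NaN where P falls below ``p_floor``."""
    I._check_bins(P)
    with np.errstate(invalid="ignore", divide="ignore"):
        value = np.where(P.value > p_floor, I.value / (phi * N * P.value), np.nan)
    return ScatteringProfile(
        q=I.q, value=value, counts=np.minimum(I.counts, P.counts), kind="S",
    )
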