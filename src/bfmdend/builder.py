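"""Single-spacer dendrimer topologies and self-avoiding initial conformations.

The molecule is grown around two bonded *central* units.  Each central
carries two branch segments, and every bifunctional *branching* unit of
generation g carries two segments towards generation g+1.  A segment
consists of two identical BFM bond vectors with one *intermediate*
(spacer) unit at the midpoint, so a generation-G molecule has

    N(G) = 10 + 16 (2^G − 1)

units: N = 10, 26, 58, 122, 250, 506 for G = 0..5.  Each unit blocks 8
lattice sites net, hence the molecular site mass M = 8 N and the system
volume fraction Φ = n_t M / L³.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import grow_kernel
from .lattice import (
    BondEnergyTable,
    LatticeBox,
    OccupancyGrid,
    allowed_bond_set,
)

__all__ = [
    "ROLE_CENTRAL",
    "ROLE_BRANCHING",
    "ROLE_INTERMEDIATE",
    "DendrimerTopology",
    "SystemState",
    "build_topology",
    "grow_conformation",
    "build_system",
    "overlap_fraction_bound",
    "ConformationError",
    "InfeasibleDensityError",
]

ROLE_CENTRAL = 0
ROLE_BRANCHING = 1
ROLE_INTERMEDIATE = 2

MAX_GENERATION = 5


class ConformationError(RuntimeError):
    """Self-avoiding growth failed within the restart budget."""

    def __init__(self, message: str, attempts: int):
        super().__init__(message)
        self.attempts = attempts


class InfeasibleDensityError(RuntimeError):
    """Requested system density could not be realised."""


@dataclass(frozen=True)
class DendrimerTopology:
    """Connectivity of one single-spacer dendrimer.

    Attributes
    ----------
    G : generation number (0..5)
    roles : int8[N], one of ROLE_CENTRAL / ROLE_BRANCHING / ROLE_INTERMEDIATE
    generations : int8[N]; −1 for the two centrals, otherwise the
        generation index of the unit's segment
    edges : int64[N−1, 2] bonded unit-id pairs (a tree)
    segments : int64[S, 3] rows (parent, intermediate, child) where parent
        and child are branching points (or centrals) joined through one
        intermediate by two bonds
    """

    G: int
    roles: np.ndarray
    generations: np.ndarray
    edges: np.ndarray
    segments: np.ndarray

    @property
    def n_units(self) -> int:
        return int(self.roles.shape[0])

    @property
    def site_mass(self) -> int:
        """Blocked-site mass M = 8 N of the molecule."""
        return 8 * self.n_units

    def outer_unit_ids(self) -> np.ndarray:
        """Ids of the outermost-generation branching units."""
        return np.where(
            (self.roles == ROLE_BRANCHING) & (self.generations == self.G)
        )[0]

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_units, dtype=np.int64)
        np.add.at(deg, self.edges[:, 0], 1)
        np.add.at(deg, self.edges[:, 1], 1)
        return deg


def expected_unit_count(G: int) -> int:
    """Closed-form unit count N(G) = 10 + 16(2^G − 1)."""
    return 10 + 16 * (2**G - 1)


def build_topology(G: int) -> DendrimerTopology:
    """Construct the generation-G single-spacer dendrimer tree.

    Deterministic; raises ``ValueError`` outside the supported range
    0 <= G <= 5 (larger generations cannot be embedded in the lattice).
    """
    if not 0 <= G <= MAX_GENERATION:
        raise ValueError(f"generation must be in 0..{MAX_GENERATION}, got {G}")

    roles: list[int] = [ROLE_CENTRAL, ROLE_CENTRAL]
    gens: list[int] = [-1, -1]
    edges: list[tuple[int, int]] = [(0, 1)]
    segments: list[tuple[int, int, int]] = []

    def add_segment(parent: int, gen: int) -> int:
        inter = len(roles)
        roles.append(ROLE_INTERMEDIATE)
        gens.append(gen)
        child = len(roles)
        roles.append(ROLE_BRANCHING)
        gens.append(gen)
        edges.append((parent, inter))
        edges.append((inter, child))
        segments.append((parent, inter, child))
        return child

    # generation 0: two segments off each central
    frontier = [add_segment(c, 0) for c in (0, 1) for _ in range(2)]
    # subsequent shells: two segments off every frontier branching unit
    for gen in range(1, G + 1):
        frontier = [add_segment(bp, gen) for bp in frontier for _ in range(2)]

    return DendrimerTopology(
        G=G,
        roles=np.array(roles, dtype=np.int8),
        generations=np.array(gens, dtype=np.int8),
        edges=np.array(edges, dtype=np.int64),
        segments=np.array(segments, dtype=np.int64),
    )


_ALLOWED_BONDS = None


def _allowed_bond_array() -> np.ndarray:
    global _ALLOWED_BONDS
    if _ALLOWED_BONDS is None:
        _ALLOWED_BONDS = np.array(sorted(allowed_bond_set()), dtype=np.int64)
    return _ALLOWED_BONDS


def _dfs_segments(topology: DendrimerTopology) -> tuple[np.ndarray, np.ndarray]:
    """Segments in depth-first order with a preferred ±x direction per
    gen-0 subtree (two subtrees grow −x off central 0, two grow +x off
    central 1).  Depth-first placement keeps excluded-volume jams local,
    so backtracking during growth unwinds the segments that caused them."""
    children: dict[int, list] = {}
    for p_, i_, c_ in topology.segments:
        children.setdefault(int(p_), []).append((int(p_), int(i_), int(c_)))
    order: list[tuple[int, int, int]] = []
    dirs: list[int] = []

    def rec(unit: int, d: int) -> None:
        for seg in children.get(unit, []):
            order.append(seg)
            dirs.append(d)
            rec(seg[2], d)

    for central, d in ((0, -1), (1, 1)):
        for seg in children.get(central, []):
            order.append(seg)
            dirs.append(d)
            rec(seg[2], d)
    return np.array(order, dtype=np.int64), np.array(dirs, dtype=np.int64)


def grow_conformation(
    topology: DendrimerTopology,
    rng: np.random.Generator,
    box: LatticeBox | None = None,
    anchor=(0, 0, 0),
    axis_limits: tuple[tuple[int, int], int] | None = None,
    occupancy: OccupancyGrid | None = None,
    segment_attempts: int = 300,
    max_restarts: int = 10_000,
    anchor_jitter: int = 0,
    rod_flip_prob: float = 0.9,
) -> np.ndarray:
    """Grow a self-avoiding conformation of *topology* by rejection.

    The two centrals are joined by a (3,0,0) bond; each segment is
    realised as two identical randomly chosen bond vectors with the
    intermediate at the midpoint.  Placements that overlap already
    placed units (minimum-image Chebyshev distance < 2) are rejected;
    a jammed segment backtracks (progressively deeper on repeated
    failures), and an exhausted backtracking budget restarts the whole
    molecule, up to ``max_restarts`` times.

    Parameters
    ----------
    axis_limits : ((axis_a, axis_b), extent), optional
        Confine growth to a fixed window of ``extent`` lattice sites
        along axes 1 and 2 (y, z), producing the elongated "rod"
        conformations used to equilibrate congested systems.  Bond draws
        are then biased so each gen-0 subtree extends along its own ±x
        direction (``rod_flip_prob``), which is what makes dense rods
        reachable by random growth; the bias only shapes the *initial*
        state and is erased by equilibration.
    occupancy : shared grid, optional
        When given, the molecule also avoids units of previously placed
        molecules and the accepted conformation is registered in it.
    anchor_jitter : int
        After a failed start, displace the anchor uniformly within this
        many sites (rescues anchors blocked by earlier molecules).

    Returns unwrapped integer coordinates, shape (N, 3).

    Raises :class:`ConformationError` (with the attempt count) when the
    restart budget is exhausted; generations above 5 are generally not
    reachable for this dendrimer architecture.
    """
    if box is None:
        # generous default: maximal radial extent is ~6(G+2) sites
        box = LatticeBox(16 * (topology.G + 2))
    bonds = _allowed_bond_array()
    anchor = np.asarray(anchor, dtype=np.int64)

    if axis_limits is not None:
        axes, extent = tuple(axis_limits[0]), int(axis_limits[1])
        if tuple(sorted(axes)) != (1, 2):
            raise ValueError("axis limits are supported on axes (1, 2) (y, z)")
        flip_prob = rod_flip_prob
    else:
        extent = 4 * box.L  # no confinement
        flip_prob = 0.0

    segments, dirs = _dfs_segments(topology)
    grid = occupancy.counts if occupancy is not None else OccupancyGrid(box).counts
    coords = np.zeros((topology.n_units, 3), dtype=np.int64)
    seed = int(rng.integers(0, 2**31))
    ok, restarts, attempts = grow_kernel(
        grid, box.L, coords, segments, dirs, bonds,
        int(anchor[0]), int(anchor[1]), int(anchor[2]),
        extent, flip_prob, segment_attempts, max_restarts,
        20, anchor_jitter, seed,
    )
    if not ok:
        raise ConformationError(
            f"failed to grow G={topology.G} conformation after "
            f"{restarts} restarts ({attempts} placement attempts)",
            attempts=attempts,
        )
    return coords


@dataclass
class SystemState:
    """A many-molecule BFM system on a periodic cubic lattice.

    Coordinates are *unwrapped* (the source of truth); wrapped positions
    are derived modulo L for occupancy and scattering.  ``mol_id`` maps
    each unit to its molecule; all molecules share ``topology``.
    """

    box: LatticeBox
    topology: DendrimerTopology
    n_t: int
    coords: np.ndarray  # int64[n_t*N, 3], unwrapped
    energy_table: BondEnergyTable = field(default_factory=BondEnergyTable)
    occupancy: OccupancyGrid | None = None

    def __post_init__(self) -> None:
        n = self.n_t * self.topology.n_units
        if self.coords.shape != (n, 3):
            raise ValueError(
                f"coords shape {self.coords.shape} != ({n}, 3) for "
                f"n_t={self.n_t}, N={self.topology.n_units}"
            )
        if self.occupancy is None:
            # non-strict: external snapshots may be invalid; the validator,
            # not state construction, is the place that reports that
            occ = OccupancyGrid(self.box)
            occ.place_many(self.box.wrap(self.coords), strict=False)
            self.occupancy = occ

    @property
    def n_units_total(self) -> int:
        return self.n_t * self.topology.n_units

    @property
    def phi(self) -> float:
        """Volume fraction Φ = n_t · 8N / L³ (exact rational, as float)."""
        return self.n_t * self.topology.site_mass / self.box.L**3

    @property
    def mol_id(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_t), self.topology.n_units)

    def all_edges(self) -> np.ndarray:
        """Bond list over all molecules (unit ids offset per molecule)."""
        N = self.topology.n_units
        offsets = (np.arange(self.n_t) * N)[:, None, None]
        return (self.topology.edges[None, :, :] + offsets).reshape(-1, 2)

    def molecule_coords(self, i: int) -> np.ndarray:
        N = self.topology.n_units
        return self.coords[i * N : (i + 1) * N]

    def wrapped(self) -> np.ndarray:
        return self.box.wrap(self.coords)

    def copy(self) -> "SystemState":
        return SystemState(
            box=self.box,
            topology=self.topology,
            n_t=self.n_t,
            coords=self.coords.copy(),
            energy_table=self.energy_table,
        )


def _anchor_grid(L: int, n_t: int) -> np.ndarray:
    """Regular cubic sublattice anchors maximising nearest spacing."""
    k = 1
    while k**3 < n_t:
        k += 1
    spacing = L // k
    pts = []
    for i in range(k):
        for j in range(k):
            for m in range(k):
                pts.append((i * spacing, j * spacing, m * spacing))
    return np.array(pts[:n_t], dtype=np.int64)


def build_system(
    G: int,
    L: int,
    target_phi: float,
    mode: str = "regular",
    rng: np.random.Generator | None = None,
    n_t: int | None = None,
    energy_table: BondEnergyTable | None = None,
    **grow_kwargs,
) -> SystemState:
    """Assemble ``n_t = round(Φ L³ / 8N)`` molecules at maximal spacing.

    ``mode='rod'`` grows conformations confined to an 8-site slab along
    two axes, which opens interpenetration channels in congested systems.
    The achieved volume fraction is reported exactly as n_t·8N/L³ via
    ``SystemState.phi``.
    """
    if mode not in ("regular", "rod"):
        raise ValueError(f"mode must be 'regular' or 'rod', got {mode!r}")
    rng = rng if rng is not None else np.random.default_rng()
    topo = build_topology(G)
    box = LatticeBox(L)
    if n_t is None:
        n_t = int(round(target_phi * L**3 / topo.site_mass))
    if n_t < 1:
        raise InfeasibleDensityError(
            f"target Φ={target_phi} on L={L} yields n_t=0 molecules of G={G}"
        )
    anchors = _anchor_grid(L, n_t)
    axis_limits = (((1, 2), 8) if mode == "rod" else None)
    occ = OccupancyGrid(box)
    coords = np.empty((n_t * topo.n_units, 3), dtype=np.int64)
    for i, anchor in enumerate(anchors):
        try:
            spacing = L // max(1, int(round(n_t ** (1 / 3) + 0.49)))
            conf = grow_conformation(
                topo, rng, box=box, anchor=anchor,
                axis_limits=axis_limits, occupancy=occ,
                anchor_jitter=max(2, spacing // 4), **grow_kwargs,
            )
        except ConformationError as err:
            raise InfeasibleDensityError(
                f"placement of molecule {i + 1}/{n_t} failed "
                f"(Φ={n_t * topo.site_mass / L**3:.3f}): {err}"
            ) from err
        coords[i * topo.n_units : (i + 1) * topo.n_units] = conf
    return SystemState(
        box=box, topology=topo, n_t=n_t, coords=coords,
        energy_table=energy_table or BondEnergyTable(), occupancy=occ,
    )


def overlap_fraction_bound(M: float, R_ce: float) -> float:
    """Maximum no-overlap volume fraction for hard spheres of radius R_ce.

    Φ_over = 0.74 · M / (4πR_ce³/3): the densest packing of tangent
    spheres (occupation factor 0.74) carrying the molecular site mass M.
    """
    if R_ce <= 0:
        raise ValueError(f"R_ce must be positive, got {R_ce}")
    return 0.74 * M / (4.0 * np.pi * R_ce**3 / 3.0)
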