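"""Simple-cubic lattice geometry for the bond fluctuation model (BFM).

In the BFM each monomer unit sits on a lattice site and blocks the 26
neighbouring sites, so no two unit centres may come closer than a
Chebyshev (chessboard) distance of 2 — the hard excluded volume that
models good-solvent repulsion.  Bonds between connected units are
restricted to the 108 lattice vectors obtained from the sign and
permutation orbits of (2,0,0), (2,1,0), (2,1,1), (2,2,1), (3,0,0) and
(3,1,0); the (±2,±2,0) family is excluded because such bonds could be
crossed during single-site moves.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BOND_CLASS_REPRESENTATIVES",
    "allowed_bond_set",
    "bond_allowed_lut",
    "bond_class_lut",
    "LatticeBox",
    "BondEnergyTable",
    "units_overlap",
    "OccupancyGrid",
    "OverlapError",
]

#: Canonical representatives of the six allowed bond classes.
BOND_CLASS_REPRESENTATIVES: tuple[tuple[int, int, int], ...] = (
    (2, 0, 0),
    (2, 1, 0),
    (2, 1, 1),
    (2, 2, 1),
    (3, 0, 0),
    (3, 1, 0),
)

#: Maximum absolute bond component; used to size lookup tables.
MAX_BOND_COMPONENT = 3


class OverlapError(ValueError):
    """Raised when a unit is placed onto an excluded-volume-blocked site."""


def _orbit(rep: tuple[int, int, int]) -> set[tuple[int, int, int]]:
    """All distinct sign flips and coordinate permutations of *rep*."""
    out: set[tuple[int, int, int]] = set()
    for perm in itertools.permutations(rep):
        for signs in itertools.product((1, -1), repeat=3):
            out.add((perm[0] * signs[0], perm[1] * signs[1], perm[2] * signs[2]))
    return out


def allowed_bond_set() -> frozenset[tuple[int, int, int]]:
    """The canonical 108-vector BFM bond set.

    Returns the union of the sign/permutation orbits of the six class
    representatives.  Squared lengths are restricted to {4, 5, 6, 9, 10};
    the crossable (±2, ±2, 0) class is absent.
    """
    out: set[tuple[int, int, int]] = set()
    for rep in BOND_CLASS_REPRESENTATIVES:
        out |= _orbit(rep)
    return frozenset(out)


def bond_allowed_lut() -> np.ndarray:
    """Boolean membership table, indexed by ``[bx+3, by+3, bz+3]``."""
    lut = np.zeros((7, 7, 7), dtype=np.bool_)
    for b in allowed_bond_set():
        lut[b[0] + 3, b[1] + 3, b[2] + 3] = True
    return lut


def bond_class_lut() -> np.ndarray:
    """Class-index table (0..5 in the order of ``BOND_CLASS_REPRESENTATIVES``);
    −1 marks disallowed vectors.  Indexed by ``[bx+3, by+3, bz+3]``."""
    lut = np.full((7, 7, 7), -1, dtype=np.int8)
    for ci, rep in enumerate(BOND_CLASS_REPRESENTATIVES):
        for b in _orbit(rep):
            lut[b[0] + 3, b[1] + 3, b[2] + 3] = ci
    return lut


@dataclass(frozen=True)
class LatticeBox:
    """Cubic periodic simulation box of integer edge ``L`` (lattice units)."""

    L: int
    periodic: bool = True

    def __post_init__(self) -> None:
        if self.L < 8:
            raise ValueError(f"box edge must be >= 8 lattice sites, got {self.L}")

    def wrap(self, coords: np.ndarray) -> np.ndarray:
        """Map (possibly unwrapped) integer coordinates into [0, L)."""
        return np.mod(coords, self.L)

    def min_image(self, d: np.ndarray) -> np.ndarray:
        """Minimum-image component differences in (−L/2, L/2]."""
        d = np.mod(d, self.L)
        return np.where(d > self.L / 2, d - self.L, d)


class BondEnergyTable:
    """Per-class bond energies in units of k_B T.

    The model assigns one energy to each of the six bond-vector classes;
    the default table is all-zero (athermal), in which case the Metropolis
    rule reduces to the pure connectivity + excluded-volume check.
    """

    #: stable textual labels for the six classes
    LABELS = tuple("".join(str(c) for c in rep) for rep in BOND_CLASS_REPRESENTATIVES)

    def __init__(self, energies: dict[str, float] | None = None):
        table = {label: 0.0 for label in self.LABELS}
        if energies:
            for key, value in energies.items():
                if key not in table:
                    raise KeyError(
                        f"unknown bond class {key!r}; expected one of {self.LABELS}"
                    )
                table[key] = float(value)
                if not np.isfinite(table[key]):
                    raise ValueError(f"energy for class {key!r} must be finite")
        self._table = table

    def energy_array(self) -> np.ndarray:
        """Energies as float64[6], ordered like ``BOND_CLASS_REPRESENTATIVES``."""
        return np.array([self._table[label] for label in self.LABELS], dtype=np.float64)

    def as_dict(self) -> dict[str, float]:
        return dict(self._table)

    @property
    def athermal(self) -> bool:
        return all(v == 0.0 for v in self._table.values())

    @classmethod
    def from_json(cls, text: str) -> "BondEnergyTable":
        return cls(json.loads(text))

    def to_json(self) -> str:
        return json.dumps(self._table, sort_keys=True)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, BondEnergyTable) and self._table == other._table

    def __repr__(self) -> str:
        return f"BondEnergyTable({self._table!r})"


def units_overlap(p, q, box: LatticeBox) -> bool:
    """True iff two unit centres violate the excluded-volume condition.

    Centres conflict when their minimum-image Chebyshev distance is <= 1,
    i.e. they coincide or each lies among the other's 26 blocked sites.
    """
    d = np.mod(np.asarray(p, dtype=np.int64) - np.asarray(q, dtype=np.int64), box.L)
    d = np.minimum(d, box.L - d)
    return bool(np.max(d) <= 1)


# relative offsets of the 27-site blocked neighbourhood (incl. the centre)
_NEIGHBOUR_OFFSETS = np.array(
    list(itertools.product((-1, 0, 1), repeat=3)), dtype=np.int64
)


@dataclass
class OccupancyGrid:
    """Dense blocked-count bookkeeping for the excluded-volume condition.

    ``counts[c]`` holds the number of unit centres within Chebyshev
    distance 1 of site ``c`` (every centre contributes to its own 27-site
    neighbourhood).  A site is blocked for a new centre iff its count is
    nonzero.  Incremental updates cost 27 cells per place/remove.
    """

    box: LatticeBox
    counts: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        L = self.box.L
        self.counts = np.zeros((L, L, L), dtype=np.uint8)

    def _cells(self, pos) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        cells = np.mod(np.asarray(pos, dtype=np.int64) + _NEIGHBOUR_OFFSETS, self.box.L)
        return cells[:, 0], cells[:, 1], cells[:, 2]

    def blocked(self, pos) -> bool:
        """True iff a new unit centre may not be placed at ``pos``."""
        w = np.mod(np.asarray(pos, dtype=np.int64), self.box.L)
        return bool(self.counts[w[0], w[1], w[2]] > 0)

    def place(self, pos, strict: bool = True) -> None:
        """Register a unit centre; raises :class:`OverlapError` if blocked.

        ``strict=False`` skips the excluded-volume check (bookkeeping for
        externally supplied, possibly invalid, states).
        """
        if strict and self.blocked(pos):
            raise OverlapError(f"site {tuple(np.asarray(pos) % self.box.L)} is blocked")
        i, j, k = self._cells(pos)
        np.add.at(self.counts, (i, j, k), 1)

    def remove(self, pos) -> None:
        """Unregister a unit centre previously placed at ``pos``."""
        i, j, k = self._cells(pos)
        if self.counts[i[13], j[13], k[13]] == 0:  # offset (0,0,0) is row 13
            raise ValueError(f"no unit registered at {tuple(pos)}")
        np.subtract.at(self.counts, (i, j, k), 1)

    def place_many(self, coords: np.ndarray, strict: bool = True) -> None:
        for row in np.asarray(coords, dtype=np.int64):
            self.place(row, strict=strict)
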