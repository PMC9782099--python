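"""Brute-force state validation: the oracle behind all fast bookkeeping.

Checks every bond against the allowed 108-vector set (on unwrapped
coordinates) and every unit pair against the excluded-volume condition
(minimum-image Chebyshev distance >= 2).  O(n²), intended for small
systems and spot checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .builder import SystemState
from .lattice import bond_allowed_lut

__all__ = ["ValidationReport", "validate_state", "brute_force_blocked_map"]

_BOND_OK = bond_allowed_lut()


@dataclass
class ValidationReport:
    """Lists of violations; empty report ⇔ valid state."""

    bond_violations: list = field(default_factory=list)   # (a, b, bond_vector)
    overlap_pairs: list = field(default_factory=list)     # (a, b, chebyshev)

    @property
    def ok(self) -> bool:
        return not self.bond_violations and not self.overlap_pairs

    def summary(self) -> str:
        if self.ok:
            return "valid: no bond or overlap violations"
        return (
            f"INVALID: {len(self.bond_violations)} bond violation(s), "
            f"{len(self.overlap_pairs)} overlap pair(s)"
        )


def validate_state(state: SystemState, max_pairs_chunk: int = 2_000_000) -> ValidationReport:
    """All-pairs excluded-volume scan + per-bond set membership."""
    report = ValidationReport()
    coords = state.coords
    L = state.box.L

    for a, b in state.all_edges():
        bond = coords[b] - coords[a]
        if np.max(np.abs(bond)) > 3 or not _BOND_OK[tuple(bond + 3)]:
            report.bond_violations.append((int(a), int(b), tuple(int(x) for x in bond)))

    wrapped = state.box.wrap(coords)
    n = len(wrapped)
    # chunked all-pairs minimum-image Chebyshev distances
    rows_per_chunk = max(1, max_pairs_chunk // max(1, n))
    for start in range(0, n, rows_per_chunk):
        stop = min(n, start + rows_per_chunk)
        d = np.abs(wrapped[start:stop, None, :] - wrapped[None, :, :])
        d = np.minimum(d, L - d)
        cheb = d.max(axis=2)
        ii, jj = np.where(cheb <= 1)
        for i, j in zip(ii + start, jj):
            if i < j:
                report.overlap_pairs.append((int(i), int(j), int(cheb[i - start, j])))
    return report


def brute_force_blocked_map(centers: np.ndarray, L: int) -> np.ndarray:
    """Blocked-site map from an all-pairs scan (occupancy-grid oracle).

    A site is blocked iff some centre lies within Chebyshev distance 1
    of it (minimum image).
    """
    blocked = np.zeros((L, L, L), dtype=bool)
    ax = np.arange(L)
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    sites = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    for c in np.mod(np.asarray(centers, dtype=np.int64), L):
        d = np.abs(sites - c)
        d = np.minimum(d, L - d)
        hit = d.max(axis=1) <= 1
        blocked.ravel()[hit] = True
    return blocked
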