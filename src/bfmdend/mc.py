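"""Metropolis Monte Carlo bead-jump dynamics on the lattice.

A *bead jump* displaces a single unit to a neighbouring site.  The jump
is accepted when every bond incident to the unit stays in the allowed
set, the target site is free of other units (excluded volume), and the
Metropolis criterion on the bond-energy change passes (automatic for the
athermal default).  One *step* (sweep) is n_t·N jump attempts — each
unit receives, statistically, one chance to move.  Rejected attempts
leave the state unchanged, so the previous configuration is counted
again in any running average.

The default move set is the classical BFM single-site jump along one of
the six lattice directions; ``moves=26`` selects jumps to any of the 26
neighbouring sites instead.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from . import observables as obs
from ._kernels import run_bead_jumps
from .builder import SystemState
from .lattice import bond_allowed_lut, bond_class_lut

__all__ = [
    "MCSchedule",
    "TrajectoryRecords",
    "move_set",
    "metropolis_accept",
    "attempt_bead_jump",
    "run",
    "equilibration_check",
    "equilibrate",
]

MOVES_6 = np.array(
    [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)],
    dtype=np.int64,
)
MOVES_26 = np.array(
    [m for m in itertools.product((-1, 0, 1), repeat=3) if m != (0, 0, 0)],
    dtype=np.int64,
)


def move_set(moves: int) -> np.ndarray:
    if moves == 6:
        return MOVES_6
    if moves == 26:
        return MOVES_26
    raise ValueError(f"move set must be 6 or 26, got {moves}")


@dataclass(frozen=True)
class MCSchedule:
    """Run schedule: counts are in steps (sweeps of n_t·N attempts)."""

    equilibration_steps: int
    production_steps: int
    sample_every: int = 4000
    seed: int = 0
    moves: int = 6

    def __post_init__(self) -> None:
        if self.sample_every < 1:
            raise ValueError("sample_every must be >= 1")
        if self.equilibration_steps < 0 or self.production_steps < 0:
            raise ValueError("step counts must be non-negative")


@dataclass
class TrajectoryRecords:
    """Per-sample, per-molecule observable records from one run.

    ``asph_num``/``asph_den`` are the separately averaged terms of the
    asphericity estimator; ``com`` is unwrapped.  ``snapshots`` holds
    full unwrapped coordinate sets when snapshot storage was requested.
    """

    steps: np.ndarray  # int64[S]
    rg2: np.ndarray    # float64[S, n_t]
    rce2: np.ndarray   # float64[S, n_t]
    asph_num: np.ndarray
    asph_den: np.ndarray
    branch_dist: np.ndarray
    com: np.ndarray    # float64[S, n_t, 3]
    snapshots: list[np.ndarray] = field(default_factory=list)
    snapshot_steps: list[int] = field(default_factory=list)
    attempts: int = 0
    accepted: int = 0

    @property
    def n_samples(self) -> int:
        return int(self.steps.shape[0])

    def shape_summary(self) -> obs.ShapeSummary:
        """Ensemble rms sizes and asphericity over all samples/molecules."""
        rg2 = float(self.rg2.mean())
        rce2 = float(self.rce2.mean())
        A = float(self.asph_num.mean() / self.asph_den.mean())
        return obs.ShapeSummary(
            Rg=math.sqrt(rg2), Rce=math.sqrt(rce2), A=A,
            eigenvalues=(float("nan"),) * 3,
        )


def metropolis_accept(dE: float, rng: np.random.Generator) -> bool:
    """Metropolis rule: accept iff ΔE <= 0 or u < exp(−ΔE), u ~ U[0,1)."""
    if not np.isfinite(dE):
        raise ValueError(f"energy change must be finite, got {dE}")
    if dE <= 0.0:
        return True
    return bool(rng.random() < math.exp(-dE))


_BOND_OK = bond_allowed_lut()
_BOND_CLASS = bond_class_lut()


def _adjacency(state: SystemState) -> tuple[np.ndarray, np.ndarray]:
    """CSR adjacency over all units of all molecules."""
    n = state.n_units_total
    edges = state.all_edges()
    deg = np.zeros(n, dtype=np.int64)
    np.add.at(deg, edges[:, 0], 1)
    np.add.at(deg, edges[:, 1], 1)
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(deg, out=indptr[1:])
    indices = np.empty(indptr[-1], dtype=np.int64)
    cursor = indptr[:-1].copy()
    for a, b in edges:
        indices[cursor[a]] = b
        cursor[a] += 1
        indices[cursor[b]] = a
        cursor[b] += 1
    return indptr, indices


def attempt_bead_jump(
    state: SystemState,
    unit_id: int,
    displacement,
    rng: np.random.Generator,
) -> bool:
    """Reference single-jump attempt (pure Python; mutates *state*).

    Applies, in order: bond-set check on every incident bond, excluded
    volume at the target site, Metropolis on the bond-energy change.
    """
    n = state.n_units_total
    if not 0 <= unit_id < n:
        raise KeyError(f"unknown unit id {unit_id}")
    disp = np.asarray(displacement, dtype=np.int64)
    if np.max(np.abs(disp)) != 1:
        raise ValueError("displacement must target a neighbouring site")
    indptr, indices = _adjacency(state)
    old = state.coords[unit_id].copy()
    new = old + disp
    energies = state.energy_table.energy_array()

    dE = 0.0
    for v in indices[indptr[unit_id] : indptr[unit_id + 1]]:
        b_new = state.coords[v] - new
        if np.max(np.abs(b_new)) > 3 or not _BOND_OK[tuple(b_new + 3)]:
            return False
        b_old = state.coords[v] - old
        dE += energies[_BOND_CLASS[tuple(b_new + 3)]]
        dE -= energies[_BOND_CLASS[tuple(b_old + 3)]]

    occ = state.occupancy
    w_new = state.box.wrap(new)
    # the mover's own contribution blocks the target cell exactly once
    if occ.counts[w_new[0], w_new[1], w_new[2]] != 1:
        return False

    if not metropolis_accept(dE, rng):
        return False

    occ.remove(state.box.wrap(old))
    occ.place(w_new)
    state.coords[unit_id] = new
    return True


def _collect_sample(state: SystemState, records: dict, step: int,
                    store_snapshot: bool) -> None:
    topo = state.topology
    outer = topo.outer_unit_ids()
    rg2 = np.empty(state.n_t)
    rce2 = np.empty(state.n_t)
    num = np.empty(state.n_t)
    den = np.empty(state.n_t)
    bdist = np.empty(state.n_t)
    com = np.empty((state.n_t, 3))
    for i in range(state.n_t):
        c = state.molecule_coords(i).astype(np.float64)
        eig = obs.gyration_eigenvalues(c)
        rg2[i] = eig.sum()
        num[i], den[i] = obs.asphericity_terms(eig)
        rce2[i] = obs.center_to_end(c, outer)
        bdist[i] = obs.mean_branch_distance(c, topo.segments)
        com[i] = c.mean(axis=0)
    records["steps"].append(step)
    records["rg2"].append(rg2)
    records["rce2"].append(rce2)
    records["asph_num"].append(num)
    records["asph_den"].append(den)
    records["branch_dist"].append(bdist)
    records["com"].append(com)
    if store_snapshot:
        records["snapshots"].append(state.coords.copy())
        records["snapshot_steps"].append(step)


def run(
    state: SystemState,
    schedule: MCSchedule,
    store_snapshots: bool = False,
    snapshot_every: int = 1,
) -> TrajectoryRecords:
    """Run equilibration then production sweeps, sampling observables.

    Mutates *state* in place.  Properties are collected every
    ``schedule.sample_every`` steps of the production phase (and a final
    sample at the end if the production length is not a multiple of the
    cadence is *not* added — sampling is strictly on-cadence).  With
    identical state, schedule and seed the trajectory is bit-identical.
    """
    topo = state.topology
    n = state.n_units_total
    indptr, indices = _adjacency(state)
    moves = move_set(schedule.moves)
    energies = state.energy_table.energy_array()
    athermal = state.energy_table.athermal
    seeds = np.random.SeedSequence(schedule.seed)
    grid = state.occupancy.counts

    attempts = 0
    accepted = 0

    def advance(n_steps: int) -> None:
        nonlocal attempts, accepted
        if n_steps <= 0:
            return
        n_att = n_steps * n
        seed = int(seeds.spawn(1)[0].generate_state(1, np.uint32)[0])
        accepted += run_bead_jumps(
            state.coords, grid, state.box.L, indptr, indices,
            _BOND_OK, _BOND_CLASS, energies, moves, n_att, seed, athermal,
        )
        attempts += n_att

    advance(schedule.equilibration_steps)

    records: dict = {k: [] for k in (
        "steps", "rg2", "rce2", "asph_num", "asph_den",
        "branch_dist", "com", "snapshots", "snapshot_steps",
    )}
    n_chunks = schedule.production_steps // schedule.sample_every
    for chunk in range(n_chunks):
        advance(schedule.sample_every)
        step = schedule.equilibration_steps + (chunk + 1) * schedule.sample_every
        _collect_sample(state, records, step,
                        store_snapshots and chunk % snapshot_every == 0)
    advance(schedule.production_steps - n_chunks * schedule.sample_every)

    def arr(key):
        if not records[key]:
            shape = (0, state.n_t, 3) if key == "com" else (0, state.n_t)
            return np.empty(shape)
        return np.array(records[key])

    return TrajectoryRecords(
        steps=np.array(records["steps"], dtype=np.int64),
        rg2=arr("rg2"), rce2=arr("rce2"),
        asph_num=arr("asph_num"), asph_den=arr("asph_den"),
        branch_dist=arr("branch_dist"), com=arr("com"),
        snapshots=records["snapshots"],
        snapshot_steps=records["snapshot_steps"],
        attempts=attempts, accepted=accepted,
    )


def equilibration_check(series_a, series_b, tol: float = 0.01) -> bool:
    """True iff paired run means agree within ``tol`` (inclusive).

    ``series_a``/``series_b`` hold one mean per monitored quantity
    (size and asphericity) from two successive runs; the relative
    difference is taken against the first run.
    """
    a = np.atleast_1d(np.asarray(series_a, dtype=np.float64))
    b = np.atleast_1d(np.asarray(series_b, dtype=np.float64))
    if a.size == 0 or b.size == 0:
        raise ValueError("empty series")
    if a.shape != b.shape:
        raise ValueError("series must have matching shapes")
    return bool(np.all(np.abs(a - b) <= tol * np.abs(a)))


def equilibrate(
    state: SystemState,
    block_steps: int,
    seed: int = 0,
    moves: int = 6,
    sample_every: int | None = None,
    tol: float = 0.01,
    max_blocks: int = 50,
    monitor: str = "both",
) -> dict:
    """Run successive equal blocks until the monitored means drift < ``tol``.

    Mirrors the 1% equilibration criterion: the mean size (and, with
    ``monitor='both'``, the mean asphericity) of two successive blocks
    must agree within ``tol``.  ``monitor='rg'`` gates on the size only —
    at short block lengths the asphericity block means carry statistical
    noise well above 1%, so gating on A would demand production-scale
    blocks; A is still recorded in the history.  Returns a report dict
    with the number of blocks run and the block means; raises
    ``RuntimeError`` if ``max_blocks`` is exhausted.
    """
    if monitor not in ("both", "rg"):
        raise ValueError("monitor must be 'both' or 'rg'")
    sample_every = sample_every or max(1, block_steps // 50)
    prev = None
    history = []
    for block in range(max_blocks):
        rec = run(state, MCSchedule(
            equilibration_steps=0, production_steps=block_steps,
            sample_every=sample_every, seed=seed + block, moves=moves,
        ))
        summ = rec.shape_summary()
        cur = (summ.Rg, summ.A)
        history.append(cur)
        if prev is not None:
            gate = slice(None) if monitor == "both" else slice(0, 1)
            if equilibration_check(prev[gate], cur[gate], tol=tol):
                return {"blocks": block + 1, "block_steps": block_steps,
                        "history": history, "converged": True}
        prev = cur
    raise RuntimeError(
        f"equilibration not reached after {max_blocks} blocks of {block_steps} steps"
    )
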