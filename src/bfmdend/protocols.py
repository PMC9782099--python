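"""Canonical run protocols for single-molecule (dilute-limit) studies.

At the lowest volume fractions studied with this model the molecules are
effectively isolated, so single-molecule runs in a production-size box
reproduce the dilute-limit sizes, shapes and intramolecular distances.
The protocol below grows one molecule, equilibrates it in blocks until
the mean size and asphericity of successive blocks agree within 1%
(topping up to a requested minimum), and then samples a production
trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .builder import SystemState, build_system
from .mc import MCSchedule, TrajectoryRecords, equilibrate, run

__all__ = ["IsolatedMoleculeResult", "isolated_molecule_run"]


@dataclass
class IsolatedMoleculeResult:
    """State + production records + summary scalars of a dilute-limit run."""

    state: SystemState
    records: TrajectoryRecords
    equilibration_sweeps: int
    Rg: float
    Rce: float
    A: float
    mean_branch_distance: float

    @property
    def rce_over_rg(self) -> float:
        return self.Rce / self.Rg


def isolated_molecule_run(
    G: int,
    L: int,
    production_sweeps: int,
    sample_every: int = 500,
    seed: int = 0,
    min_equilibration_sweeps: int = 100_000,
    equilibration_block: int = 50_000,
    moves: int = 6,
) -> IsolatedMoleculeResult:
    """Equilibrate and sample one generation-G molecule in an L-box.

    Equilibration runs in blocks of ``equilibration_block`` sweeps until
    the block means of Rg and A drift by at most 1% between successive
    blocks, and never less than ``min_equilibration_sweeps`` in total.
    Production then collects shape observables every ``sample_every``
    sweeps.  Fully deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    state = build_system(G=G, L=L, target_phi=0.0, n_t=1, rng=rng, mode="regular")

    report = equilibrate(
        state, block_steps=equilibration_block, seed=seed + 1, moves=moves,
        monitor="rg",
        max_blocks=max(8, 8 * min_equilibration_sweeps // equilibration_block),
    )
    done = report["blocks"] * equilibration_block
    if done < min_equilibration_sweeps:
        run(state, MCSchedule(
            equilibration_steps=min_equilibration_sweeps - done,
            production_steps=0, sample_every=sample_every,
            seed=seed + 2, moves=moves,
        ))
        done = min_equilibration_sweeps

    rec = run(state, MCSchedule(
        equilibration_steps=0, production_steps=production_sweeps,
        sample_every=sample_every, seed=seed + 3, moves=moves,
    ))
    summary = rec.shape_summary()
    return IsolatedMoleculeResult(
        state=state, records=rec, equilibration_sweeps=done,
        Rg=summary.Rg, Rce=summary.Rce, A=summary.A,
        mean_branch_distance=float(rec.branch_dist.mean()),
    )
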