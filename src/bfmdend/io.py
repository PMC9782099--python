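"""Configuration, serialization and result writers.

Run configurations load from TOML and hash to a short digest that every
writer embeds in its output header, together with the package version
and master seed, so result files are traceable to the exact run setup.
Snapshots use an extended-XYZ-like plain-text format; profiles and
observable tables are CSV; potentials are JSON.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .builder import SystemState, build_topology
from .lattice import BondEnergyTable, LatticeBox
from .scattering import RadialDistribution, ScatteringProfile

__all__ = [
    "RunConfig",
    "config_hash",
    "write_snapshot",
    "read_snapshot",
    "write_profile_csv",
    "write_rdf_csv",
    "write_topology_csv",
    "write_summary_json",
]

_ROLE_NAMES = {0: "central", 1: "branching", 2: "intermediate"}
_ROLE_CODES = {v: k for k, v in _ROLE_NAMES.items()}


@dataclass(frozen=True)
class RunConfig:
    """Complete, serialisable description of a simulation run."""

    generation: int = 4
    box: int = 96
    #: global-property runs (g(R), S(q)) use a doubled box edge so the
    #: box stays well above ~2.5 molecular diameters
    double_box: bool = False
    phi: float = 0.041
    n_t: int | None = None
    init_mode: str = "regular"
    moves: int = 6
    equilibration_steps: int = 100_000
    production_steps: int = 100_000
    sample_every: int = 4000
    seed: int = 0
    bond_energies: dict = field(default_factory=dict)
    qmax: float = 1.0
    smooth_window: int = 3
    rdf_bin_width: float = 1.0
    potential_tries: int = 100_000
    potential_bins: int = 200
    potential_min_tries: int = 26

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def energy_table(self) -> BondEnergyTable:
        return BondEnergyTable(self.bond_energies or None)

    @property
    def effective_box(self) -> int:
        return 2 * self.box if self.double_box else self.box


def config_hash(config: RunConfig) -> str:
    """Stable 12-hex digest of the canonical JSON form of the config."""
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header_lines(config: RunConfig | None, extra: dict | None = None) -> list[str]:
    meta = {"version": __version__}
    if config is not None:
        meta["config_hash"] = config_hash(config)
        meta["seed"] = config.seed
    if extra:
        meta.update(extra)
    return [f"# {k}={v}" for k, v in meta.items()]


def write_snapshot(path: str | Path, state: SystemState,
                   config: RunConfig | None = None, step: int | None = None) -> None:
    """Extended-XYZ-like text: count, metadata comment, then
    ``id role generation molecule x y z`` rows (unwrapped coordinates)."""
    topo = state.topology
    mol = state.mol_id
    roles = np.tile(topo.roles, state.n_t)
    gens = np.tile(topo.generations, state.n_t)
    lines = [str(state.n_units_total)]
    meta = {"L": state.box.L, "G": topo.G, "n_t": state.n_t, "step": step,
            "version": __version__}
    if config is not None:
        meta["config_hash"] = config_hash(config)
    lines.append(" ".join(f"{k}={v}" for k, v in meta.items() if v is not None))
    for i in range(state.n_units_total):
        x, y, z = state.coords[i]
        lines.append(
            f"{i} {_ROLE_NAMES[int(roles[i])]} {int(gens[i])} {int(mol[i])} "
            f"{x} {y} {z}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_snapshot(path: str | Path) -> SystemState:
    """Read a snapshot written by :func:`write_snapshot`."""
    lines = Path(path).read_text().strip().splitlines()
    n = int(lines[0])
    meta = dict(kv.split("=", 1) for kv in lines[1].split() if "=" in kv)
    L = int(meta["L"])
    G = int(meta["G"])
    n_t = int(meta["n_t"])
    coords = np.empty((n, 3), dtype=np.int64)
    for row, line in enumerate(lines[2 : 2 + n]):
        parts = line.split()
        coords[row] = [int(parts[4]), int(parts[5]), int(parts[6])]
    return SystemState(
        box=LatticeBox(L), topology=build_topology(G), n_t=n_t, coords=coords
    )


def write_profile_csv(path: str | Path, profile: ScatteringProfile,
                      config: RunConfig | None = None) -> None:
    df = pd.DataFrame({"q": profile.q, profile.kind: profile.value,
                       "n_vectors": profile.counts})
    header = "\n".join(_header_lines(config, {"kind": profile.kind}))
    with open(path, "w") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, index=False)


def write_rdf_csv(path: str | Path, dist: RadialDistribution,
                  config: RunConfig | None = None) -> None:
    df = pd.DataFrame({"R": dist.centers, "g": dist.g,
                       "pair_count": dist.pair_counts})
    header = "\n".join(_header_lines(config, {
        "n_configs": dist.n_configs, "n_t": dist.n_t, "L": dist.L}))
    with open(path, "w") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, index=False)


def write_topology_csv(path: str | Path, G: int) -> None:
    """Edge-list export: unit id, role, generation, neighbour ids."""
    topo = build_topology(G)
    nbrs: list[list[int]] = [[] for _ in range(topo.n_units)]
    for a, b in topo.edges:
        nbrs[a].append(int(b))
        nbrs[b].append(int(a))
    df = pd.DataFrame({
        "id": np.arange(topo.n_units),
        "role": [_ROLE_NAMES[int(r)] for r in topo.roles],
        "generation": topo.generations,
        "neighbors": [";".join(map(str, sorted(x))) for x in nbrs],
    })
    df.to_csv(path, index=False)


def write_summary_json(path: str | Path, summary: dict,
                       config: RunConfig | None = None) -> None:
    out = dict(summary)
    out["_meta"] = {"version": __version__}
    if config is not None:
        out["_meta"]["config_hash"] = config_hash(config)
        out["_meta"]["seed"] = config.seed
    Path(path).write_text(json.dumps(out, indent=1, default=float) + "\n")
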