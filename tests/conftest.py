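import numpy as np
import pytest

import bfmdend as bd
from bfmdend.mc import MCSchedule, run


@pytest.fixture(scope="session")
def g1_single_state():
    """One equilibrated-ish G1 molecule in a small box (session-shared)."""
    rng = np.random.default_rng(42)
    state = bd.build_system(G=1, L=32, target_phi=0.0, n_t=1, rng=rng)
    run(state, MCSchedule(equilibration_steps=2000, production_steps=0,
                          sample_every=100, seed=7))
    return state


@pytest.fixture(scope="session")
def g2_dilute_records():
    """A small multi-molecule G2 system with a short production run."""
    rng = np.random.default_rng(3)
    state = bd.build_system(G=2, L=48, target_phi=0.05, rng=rng)
    rec = run(state, MCSchedule(equilibration_steps=2000, production_steps=8000,
                                sample_every=200, seed=9), store_snapshots=True)
    return state, rec
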