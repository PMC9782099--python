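"""Metropolis rule, bead-jump semantics and trajectory invariants."""

import numpy as np
import pytest

import bfmdend as bd
from bfmdend.builder import DendrimerTopology, SystemState, build_system
from bfmdend.lattice import LatticeBox
from bfmdend.mc import (
    MCSchedule,
    attempt_bead_jump,
    equilibration_check,
    metropolis_accept,
    run,
)
from bfmdend.validate import validate_state


class TestMetropolis:
    def test_nonpositive_always_accepts(self):
        rng = np.random.default_rng(0)
        assert all(metropolis_accept(0.0, rng) for _ in range(100))
        assert all(metropolis_accept(-1.0, rng) for _ in range(100))

    def test_uphill_rate_matches_boltzmann(self):
        """P(accept | dE=1) = e^-1 within 3 sigma over 1e5 trials."""
        rng = np.random.default_rng(1)
        n = 100_000
        hits = sum(metropolis_accept(1.0, rng) for _ in range(n))
        p = np.exp(-1.0)
        sigma = np.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) < 3 * sigma

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            metropolis_accept(float("nan"), np.random.default_rng(0))


class TestBeadJump:
    def test_athermal_unconstrained_move_accepts(self, g1_single_state):
        state = g1_single_state.copy()
        rng = np.random.default_rng(0)
        # displace the whole molecule's most isolated unit along +x until
        # one legal move is found; acceptance must then be deterministic
        accepted = 0
        attempts = 0
        for unit in range(state.n_units_total):
            for disp in ((1, 0, 0), (0, 1, 0), (0, 0, 1)):
                before = state.coords.copy()
                ok = attempt_bead_jump(state, unit, disp, rng)
                attempts += 1
                if ok:
                    accepted += 1
                    assert not np.array_equal(before, state.coords)
                else:
                    assert np.array_equal(before, state.coords)
        assert accepted > 0  # a dilute molecule always has movable units
        assert validate_state(state).ok

    def test_unknown_unit_raises(self, g1_single_state):
        with pytest.raises(KeyError):
            attempt_bead_jump(g1_single_state.copy(), 10_000, (1, 0, 0),
                              np.random.default_rng(0))

    @staticmethod
    def _two_dimer_state():
        """Two bonded dimers: unit 0 one step below unit 2's blocked zone."""
        topo = DendrimerTopology(
            G=0,
            roles=np.ones(4, dtype=np.int8),
            generations=np.zeros(4, dtype=np.int8),
            edges=np.array([[0, 1], [2, 3]], dtype=np.int64),
            segments=np.empty((0, 3), dtype=np.int64),
        )
        coords = np.array(
            [[0, 0, 0], [3, 0, 0], [0, 2, 0], [3, 2, 0]], dtype=np.int64
        )
        return SystemState(box=LatticeBox(16), topology=topo, n_t=1,
                           coords=coords)

    def test_move_onto_blocked_site_rejected(self):
        state = self._two_dimer_state()
        rng = np.random.default_rng(0)
        # bond 0-1 would become (3,-1,0): allowed — the rejection is
        # purely excluded volume (target within 1 of unit 2)
        assert attempt_bead_jump(state, 0, (0, 1, 0), rng) is False
        # moving away instead is legal
        assert attempt_bead_jump(state, 0, (0, -1, 0), rng) is True

    def test_move_breaking_bond_set_rejected(self):
        state = self._two_dimer_state()
        rng = np.random.default_rng(0)
        # bond 0-1 would become (4,0,0): outside the allowed set
        assert attempt_bead_jump(state, 0, (-1, 0, 0), rng) is False


class TestRun:
    def test_zero_production_yields_empty_records(self, g1_single_state):
        state = g1_single_state.copy()
        before = state.coords.copy()
        rec = run(state, MCSchedule(equilibration_steps=0, production_steps=0,
                                    sample_every=10, seed=3))
        assert rec.n_samples == 0
        assert np.array_equal(before, state.coords)

    def test_validity_preserved_after_random_moves(self, g2_dilute_records):
        state, _ = g2_dilute_records
        assert validate_state(state).ok

    def test_reproducibility_bit_identical(self):
        rng1 = np.random.default_rng(7)
        s1 = build_system(G=1, L=32, target_phi=0.0, n_t=1, rng=rng1)
        rng2 = np.random.default_rng(7)
        s2 = build_system(G=1, L=32, target_phi=0.0, n_t=1, rng=rng2)
        sched = MCSchedule(equilibration_steps=500, production_steps=1500,
                           sample_every=100, seed=11)
        r1 = run(s1, sched)
        r2 = run(s2, sched)
        assert np.array_equal(s1.coords, s2.coords)
        assert np.array_equal(r1.rg2, r2.rg2)
        assert r1.accepted == r2.accepted

    def test_26_move_set_also_preserves_validity(self):
        rng = np.random.default_rng(13)
        state = build_system(G=1, L=32, target_phi=0.0, n_t=1, rng=rng)
        run(state, MCSchedule(equilibration_steps=0, production_steps=2000,
                              sample_every=500, seed=2, moves=26))
        assert validate_state(state).ok

    def test_full_lattice_is_frozen(self):
        """At volume fraction 1 (centres on the even sublattice) no unit
        can move: the accepted-move count must be exactly zero."""
        L = 8
        # boustrophedon path over the even sublattice: consecutive sites
        # always differ by a single (2,0,0)-class bond
        pts = []
        xs = range(0, L, 2)
        for i, x in enumerate(xs):
            ys = list(range(0, L, 2))
            if i % 2:
                ys.reverse()
            for j, y in enumerate(ys):
                zs = list(range(0, L, 2))
                if (i + j) % 2:
                    zs.reverse()
                pts.extend((x, y, z) for z in zs)
        coords = np.array(pts, dtype=np.int64)
        n = len(coords)  # 64 units, phi = 8*64/512 = 1
        edges = np.array([[i, i + 1] for i in range(n - 1)], dtype=np.int64)
        topo = DendrimerTopology(
            G=0, roles=np.ones(n, dtype=np.int8),
            generations=np.zeros(n, dtype=np.int8),
            edges=edges, segments=np.empty((0, 3), dtype=np.int64),
        )
        state = SystemState(box=LatticeBox(L), topology=topo, n_t=1,
                            coords=coords)
        assert state.phi == 1.0
        rec = run(state, MCSchedule(equilibration_steps=0,
                                    production_steps=500, sample_every=500,
                                    seed=0))
        assert rec.accepted == 0


class TestEquilibrationCheck:
    def test_identical_series_pass(self):
        assert equilibration_check([12.0, 0.03], [12.0, 0.03])

    def test_five_percent_drift_fails(self):
        assert not equilibration_check([12.0, 0.03], [12.6, 0.03])

    def test_exactly_one_percent_is_inclusive(self):
        assert equilibration_check([100.0], [101.0])

    def test_empty_series_raises(self):
        with pytest.raises(ValueError):
            equilibration_check([], [])
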