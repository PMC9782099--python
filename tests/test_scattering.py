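"""Scattering intensity, form/structure factors, g(R) and factorization."""

import numpy as np
import pytest

from bfmdend.builder import build_system
from bfmdend.fixtures import make_fixture
from bfmdend.scattering import (
    QGrid,
    ScatteringProfile,
    apparent_structure_factor,
    factorized_intensity,
    form_factor,
    intensity,
    intensity_direct_sum,
    rdf,
    smooth_profile,
    sq_from_gr,
    structure_factor_com,
)


def _profile(q, v):
    q = np.asarray(q, dtype=float)
    return ScatteringProfile(q=q, value=np.asarray(v, dtype=float),
                             counts=np.ones_like(q, dtype=np.int64))


class TestQGrid:
    def test_vectors_commensurate_and_binned(self):
        grid = QGrid.build(12, qmax=2.0)
        assert np.all(np.any(grid.hkl != 0, axis=1))
        mags = np.linalg.norm(grid.qvecs, axis=1)
        np.testing.assert_allclose(
            grid.bin_centers[grid.bin_index], mags, atol=np.pi / 12 + 1e-9
        )

    def test_qmax_below_first_mode_raises(self):
        with pytest.raises(ValueError):
            QGrid.build(12, qmax=0.1)

    def test_shell_subsampling_caps_counts(self):
        full = QGrid.build(16, qmax=2.0)
        capped = QGrid.build(16, qmax=2.0, max_per_shell=10,
                             rng=np.random.default_rng(0))
        assert np.all(np.bincount(capped.bin_index,
                                  minlength=capped.n_bins) <= 10)
        assert capped.n_bins == full.n_bins


class TestContrastIdentity:
    def test_site_contrast_sums_to_zero(self):
        """n_t N (1 - phi/8) - (L^3 - n_t N)(phi/8) = 0 exactly."""
        for L, n_units in ((12, 10), (16, 100)):
            phi = 8.0 * n_units / L**3
            total = n_units * (1 - phi / 8) - (L**3 - n_units) * (phi / 8)
            assert total == pytest.approx(0.0, abs=1e-9)

    def test_center_shortcut_equals_full_lattice_sum(self):
        """On an L=12 box the centre-site reduction must reproduce the
        literal L^3-site contrast sum to machine precision."""
        rng = np.random.default_rng(2)
        L = 12
        # 8 random non-overlapping centres
        pts = []
        occ = set()
        while len(pts) < 8:
            p = tuple(rng.integers(0, L, 3))
            if all(max(min(abs(a - b), L - abs(a - b)) for a, b in zip(p, q)) >= 2
                   for q in pts):
                pts.append(p)
        pts = np.array(pts)
        grid = QGrid.build(L, qmax=1.8)
        fast = intensity([pts], grid)
        slow = intensity_direct_sum(pts, L, grid)
        np.testing.assert_allclose(fast.value, slow.value, rtol=1e-9, atol=1e-11)


class TestFormFactor:
    def test_single_molecule_intensity_is_phi_n_p(self, g1_single_state):
        state = g1_single_state
        grid = QGrid.build(state.box.L, qmax=1.0, max_per_shell=40,
                           rng=np.random.default_rng(1))
        prof = intensity([state.wrapped()], grid)
        P = form_factor(prof, state.phi, state.topology.n_units)
        np.testing.assert_allclose(
            prof.value, state.phi * state.topology.n_units * P.value, rtol=1e-12
        )

    def test_form_factor_guinier_limit_at_small_q(self):
        """Compact rigid cluster in a large box: q1*Rg << 1, so the first
        bin must satisfy P ~ 1 - (q Rg)^2/3 (coherent zero-mean limit)."""
        from bfmdend.observables import radius_of_gyration

        L = 64
        ax = np.array([-2, 0, 2])
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1) + 32
        grid = QGrid.build(L, qmax=0.3)
        phi = 8.0 * len(pts) / L**3
        P = form_factor(intensity([pts], grid), phi, len(pts))
        # the first bin averages the (1,0,0) and (1,1,0) shells: use its
        # actual mean q^2 in the expansion
        q2_bin = (grid.qvecs[grid.bin_index == 0] ** 2).sum(axis=1).mean()
        expected = 1.0 - q2_bin * radius_of_gyration(pts) / 3.0
        assert P.value[0] == pytest.approx(expected, abs=0.01)
        assert P.value[0] < 1.0
        # and P decays monotonically over the first few shells
        finite = P.value[np.isfinite(P.value)]
        assert np.all(np.diff(finite[:3]) < 0)

    def test_point_particle_form_factor_is_flat(self):
        grid = QGrid.build(16, qmax=1.5)
        prof = intensity([np.array([[3, 7, 11]])], grid)
        P = form_factor(prof, phi=8 / 16**3, N=1)
        np.testing.assert_allclose(P.value, 1.0, rtol=1e-9)

    def test_zero_phi_raises(self):
        with pytest.raises(ValueError):
            form_factor(_profile([0.1], [1.0]), 0.0, 10)


class TestStructureFactor:
    def test_single_molecule_is_unity(self):
        grid = QGrid.build(32, qmax=1.0, max_per_shell=30,
                           rng=np.random.default_rng(0))
        S = structure_factor_com([np.array([[5.0, 8.0, 2.0]])], grid)
        np.testing.assert_allclose(S.value, 1.0, rtol=1e-12)

    def test_ideal_gas_is_unity_within_noise(self):
        rng = np.random.default_rng(3)
        configs = [rng.uniform(0, 50, size=(100, 3)) for _ in range(200)]
        grid = QGrid.build(50, qmax=1.2, max_per_shell=40, rng=rng)
        S = structure_factor_com(configs, grid)
        # self-term only: S = 1 +- O(1/sqrt(n_cfg * n_vec))
        assert np.nanmax(np.abs(S.value - 1.0)) < 0.35
        assert abs(np.nanmean(S.value) - 1.0) < 0.05
        assert np.all(S.value >= 0.0)


class TestSmoothing:
    def test_window_one_is_identity(self):
        p = _profile([0.1, 0.2, 0.3], [1.0, 5.0, 2.0])
        assert smooth_profile(p, 1) is p

    def test_constant_profile_unchanged(self):
        p = _profile(np.linspace(0.1, 1, 20), np.full(20, 3.3))
        np.testing.assert_allclose(smooth_profile(p, 5).value, 3.3)

    def test_noise_reduced_peak_preserved(self):
        x, noisy, clean = make_fixture("noisy_peak", {"noise": 0.2}, seed=4)
        p = _profile(x, noisy)
        sm = smooth_profile(p, 5)
        assert np.std(sm.value - clean) < np.std(noisy - clean)
        assert abs(int(np.argmax(sm.value)) - int(np.argmax(clean))) <= 1

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smooth_profile(_profile([0.1], [1.0]), 2)


class TestRdf:
    def test_uniform_points_give_unit_g(self):
        rng = np.random.default_rng(5)
        configs = [rng.uniform(0, 40, size=(120, 3)) for _ in range(150)]
        dist = rdf(configs, L=40, bin_width=1.0)
        inner = dist.g[4:]  # skip sparsely populated first shells
        assert np.all(np.abs(inner - 1.0) < 0.15)
        assert abs(inner.mean() - 1.0) < 0.02

    def test_two_fixed_points_single_bin(self):
        coms = [np.array([[0.0, 0.0, 0.0], [7.3, 0.0, 0.0]])]
        dist = rdf(coms, L=40, bin_width=1.0)
        hit = np.nonzero(dist.pair_counts)[0]
        assert list(hit) == [7]
        assert dist.pair_counts[7] == 1

    def test_pair_count_recovered_by_shell_integral(self):
        """sum over bins of g * ideal-shell expectation = contained pairs."""
        rng = np.random.default_rng(6)
        coms = [rng.uniform(0, 30, size=(60, 3)) for _ in range(20)]
        dist = rdf(coms, L=30, bin_width=0.5)
        shell = (4 * np.pi / 3) * (dist.edges[1:] ** 3 - dist.edges[:-1] ** 3)
        ideal = dist.n_configs * (60 * 59 / 2) * shell / 30**3
        assert (dist.g * ideal).sum() == pytest.approx(dist.pair_counts.sum())

    def test_bad_bin_width_raises(self):
        with pytest.raises(ValueError):
            rdf([np.zeros((3, 3))], L=30, bin_width=0.0)


class TestSqFromGr:
    def test_unit_g_gives_unit_s(self):
        from bfmdend.scattering import RadialDistribution

        edges = np.arange(0, 15.5, 0.5)
        dist = RadialDistribution(edges=edges, g=np.ones(len(edges) - 1),
                                  pair_counts=np.ones(len(edges) - 1),
                                  n_configs=1, n_t=10, L=30)
        S = sq_from_gr(dist, number_density=10 / 30**3,
                       q=np.linspace(0.2, 3.0, 20))
        np.testing.assert_allclose(S.value, 1.0, atol=1e-12)

    def test_roundtrip_against_direct_structure_factor(self):
        """S from the COM sum and S from transforming g(R) agree on the
        same ideal-gas ensemble (both ~1)."""
        rng = np.random.default_rng(7)
        configs = [rng.uniform(0, 40, size=(80, 3)) for _ in range(100)]
        grid = QGrid.build(40, qmax=1.0, max_per_shell=40, rng=rng)
        S_direct = structure_factor_com(configs, grid)
        dist = rdf(configs, L=40, bin_width=0.5)
        S_gr = sq_from_gr(dist, number_density=80 / 40**3, q=S_direct.q)
        mask = S_direct.q > 0.3
        np.testing.assert_allclose(S_gr.value[mask], S_direct.value[mask],
                                   atol=0.25)


class TestFactorization:
    def test_unit_structure_recovers_single_molecule_intensity(self):
        q = np.linspace(0.1, 1.0, 10)
        P = _profile(q, np.exp(-q**2))
        S = _profile(q, np.ones_like(q))
        I = factorized_intensity(P, S, phi=0.05, N=250)
        np.testing.assert_allclose(I.value, 0.05 * 250 * P.value)

    def test_apparent_structure_inverts_exactly(self):
        q = np.linspace(0.1, 1.0, 10)
        P = _profile(q, np.exp(-q**2))
        S = _profile(q, 1.0 + 0.5 * np.sin(q * 5))
        I = factorized_intensity(P, S, phi=0.1, N=58)
        S_app = apparent_structure_factor(I, P, phi=0.1, N=58)
        np.testing.assert_allclose(S_app.value, S.value, rtol=1e-12)

    def test_mismatched_bins_raise(self):
        with pytest.raises(ValueError):
            factorized_intensity(_profile([0.1, 0.2], [1, 1]),
                                 _profile([0.1, 0.3], [1, 1]), 0.1, 10)

    def test_low_p_bins_flagged_nan(self):
        q = np.array([0.1, 0.2])
        I = _profile(q, [1.0, 1.0])
        P = _profile(q, [0.5, 1e-12])
        S_app = apparent_structure_factor(I, P, phi=0.1, N=10)
        assert np.isfinite(S_app.value[0])
        assert np.isnan(S_app.value[1])
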