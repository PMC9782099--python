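"""Mayer-function sampling, effective potential and its quadratic fit."""

import numpy as np
import pytest

from bfmdend.fixtures import make_fixture
from bfmdend.potential import (
    EffectivePotential,
    MayerEstimate,
    effective_potential,
    evaluate_potential,
    fit_potential,
    sample_mayer,
)


def _mayer(r_centers, f):
    r_centers = np.asarray(r_centers, dtype=float)
    dr = r_centers[1] - r_centers[0]
    edges = np.concatenate([[r_centers[0] - dr / 2], r_centers + dr / 2])
    f = np.asarray(f, dtype=float)
    tries = np.full(len(f), 1000, dtype=np.int64)
    return MayerEstimate(r_edges=edges, f_M=f, tries=tries,
                         overlaps=(-f * 1000).astype(np.int64), min_tries=26,
                         low_stat_bins=np.zeros(len(f), dtype=bool))


def _single_unit_overlap_probability(R, n_grid=400):
    """Fraction of directions u with R*u inside the Chebyshev ball |x|_inf < 2
    (independent quadrature oracle over the sphere)."""
    theta = (np.arange(n_grid) + 0.5) * np.pi / n_grid
    phi = (np.arange(n_grid) + 0.5) * 2 * np.pi / n_grid
    T, P = np.meshgrid(theta, phi, indexing="ij")
    x = R * np.sin(T) * np.cos(P)
    y = R * np.sin(T) * np.sin(P)
    z = R * np.cos(T)
    inside = (np.abs(x) < 2) & (np.abs(y) < 2) & (np.abs(z) < 2)
    w = np.sin(T)
    return float((inside * w).sum() / w.sum())


class TestMayerSampling:
    def test_far_separation_never_overlaps(self):
        lib = [np.zeros((1, 3))]
        est = sample_mayer(lib, r_max=10.0, n_tries=2000, n_bins=10,
                           rng=np.random.default_rng(0), r_min=8.0)
        np.testing.assert_allclose(est.f_M, 0.0)

    def test_zero_separation_of_compact_molecules_always_overlaps(self):
        rng = np.random.default_rng(1)
        blob = rng.integers(-3, 4, size=(30, 3)).astype(float)
        est = sample_mayer([blob], r_max=0.5, n_tries=500, n_bins=1, rng=rng)
        assert est.f_M[0] == pytest.approx(-1.0)

    def test_single_unit_molecules_match_geometry_oracle(self):
        """f_M(R) for two point units is minus the sphere fraction inside
        the Chebyshev-2 cube; checked in three regimes."""
        lib = [np.zeros((1, 3))]
        rng = np.random.default_rng(2)
        centers = np.array([1.0, 2.5, 3.2])
        for R in centers:
            est = sample_mayer(lib, r_max=R + 0.005, r_min=R - 0.005,
                               n_tries=40_000, n_bins=1, rng=rng)
            p_oracle = _single_unit_overlap_probability(R)
            se = np.sqrt(max(p_oracle * (1 - p_oracle), 1e-4) / 40_000)
            assert -est.f_M[0] == pytest.approx(p_oracle, abs=4 * se + 1e-3)

    def test_error_halves_when_tries_quadruple(self):
        """Binomial standard error scales as tries^-1/2."""
        est1 = _mayer(np.linspace(1, 10, 10), np.full(10, -0.5))
        se1 = est1.stderr()
        est2 = MayerEstimate(
            r_edges=est1.r_edges, f_M=est1.f_M, tries=est1.tries * 4,
            overlaps=est1.overlaps * 4, min_tries=26,
            low_stat_bins=est1.low_stat_bins)
        np.testing.assert_allclose(est2.stderr(), se1 / 2)

    def test_low_statistics_bins_flagged(self):
        lib = [np.zeros((1, 3))]
        est = sample_mayer(lib, r_max=5.0, n_tries=50, n_bins=10,
                           rng=np.random.default_rng(3), min_tries=26)
        assert est.low_stat_bins.all()

    def test_bounds_respected(self):
        rng = np.random.default_rng(4)
        blob = rng.integers(-4, 5, size=(20, 3)).astype(float)
        est = sample_mayer([blob], r_max=25.0, n_tries=5000, n_bins=25, rng=rng)
        assert np.all(est.f_M <= 0.0)
        assert np.all(est.f_M >= -1.0)


class TestEffectivePotential:
    def test_closed_forms(self):
        est = _mayer([1, 2, 3], [0.0, -0.5, -1.0])
        pot = effective_potential(est)
        assert pot.w_eff[0] == 0.0
        assert pot.w_eff[1] == pytest.approx(np.log(2))
        assert np.isinf(pot.w_eff[2]) and pot.hardcore[2]

    def test_nonnegative(self):
        rng = np.random.default_rng(5)
        f = -rng.uniform(0, 1, 50)
        pot = effective_potential(_mayer(np.linspace(1, 20, 50), f))
        assert np.all(pot.w_eff[np.isfinite(pot.w_eff)] >= 0)


class TestFit:
    def test_recovers_known_coefficients(self):
        """Synthetic ln-w data from known (c0, c1, c2) + noise: estimates
        within 3 standard errors."""
        r, w, truth = make_fixture(
            "known_potential",
            {"c0": 1.2, "c1": -0.03, "c2": -1e-4, "log_noise": 0.03,
             "r": np.linspace(1, 10, 60)},
            seed=6,
        )
        pot = EffectivePotential(r_centers=r, w_eff=w,
                                 hardcore=np.zeros(len(r), dtype=bool))
        fit = fit_potential(pot)
        for est, se, true in zip(fit.coefficients, fit.stderr, truth):
            assert abs(est - true) <= 3 * se

    def test_gaussian_case_gives_null_quartic(self):
        r, w, _ = make_fixture(
            "known_potential",
            {"c0": 1.0, "c1": -0.02, "c2": 0.0, "log_noise": 0.01,
             "r": np.linspace(1, 12, 50)},
            seed=7,
        )
        pot = EffectivePotential(r_centers=r, w_eff=w,
                                 hardcore=np.zeros(len(r), dtype=bool))
        fit = fit_potential(pot)
        assert abs(fit.c2) <= 3 * fit.stderr[2]

    def test_too_few_bins_raise(self):
        pot = EffectivePotential(r_centers=np.array([1.0, 2.0]),
                                 w_eff=np.array([1.0, 0.5]),
                                 hardcore=np.zeros(2, dtype=bool))
        with pytest.raises(ValueError):
            fit_potential(pot)


class TestEvaluate:
    def _fit(self):
        r = np.linspace(1, 12, 50)
        w = np.exp(2.0 - 0.05 * r**2)
        pot = EffectivePotential(r_centers=r, w_eff=w,
                                 hardcore=np.zeros(50, dtype=bool))
        return fit_potential(pot)

    def test_origin_value_and_far_zero(self):
        fit = self._fit()
        assert evaluate_potential(fit, 0.0) == pytest.approx(np.exp(fit.c0))
        assert evaluate_potential(fit, 1e6) == 0.0

    def test_roundtrip_at_bin_centers(self):
        fit = self._fit()
        r = np.linspace(1, 12, 50)
        np.testing.assert_allclose(
            evaluate_potential(fit, r), np.exp(2.0 - 0.05 * r**2), rtol=1e-6
        )

    def test_monotone_decay_on_validity_range(self):
        fit = self._fit()
        r = np.linspace(0, fit.R_cut, 200)
        w = evaluate_potential(fit, r)
        assert np.all(np.diff(w) <= 1e-12)

    def test_json_roundtrip(self):
        from bfmdend.potential import PotentialFit

        fit = self._fit()
        again = PotentialFit.from_json(fit.to_json(note="test"))
        assert again.coefficients == pytest.approx(fit.coefficients)
        assert again.R_cut == pytest.approx(fit.R_cut)
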