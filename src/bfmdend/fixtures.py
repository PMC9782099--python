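"""Deterministic test-surface generators.

Small synthetic inputs used by the test suite and available from the
CLI: tiny dendrimer systems, ideal-gas point sets, samples from a known
quadratic log-potential, and a noisy peaked profile for smoothing checks.
"""

from __future__ import annotations

import numpy as np

from .builder import SystemState, build_system

__all__ = ["make_fixture"]


def _tiny_dendrimer(params: dict, rng: np.random.Generator) -> SystemState:
    G = int(params.get("G", 1))
    if G > 2:
        raise ValueError("tiny_dendrimer supports G <= 2")
    L = int(params.get("L", 32))
    n_t = params.get("n_t", 1)
    return build_system(
        G=G, L=L, target_phi=params.get("phi", 0.0), n_t=int(n_t), rng=rng
    )


def _ideal_gas(params: dict, rng: np.random.Generator) -> np.ndarray:
    n_t = int(params.get("n_t", 100))
    L = float(params.get("L", 50))
    n_configs = int(params.get("n_configs", 1))
    pts = rng.uniform(0.0, L, size=(n_configs, n_t, 3))
    return pts[0] if n_configs == 1 else pts


def _known_potential(params: dict, rng: np.random.Generator):
    """Noisy w_eff samples from w(R) = exp(c0 + c1 R² + c2 R⁴)."""
    c0 = float(params.get("c0", 1.0))
    c1 = float(params.get("c1", -0.02))
    c2 = float(params.get("c2", 0.0))
    r = np.asarray(params.get("r", np.linspace(1.0, 12.0, 40)), dtype=np.float64)
    noise = float(params.get("log_noise", 0.02))
    log_w = c0 + c1 * r**2 + c2 * r**4 + rng.normal(0.0, noise, size=r.shape)
    return r, np.exp(log_w), (c0, c1, c2)


def _noisy_peak(params: dict, rng: np.random.Generator):
    """Peaked signal + white noise on a uniform grid (x, noisy, clean)."""
    n = int(params.get("n", 101))
    x = np.linspace(0.0, 2.0, n)
    x0 = float(params.get("peak", 0.8))
    width = float(params.get("width", 0.15))
    clean = 1.0 + 2.0 * np.exp(-((x - x0) ** 2) / (2 * width**2))
    noisy = clean + rng.normal(0.0, float(params.get("noise", 0.15)), size=n)
    return x, noisy, clean


_KINDS = {
    "tiny_dendrimer": _tiny_dendrimer,
    "ideal_gas": _ideal_gas,
    "known_potential": _known_potential,
    "noisy_peak": _noisy_peak,
}


def make_fixture(kind: str, params: dict | None = None, seed: int = 0):
    """Build a named fixture; deterministic under a fixed seed."""
    if kind not in _KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {sorted(_KINDS)}")
    rng = np.random.default_rng(seed)
    return _KINDS[kind](params or {}, rng)
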