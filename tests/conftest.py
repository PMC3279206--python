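import numpy as np
import pytest

from mhsidetect import SimulationConfig, simulate_scene


def sparse_instances(seed, count=100, coherence_max=0.5, max_sparsity=2):
    """Seeded random sparse-recovery instances with unit-norm atoms.

    Yields (y, A, gamma_true) with B in 8..12, N in 12..16, true sparsity
    <= max_sparsity, mutual coherence below *coherence_max* so that exact
    support recovery is information-theoretically clean.
    """
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < count:
        b = int(rng.integers(8, 13))
        n = int(rng.integers(12, 17))
        a = rng.standard_normal((b, n))
        a /= np.linalg.norm(a, axis=0)
        gram = np.abs(a.T @ a)
        np.fill_diagonal(gram, 0.0)
        if gram.max() >= coherence_max:
            continue
        k = int(rng.integers(1, max_sparsity + 1))
        support = rng.choice(n, k, replace=False)
        gamma = np.zeros(n)
        gamma[support] = rng.uniform(0.5, 2.0, k) * rng.choice([-1.0, 1.0], k)
        out.append((a @ gamma, a, gamma))
    return out


@pytest.fixture(scope="session")
def small_scene():
    """A small noisy scene shared by read-only tests."""
    cfg = SimulationConfig(height=24, width=24, seed=5)
    return cfg, simulate_scene(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
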