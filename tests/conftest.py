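import numpy as np
import pytest

from deconfound.matrices import ExpressionMatrix
from deconfound.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Small default-noise two-group simulation shared across tests."""
    cfg = SimulationConfig(
        n_genes=600, n_diff=40, n_markers=10, n_samples_per_group=20, random_seed=101
    )
    return simulate_dataset(cfg)


def make_blocky_factorization(n_genes=200, n_samples=20, seed=1):
    """Noise-free identifiable X = S @ C with equal-mean block signatures.

    Each cell type expresses its own block of genes (the other block at a
    small shared floor), both blocks drawn from the same distribution so
    the column means of S agree; proportions span (0.2, 0.8).
    """
    rng = np.random.default_rng(seed)
    half = n_genes // 2
    v1 = rng.uniform(4.0, 12.0, half)
    v2 = rng.uniform(4.0, 12.0, n_genes - half)
    S = np.full((n_genes, 2), 0.5)
    S[:half, 0] = v1
    S[half:, 1] = v2
    c = np.linspace(0.2, 0.8, n_samples)
    C = np.vstack([c, 1.0 - c])
    X = ExpressionMatrix(
        S @ C,
        [f"g{i:04d}" for i in range(n_genes)],
        [f"s{j:02d}" for j in range(n_samples)],
    )
    return X, S, C
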