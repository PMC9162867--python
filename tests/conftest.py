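import numpy as np
import pytest

from leukoswarm import ExpressionDataset, SyntheticConfig, generate_dataset


@pytest.fixture
def tiny_dataset() -> ExpressionDataset:
    """Deterministic 6-gene x 12-sample dataset with 2 informative genes."""
    rng = np.random.default_rng(42)
    labels = np.array([0] * 7 + [1] * 5)
    matrix = rng.normal(size=(6, 12))
    matrix[0] += np.where(labels == 0, 1.5, -1.5)
    matrix[3] += np.where(labels == 0, -1.2, 1.2)
    return ExpressionDataset(
        matrix=matrix,
        gene_ids=[f"g{i}" for i in range(6)],
        sample_ids=[f"s{j}" for j in range(12)],
        labels=labels,
    )


@pytest.fixture
def planted_dataset():
    """Moderate synthetic dataset with known planted genes."""
    cfg = SyntheticConfig(
        p=150, n_informative=10, n_redundant_blocks=2, block_size=5,
        effect_size=3.0, seed=7,
    )
    return generate_dataset(cfg)


def random_dataset(p: int, n0: int, n1: int, seed: int) -> ExpressionDataset:
    """Pure-noise two-class dataset for oracle-equivalence checks."""
    rng = np.random.default_rng(seed)
    labels = np.array([0] * n0 + [1] * n1)
    return ExpressionDataset(
        matrix=rng.normal(size=(p, n0 + n1)),
        gene_ids=[f"g{i}" for i in range(p)],
        sample_ids=[f"s{j}" for j in range(n0 + n1)],
        labels=labels,
    )
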