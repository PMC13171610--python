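import numpy as np
import pytest

from hybridmda.containers import AssociationMatrix, DiseaseDAG, SimilarityMatrix
from hybridmda.synthetic import SynthConfig, simulate_associations, simulate_dag, simulate_sequences


@pytest.fixture
def small_A() -> AssociationMatrix:
    """Deterministic 6x5 association matrix with both dense and sparse rows."""
    rng = np.random.default_rng(42)
    values = (rng.random((6, 5)) < 0.4).astype(int)
    values[0] = [1, 1, 0, 0, 0]
    values[:, 0] |= np.array([1, 0, 0, 0, 0, 1])  # ensure no all-zero column
    for i in range(6):
        if values[i].sum() == 0:
            values[i, i % 5] = 1
    return AssociationMatrix(values, [f"m{i}" for i in range(6)], [f"d{j}" for j in range(5)])


@pytest.fixture
def chain_dag() -> DiseaseDAG:
    """R -> X -> d chain plus a sibling pair under R."""
    return DiseaseDAG(
        nodes=["R", "X", "d", "A", "B"],
        parent_edges=[("X", "R"), ("d", "X"), ("A", "R"), ("B", "R")],
        decay=0.5,
    )


@pytest.fixture(scope="session")
def synth_dataset():
    """Default-condition synthetic dataset shared across read-only tests."""
    cfg = SynthConfig(seed=7)
    return {
        "cfg": cfg,
        "A": simulate_associations(cfg),
        "sequences": simulate_sequences(cfg),
        "dag": simulate_dag(cfg),
    }


@pytest.fixture(scope="session")
def small_synth_dataset():
    """Smaller planted dataset for training-loop tests."""
    cfg = SynthConfig(m=60, n=20, n_blocks=3, seed=5)
    return {
        "cfg": cfg,
        "A": simulate_associations(cfg),
        "sequences": simulate_sequences(cfg),
        "dag": simulate_dag(cfg),
    }


def random_similarity(n: int, seed: int, ids=None) -> SimilarityMatrix:
    rng = np.random.default_rng(seed)
    M = rng.random((n, n))
    M = (M + M.T) / 2
    np.fill_diagonal(M, 1.0)
    return SimilarityMatrix(M, ids or [f"e{i}" for i in range(n)], "gipk")
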