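import numpy as np
import pytest

from ignite_grn import (
    ExpressionMatrix,
    GeneActivityMatrix,
    IsingModel,
    KineticIsing,
    generate_trajectory,
    sample_ground_truth,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_expression():
    """3 genes x 4 cells with pseudotime, for I/O and preprocessing tests."""
    values = np.array([
        [1.0, 4.0, 0.0, 2.0],
        [3.0, 1.0, 5.0, 0.0],
        [2.0, 2.0, 1.0, 6.0],
    ])
    return ExpressionMatrix(
        values,
        gene_ids=["gA", "gB", "gC"],
        cell_ids=["c1", "c2", "c3", "c4"],
        pseudotime=np.array([0.0, 1.0, 2.0, 3.0]),
    )


@pytest.fixture
def two_gene_model():
    return IsingModel(
        J=np.array([[0.0, 1.0], [-1.0, 0.0]]),
        h=np.zeros(2),
        gene_ids=["g1", "g2"],
    )


@pytest.fixture(scope="session")
def planted():
    """Session-wide ground truth: sparse 10-gene model, seeded."""
    rng = np.random.default_rng(2024)
    return sample_ground_truth(10, density=0.2, coupling_scale=1.0, rng=rng)


@pytest.fixture(scope="session")
def planted_trajectory(planted):
    """T=20000 trajectory simulated from the planted model."""
    rng = np.random.default_rng(777)
    return generate_trajectory(planted.model, 20000, rng)


def recovery_scores(J_true: np.ndarray, J_fit: np.ndarray):
    """(Pearson over off-diagonal entries, sign accuracy on the strongest
    quintile of true couplings)."""
    J_fit = J_fit.copy()
    np.fill_diagonal(J_fit, 0.0)
    off = ~np.eye(J_true.shape[0], dtype=bool)
    pearson = np.corrcoef(J_true[off], J_fit[off])[0, 1]
    nz = np.abs(J_true[off]) > 0
    cutoff = np.quantile(np.abs(J_true[off][nz]), 0.8)
    strong = (np.abs(J_true) >= cutoff) & off & (J_true != 0)
    sign_acc = np.mean(np.sign(J_fit[strong]) == np.sign(J_true[strong]))
    return float(pearson), float(sign_acc)
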