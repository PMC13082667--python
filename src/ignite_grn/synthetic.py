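"""Ground-truth models and study-like synthetic datasets.

Every pipeline stage is testable without a download: a known sparse Ising
model (optionally with a within-group-activating / between-group-repressing
block structure, mimicking the antagonism between sequential pluripotency
states) simulates a spin trajectory, which is mapped to non-negative
pseudo-expression with multiplicative lognormal noise and dropout-style
zero inflation.  Pseudotime is the simulation step index, so the latent
ordering is known exactly.

Fixture conventions (documented, not claims about real data): active mean
10, inactive mean 1, lognormal noise sigma = 0.3 — chosen so the half-max
binarization is recoverable but not trivial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import (
    ExpressionMatrix,
    IsingModel,
    KnownInteractionSet,
    ValidationError,
)
from .ising import generate_trajectory

ACTIVE_MEAN = 10.0
INACTIVE_MEAN = 1.0
NOISE_SIGMA = 0.3


@dataclass
class GroundTruth:
    """A planted model plus the edge list every inference run is scored on."""

    model: IsingModel
    module_labels: np.ndarray
    planted_edges: KnownInteractionSet


def sample_ground_truth(
    n_genes: int,
    density: float,
    coupling_scale: float,
    rng: np.random.Generator,
    block_structure: list[int] | None = None,
    field_scale: float = 0.1,
) -> GroundTruth:
    """Sparse random coupling matrix with known signed edges.

    Off-diagonal couplings are present independently with probability
    ``density`` and drawn with magnitude ~ |N(0, coupling_scale)|.  Without
    blocks, signs are random.  With ``block_structure`` (group sizes summing
    to n_genes), within-block couplings are positive and between-block
    couplings negative — the mutual-antagonism motif of sequential cell
    states.  Fields are small, h ~ N(0, field_scale).
    """
    if n_genes < 2:
        raise ValidationError("need at least 2 genes")
    if not 0 < density <= 1:
        raise ValidationError("density must lie in (0, 1]")
    if density * n_genes * n_genes < 1:
        raise ValidationError("density too low: expected edge count below 1")
    if block_structure is not None:
        if sum(block_structure) != n_genes:
            raise ValidationError("block sizes must sum to n_genes")
        labels = np.concatenate([
            np.full(size, f"block{b}", dtype=object)
            for b, size in enumerate(block_structure)
        ])
    else:
        labels = np.full(n_genes, "all", dtype=object)

    present = rng.random((n_genes, n_genes)) < density
    np.fill_diagonal(present, False)
    magnitude = np.abs(rng.normal(0.0, coupling_scale, (n_genes, n_genes)))
    if block_structure is not None:
        same_block = labels[:, None] == labels[None, :]
        signs = np.where(same_block, 1.0, -1.0)
    else:
        signs = np.where(rng.random((n_genes, n_genes)) < 0.5, 1.0, -1.0)
    J = np.where(present, signs * magnitude, 0.0)
    h = rng.normal(0.0, field_scale, n_genes)
    gene_ids = np.asarray([f"g{k}" for k in range(n_genes)], dtype=object)
    model = IsingModel(J, h, gene_ids)

    edges = [
        (str(gene_ids[j]), str(gene_ids[i]), 1 if J[i, j] > 0 else -1)
        for i, j in zip(*np.nonzero(J))
    ]
    return GroundTruth(model, labels, KnownInteractionSet(edges, gene_universe=gene_ids))


def make_study(
    truth: GroundTruth,
    n_cells: int,
    dropout_rate: float,
    rng: np.random.Generator,
    noise_sigma: float = NOISE_SIGMA,
) -> tuple[ExpressionMatrix, np.ndarray]:
    """Simulate a trajectory and dress it up as a noisy expression matrix.

    Spins map to means (active -> 10, inactive -> 1), multiplied by
    lognormal noise exp(N(0, sigma)), then zeroed independently with
    probability ``dropout_rate``.  Pseudotime is the simulation step index.
    Returns (expression matrix with pseudotime attached, true spin matrix).
    """
    if not 0 <= dropout_rate < 1:
        raise ValidationError("dropout_rate must lie in [0, 1)")
    traj = generate_trajectory(truth.model, n_cells, rng)
    spins = traj.spins
    means = np.where(spins == 1, ACTIVE_MEAN, INACTIVE_MEAN)
    if noise_sigma > 0:
        values = means * np.exp(rng.normal(0.0, noise_sigma, means.shape))
    else:
        values = means.astype(float)
    if dropout_rate > 0:
        values = np.where(rng.random(values.shape) < dropout_rate, 0.0, values)
    cell_ids = np.asarray([f"c{k:06d}" for k in range(n_cells)], dtype=object)
    expr = ExpressionMatrix(
        values, truth.model.gene_ids.copy(), cell_ids,
        pseudotime=np.arange(n_cells, dtype=float),
    )
    return expr, spins
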