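"""Maximum-entropy (partial-correlation) baseline network.

The maximum-entropy distribution constrained to match the data's first and
second moments is Gaussian, and its interaction structure is carried by
the precision matrix: rho_ij = -(C^-1)_ij / sqrt((C^-1)_ii (C^-1)_jj) is
the partial correlation of genes i and j given all others.  The resulting
network is symmetric and unsigned in direction: it cannot say who
regulates whom, only that a conditional dependence exists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import ExpressionMatrix, GeneActivityMatrix, ValidationError


@dataclass
class UndirectedGRN:
    """Symmetric partial-correlation matrix with gene labels.

    Diagonal entries equal -1 under the defining formula; they carry no
    interpretation and are kept only so the matrix round-trips intact.
    """

    rho: np.ndarray
    gene_ids: np.ndarray

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, float)
        if not np.allclose(self.rho, self.rho.T):
            raise ValidationError("rho must be symmetric")


def maxent_grn(data) -> UndirectedGRN:
    """Partial-correlation network from an expression or activity matrix.

    The gene-gene covariance over cells (unbiased, n-1 denominator) is
    inverted exactly; a numerically singular covariance raises rather than
    being silently regularised.
    """
    if isinstance(data, (ExpressionMatrix, GeneActivityMatrix)):
        X = np.asarray(data.values if isinstance(data, ExpressionMatrix) else data.spins,
                       dtype=float)
        gene_ids = data.gene_ids
    else:
        X = np.asarray(data, dtype=float)
        gene_ids = np.asarray([f"g{k}" for k in range(X.shape[0])], dtype=object)
    n_genes, n_cells = X.shape
    if n_cells <= n_genes:
        raise ValidationError(
            f"covariance of {n_genes} genes from {n_cells} cells is singular; "
            "filter genes or add cells"
        )
    C = np.cov(X)
    try:
        P = np.linalg.inv(C)
    except np.linalg.LinAlgError as exc:
        raise ValidationError(
            "singular covariance matrix: filter degenerate genes or regularise "
            "explicitly upstream"
        ) from exc
    cond = np.linalg.cond(C)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValidationError(
            f"covariance matrix is numerically singular (cond={cond:.2e}); "
            "filter degenerate genes or regularise explicitly upstream"
        )
    d = np.sqrt(np.diag(P))
    rho = -P / np.outer(d, d)
    rho = (rho + rho.T) / 2  # enforce exact symmetry against round-off
    return UndirectedGRN(rho, np.asarray(gene_ids, dtype=object))
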