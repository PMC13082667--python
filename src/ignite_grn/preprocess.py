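"""Expression -> time-ordered binary gene activity.

The pipeline order is fixed: log-normalize, sort cells by pseudotime,
moving-average into mini-bulks, then binarize each gene at half its maximum
over the mini-bulk trajectory.  Mini-bulk averaging is the dropout
mitigation: averaging pseudotime-adjacent cells fills in stochastic zeros
before the half-max threshold is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np

from .containers import ExpressionMatrix, GeneActivityMatrix, ValidationError


def lognormalize(raw: ExpressionMatrix, depth_normalize: bool = True) -> ExpressionMatrix:
    """Depth-normalize each cell and apply log2(x + 1).

    Each entry becomes ``log2(x_ic / total_c + 1)`` where ``total_c`` is the
    column (cell) sum, so every value is non-negative and a cell's values no
    longer depend on its sequencing depth.  With ``depth_normalize=False``
    only the log2(x + 1) variance stabilisation is applied — appropriate for
    input already in normalized units, where dividing by the sum over a
    small gene panel would introduce compositional artifacts.
    """
    if depth_normalize:
        totals = raw.values.sum(axis=0)
        if (totals <= 0).any():
            bad = raw.cell_ids[totals <= 0]
            raise ValidationError(
                f"cells with zero total count (QC belongs upstream): {list(bad[:5])}"
            )
        values = np.log2(raw.values / totals + 1.0)
    else:
        values = np.log2(raw.values + 1.0)
    return replace(raw, values=values)


def minibulk(ordered: ExpressionMatrix, window: int, step: int = 1) -> ExpressionMatrix:
    """Moving average over pseudotime-adjacent cells ("mini-bulk").

    Output column k is the per-gene mean of input columns
    [k*step, k*step + window); the output has floor((N - window)/step) + 1
    columns.  Output pseudotime is the mean pseudotime of each window.
    """
    if step <= 0:
        raise ValidationError("step must be positive")
    n = ordered.n_cells
    if window <= 0 or window > n:
        raise ValidationError(f"window must be in [1, {n}], got {window}")
    if ordered.pseudotime is not None and np.any(np.diff(ordered.pseudotime) < 0):
        raise ValidationError("cells must be sorted by pseudotime before mini-bulk")

    n_out = (n - window) // step + 1
    # cumulative-sum sliding means: exact to ~1 ulp and O(genes * cells)
    csum = np.concatenate(
        [np.zeros((ordered.n_genes, 1)), np.cumsum(ordered.values, axis=1)], axis=1
    )
    starts = np.arange(n_out) * step
    values = (csum[:, starts + window] - csum[:, starts]) / window

    pst = None
    if ordered.pseudotime is not None:
        pcs = np.concatenate([[0.0], np.cumsum(ordered.pseudotime)])
        pst = (pcs[starts + window] - pcs[starts]) / window
    cell_ids = np.asarray([f"mb{k}" for k in range(n_out)], dtype=object)
    return ExpressionMatrix(values, ordered.gene_ids.copy(), cell_ids, pst)


def binarize(mb: ExpressionMatrix) -> GeneActivityMatrix:
    """Half-max binarization into +/-1 spins.

    Gene i is active (+1) at column t iff ``x_i(t) >= max_t x_i(t) / 2``;
    the threshold is per-gene over all columns of this (mini-bulk) matrix.
    An all-zero row satisfies 0 >= 0 everywhere and binarizes to all +1;
    such genes should have been filtered upstream, so we warn.
    """
    maxima = mb.values.max(axis=1, keepdims=True)
    degenerate = (maxima == 0).ravel()
    if degenerate.any():
        warnings.warn(
            "all-zero gene rows binarize to all +1 under the half-max rule; "
            f"consider filtering: {list(mb.gene_ids[degenerate][:5])}",
            stacklevel=2,
        )
    spins = np.where(mb.values >= maxima / 2.0, 1, -1).astype(np.int8)
    return GeneActivityMatrix(spins, mb.gene_ids.copy(), mb.cell_ids.copy(), mb.pseudotime)


def run_preprocess(
    raw: ExpressionMatrix,
    window: int = 150,
    step: int = 1,
    genes: list[str] | None = None,
    lognorm: bool | str = True,
) -> tuple[ExpressionMatrix, GeneActivityMatrix]:
    """Full preprocessing chain; returns (mini-bulk matrix, gene activity).

    ``lognorm`` is True (depth-normalize + log2(x+1), for raw counts),
    "log1p" (log2(x+1) only, for pre-normalized units) or False (input is
    already log-scale).
    """
    x = raw
    if genes is not None:
        x = x.subset_genes(genes)
    if lognorm == "log1p":
        x = lognormalize(x, depth_normalize=False)
    elif lognorm:
        x = lognormalize(x)
    if x.pseudotime is not None:
        x = x.sort_by_pseudotime()
    mb = minibulk(x, window=window, step=step)
    return mb, binarize(mb)
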