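"""Core in-memory containers shared by every pipeline stage.

Orientation is fixed everywhere: genes in rows, cells in columns.  The
coupling matrix follows the column-regulator -> row-target convention:
``J[i, j]`` is the influence of gene ``j`` on gene ``i``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


class FormatError(ValueError):
    """Raised when an external file does not match its declared format."""


def _as_labels(labels: Sequence[str], n: int, what: str) -> np.ndarray:
    arr = np.asarray(labels, dtype=object)
    if arr.ndim != 1 or arr.size != n:
        raise ValidationError(f"{what}: expected {n} labels, got shape {arr.shape}")
    if len(set(arr)) != arr.size:
        raise ValidationError(f"{what}: duplicate labels present")
    return arr


@dataclass
class ExpressionMatrix:
    """Genes x cells non-negative expression values with labels.

    Parameters
    ----------
    values : ndarray, shape (n_genes, n_cells)
        Raw counts or normalized expression; must be non-negative.
    gene_ids, cell_ids : sequences of unique strings
    pseudotime : optional ndarray, shape (n_cells,)
        Per-cell scalar ordering along the differentiation trajectory.
    """

    values: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    pseudotime: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        n_genes, n_cells = self.values.shape
        self.gene_ids = _as_labels(self.gene_ids, n_genes, "gene_ids")
        self.cell_ids = _as_labels(self.cell_ids, n_cells, "cell_ids")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must be finite")
        if (self.values < 0).any():
            raise ValidationError("expression values must be non-negative")
        if self.pseudotime is not None:
            pst = np.asarray(self.pseudotime, dtype=float)
            if pst.shape != (n_cells,):
                raise ValidationError(
                    f"pseudotime length {pst.shape} does not match {n_cells} cells"
                )
            if np.isnan(pst).any():
                missing = self.cell_ids[np.isnan(pst)]
                raise ValidationError(f"pseudotime missing for cells: {list(missing[:5])}")
            self.pseudotime = pst

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, pseudotime: pd.Series | None = None
    ) -> "ExpressionMatrix":
        pst = None
        if pseudotime is not None:
            pst = pseudotime.reindex(df.columns).to_numpy(dtype=float)
            if np.isnan(pst).any():
                missing = df.columns[np.isnan(pst)]
                raise ValidationError(f"pseudotime missing for cells: {list(missing[:5])}")
        return cls(df.to_numpy(dtype=float), df.index.to_numpy(object),
                   df.columns.to_numpy(object), pst)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Restrict to the given genes, preserving the requested order."""
        index = {g: k for k, g in enumerate(self.gene_ids)}
        try:
            rows = [index[g] for g in genes]
        except KeyError as exc:
            raise ValidationError(f"gene not in matrix: {exc.args[0]}") from exc
        return replace(self, values=self.values[rows],
                       gene_ids=np.asarray(list(genes), dtype=object))

    def sort_by_pseudotime(self) -> "ExpressionMatrix":
        """Order cells by pseudotime, ties broken by cell id (lexicographic)."""
        if self.pseudotime is None:
            raise ValidationError("cannot sort: no pseudotime attached")
        order = np.lexsort((self.cell_ids.astype(str), self.pseudotime))
        return replace(
            self,
            values=self.values[:, order],
            cell_ids=self.cell_ids[order],
            pseudotime=self.pseudotime[order],
        )


@dataclass
class GeneActivityMatrix:
    """Genes x cells spin matrix: +1 active, -1 inactive, columns time-ordered."""

    spins: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    pseudotime: np.ndarray | None = None

    def __post_init__(self) -> None:
        spins = np.asarray(self.spins)
        if spins.ndim != 2:
            raise ValidationError("spins must be a 2-D matrix")
        if not np.isin(spins, (-1, 1)).all():
            raise ValidationError("spin entries must be exactly -1 or +1")
        self.spins = spins.astype(np.int8)
        n_genes, n_cells = spins.shape
        self.gene_ids = _as_labels(self.gene_ids, n_genes, "gene_ids")
        self.cell_ids = _as_labels(self.cell_ids, n_cells, "cell_ids")
        if self.pseudotime is not None:
            pst = np.asarray(self.pseudotime, dtype=float)
            if pst.shape != (n_cells,):
                raise ValidationError("pseudotime length mismatch")
            if np.any(np.diff(pst) < 0):
                raise ValidationError("pseudotime must be non-decreasing left to right")
            self.pseudotime = pst

    @property
    def n_genes(self) -> int:
        return self.spins.shape[0]

    @property
    def n_cells(self) -> int:
        return self.spins.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.spins, index=self.gene_ids, columns=self.cell_ids)


@dataclass
class IsingModel:
    """Asymmetric kinetic Ising model: coupling matrix J and fields h.

    ``J[i, j]`` is the signed influence of gene j on gene i, in units of
    temperature.  The update rate gamma and the time step delta_t are fixed
    at 1, so per-step flip probabilities stay in [0, 1].
    """

    J: np.ndarray
    h: np.ndarray
    gene_ids: np.ndarray
    gamma: float = 1.0
    delta_t: float = 1.0

    def __post_init__(self) -> None:
        self.J = np.asarray(self.J, dtype=float)
        self.h = np.asarray(self.h, dtype=float)
        if self.J.ndim != 2 or self.J.shape[0] != self.J.shape[1]:
            raise ValidationError("J must be square")
        n = self.J.shape[0]
        if self.h.shape != (n,):
            raise ValidationError("h length must match J")
        if not (np.all(np.isfinite(self.J)) and np.all(np.isfinite(self.h))):
            raise ValidationError("model parameters must be finite")
        if not 0 < self.gamma * self.delta_t <= 1:
            raise ValidationError("gamma * delta_t must lie in (0, 1]")
        self.gene_ids = _as_labels(self.gene_ids, n, "gene_ids")

    @property
    def n_genes(self) -> int:
        return self.J.shape[0]

    def without_diagonal(self) -> "IsingModel":
        """Copy with self-couplings removed (the reported-GRN convention)."""
        J = self.J.copy()
        np.fill_diagonal(J, 0.0)
        return replace(self, J=J, h=self.h.copy())

    def gene_index(self, gene: str) -> int:
        hits = np.nonzero(self.gene_ids == gene)[0]
        if hits.size == 0:
            raise ValidationError(f"gene not in model: {gene!r}")
        return int(hits[0])


@dataclass
class KnownInteractionSet:
    """Curated signed regulator -> target edges used for FCI scoring."""

    edges: list[tuple[str, str, int]]
    directed: bool = True
    gene_universe: Sequence[str] | None = None

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        clean: list[tuple[str, str, int]] = []
        for reg, tgt, sign in self.edges:
            if int(sign) not in (-1, 1):
                raise ValidationError(f"edge sign must be +/-1, got {sign!r}")
            if (reg, tgt) in seen:
                raise ValidationError(f"duplicate edge ({reg}, {tgt})")
            seen.add((reg, tgt))
            clean.append((reg, tgt, int(sign)))
        self.edges = clean
        if self.gene_universe is not None:
            universe = set(self.gene_universe)
            for reg, tgt, _ in self.edges:
                if reg not in universe or tgt not in universe:
                    raise ValidationError(f"edge gene outside universe: ({reg}, {tgt})")

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self):
        return iter(self.edges)
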