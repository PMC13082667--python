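"""Reading and writing external formats, run configuration and RNG streams.

Supported formats are deliberately plain-text: TSV/CSV gene x cell matrices
(genes in rows), MatrixMarket MTX triplets with companion gene/cell label
files, TSV pseudotime tables (cell_id, pst) and TSV edge lists.  The edge
list convention is column-regulator -> row-target and is stated in the file
header so a transposed import fails loudly rather than silently.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import (
    ExpressionMatrix,
    FormatError,
    IsingModel,
    KnownInteractionSet,
    ValidationError,
)

EDGE_LIST_HEADER = "# orientation: regulator (column index of J) -> target (row index of J)"

#: Hyperparameter value lists for the random search (the published grid).
DEFAULT_GRID: dict[str, list] = {
    "optimizer": ["MGA", "NADAM"],
    "eta0": [0.3, 0.4, 0.5, 0.6, 0.7, 0.8],
    "dr": [0.65, 0.70, 0.75, 0.80, 0.85, 0.90, 0.95, 0.99],
    "n_dr": [15, 20, 25, 30, 35],
    "xi_m": [0.75, 0.8, 0.85, 0.90, 0.95, 0.99],
    "lam": [0.01, 0.02, 0.03, 0.04, 0.05, 0.07, 0.09],
    "n_epochs": [500, 700, 800, 900, 1200],
}

#: Subset of the published grid used for desk-scale searches and tests.
SMALL_GRID: dict[str, list] = {
    "optimizer": ["MGA", "NADAM"],
    "eta0": [0.3, 0.5, 0.7],
    "dr": [0.75, 0.90],
    "n_dr": [20, 30],
    "xi_m": [0.8, 0.9],
    "lam": [0.01, 0.02, 0.05],
    "n_epochs": [500],
}


@dataclass
class RunConfig:
    """Run-level configuration: seeds, trial counts and the search grid."""

    seed: int = 0
    n_trials: int = 250
    n_shuffle: int = 250
    grid: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_GRID.items()})
    selection_mode: str = "cmd"
    burn_in: int = 0
    include_diagonal: bool = True
    cmd_replicates: int = 250
    n_test: int = 50  # shuffled datasets in the null ensemble
    n_sets: int = 50  # hyperparameter sets per shuffled dataset

    def __post_init__(self) -> None:
        if self.n_trials < 1 or self.n_shuffle < 1:
            raise ValidationError("n_trials and n_shuffle must be positive")
        if self.selection_mode not in ("cmd", "fci"):
            raise ValidationError("selection_mode must be 'cmd' or 'fci'")
        for key, values in self.grid.items():
            if not values:
                raise ValidationError(f"grid list for {key!r} is empty")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def manifest(self) -> dict:
        return {"seed": self.seed, "config": asdict(self), "config_hash": self.config_hash()}


def substream(seed: int, name: str) -> np.random.Generator:
    """Named RNG substream derived from the master seed.

    Streams are keyed by (seed, stable hash of name) so that, e.g., changing
    the number of search trials leaves the generation streams untouched.
    """
    digest = hashlib.sha256(name.encode()).digest()
    key = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), key]))


def _read_labels(path: Path) -> np.ndarray:
    labels = [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
    return np.asarray(labels, dtype=object)


def _read_pseudotime(path: Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise FormatError(f"pseudotime table {path} needs (cell_id, pst) columns")
    return pd.Series(df.iloc[:, 1].to_numpy(float), index=df.iloc[:, 0].astype(str))


def read_expression(
    path: str | Path,
    format: str | None = None,
    pseudotime_path: str | Path | None = None,
    gene_path: str | Path | None = None,
    cell_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read a genes x cells expression matrix from TSV, CSV or MTX.

    For MTX, companion one-label-per-line files give gene (row) and cell
    (column) ids; they default to ``<stem>.genes.txt`` / ``<stem>.cells.txt``
    next to the matrix.  A pseudotime table is joined by cell id.
    """
    path = Path(path)
    if format is None:
        format = {".tsv": "tsv", ".csv": "csv", ".mtx": "mtx"}.get(path.suffix.lower())
        if format is None:
            raise FormatError(f"cannot infer format from {path.suffix!r}")
    if format in ("tsv", "csv"):
        df = pd.read_csv(path, sep="\t" if format == "tsv" else ",", index_col=0,
                         float_precision="round_trip")
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        values = df.to_numpy(dtype=float)
        gene_ids = df.index.to_numpy(object)
        cell_ids = df.columns.to_numpy(object)
    elif format == "mtx":
        gene_path = Path(gene_path) if gene_path else path.with_suffix("").with_suffix(".genes.txt")
        cell_path = Path(cell_path) if cell_path else path.with_suffix("").with_suffix(".cells.txt")
        if not gene_path.exists() or not cell_path.exists():
            raise FormatError(f"missing label files for {path}: {gene_path}, {cell_path}")
        mat = scipy.io.mmread(path)
        values = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
        gene_ids = _read_labels(gene_path)
        cell_ids = _read_labels(cell_path)
        if values.shape != (gene_ids.size, cell_ids.size):
            raise FormatError(
                f"MTX dims {values.shape} do not match labels "
                f"({gene_ids.size} genes, {cell_ids.size} cells)"
            )
    else:
        raise FormatError(f"unsupported format {format!r}")

    pst = None
    if pseudotime_path is not None:
        table = _read_pseudotime(Path(pseudotime_path))
        pst = table.reindex(pd.Index(cell_ids.astype(str))).to_numpy(float)
        if np.isnan(pst).any():
            missing = cell_ids[np.isnan(pst)]
            raise ValidationError(f"pseudotime missing for cells: {list(missing[:5])}")
    return ExpressionMatrix(values, gene_ids, cell_ids, pst)


def write_expression(matrix: ExpressionMatrix, path: str | Path,
                     pseudotime_path: str | Path | None = None) -> None:
    """Write a matrix as TSV (genes in rows); optionally its pseudotime table."""
    matrix.to_dataframe().to_csv(path, sep="\t", float_format="%.17g")
    if pseudotime_path is not None:
        if matrix.pseudotime is None:
            raise ValidationError("matrix has no pseudotime to write")
        pd.DataFrame({"cell_id": matrix.cell_ids, "pst": matrix.pseudotime}).to_csv(
            pseudotime_path, sep="\t", index=False
        )


def write_grn(model: IsingModel, path: str | Path, format: str = "matrix_tsv") -> None:
    """Write an inferred model either as a labelled matrix or an edge list.

    ``matrix_tsv``: full J with gene labels on both axes plus a dedicated
    ``__h__`` column holding the fields.  ``edge_list_tsv``: one row per
    nonzero coupling, (regulator, target, weight), using the
    column-regulator -> row-target orientation.
    """
    path = Path(path)
    if format == "matrix_tsv":
        df = pd.DataFrame(model.J, index=model.gene_ids, columns=model.gene_ids)
        df["__h__"] = model.h
        df.to_csv(path, sep="\t", float_format="%.17g")  # bitwise round-trip
    elif format == "edge_list_tsv":
        rows = []
        targets, regulators = np.nonzero(model.J)
        for i, j in zip(targets, regulators):
            rows.append((model.gene_ids[j], model.gene_ids[i], model.J[i, j]))
        with open(path, "w") as fh:
            fh.write(EDGE_LIST_HEADER + "\n")
            fh.write("regulator\ttarget\tweight\n")
            for reg, tgt, w in rows:
                fh.write(f"{reg}\t{tgt}\t{float(w)!r}\n")
    else:
        raise FormatError(f"unsupported GRN format {format!r}")


def read_grn(path: str | Path) -> IsingModel:
    """Read a model written by :func:`write_grn` in ``matrix_tsv`` format."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if "__h__" not in df.columns:
        raise FormatError(f"{path} lacks the '__h__' field column")
    h = df["__h__"].to_numpy(float)
    J = df.drop(columns="__h__").to_numpy(float)
    genes = df.index.astype(str).to_numpy(object)
    if J.shape[0] != J.shape[1] or not (df.drop(columns="__h__").columns.astype(str) == genes).all():
        raise FormatError(f"{path}: row and column gene labels disagree")
    return IsingModel(J, h, genes)


def read_edge_list(path: str | Path, directed: bool = True,
                   gene_universe: Sequence[str] | None = None) -> KnownInteractionSet:
    """Read a curated (regulator, target, sign) edge list from TSV."""
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = [c.lower() for c in df.columns]
    if not {"regulator", "target"}.issubset(cols):
        raise FormatError(f"{path} needs 'regulator' and 'target' columns")
    df.columns = cols
    sign_col = "sign" if "sign" in cols else "weight"
    edges = [
        (str(r), str(t), 1 if float(s) > 0 else -1)
        for r, t, s in zip(df["regulator"], df["target"], df[sign_col])
    ]
    return KnownInteractionSet(edges, directed=directed, gene_universe=gene_universe)


def write_activity(activity, path: str | Path) -> None:
    """Write a gene-activity (spin) matrix as TSV."""
    activity.to_dataframe().to_csv(path, sep="\t")


def save_manifest(config: RunConfig, path: str | Path, extra: Mapping | None = None) -> None:
    manifest = config.manifest()
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
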