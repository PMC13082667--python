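"""Candidate GRN scoring and selection.

Two scores rank candidate networks:

* CMD (correlation-matrices distance): Frobenius distance, scaled by gene
  count, between the Pearson correlation matrix of the input activity data
  and the element-wise average correlation matrix of model-generated
  replicates — normalised by the mean distance to shuffled-data nulls, so
  CMD = 1 means "no better than chance" and CMD = 0 means a perfect match.
* FCI (fraction of correctly inferred interactions): the fraction of
  curated signed edges whose inferred coupling carries the matching sign.

The permutation machinery (row+column index shuffles) provides both the CMD
denominator and the null ensemble for per-edge significance testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from . import ising
from .containers import (
    GeneActivityMatrix,
    IsingModel,
    KnownInteractionSet,
    ValidationError,
)
from .inference import Hyperparameters, KineticIsing, sample_hyperparameters
from .io_config import RunConfig, substream


def _spins_array(x) -> np.ndarray:
    if isinstance(x, GeneActivityMatrix):
        return np.asarray(x.spins, dtype=float)
    return np.asarray(x, dtype=float)


def correlation_matrix(data) -> np.ndarray:
    """Pearson correlation over columns (cells); constant genes -> 0.

    A gene with zero variance (e.g. pinned by a knockout) has undefined
    correlations; its row and column are set to 0 with a warning instead of
    raising, so distances over reduced gene sets remain computable.
    """
    X = _spins_array(data)
    n = X.shape[1]
    sd = X.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant gene(s): correlations set to 0",
            stacklevel=2,
        )
    Xc = X - X.mean(axis=1, keepdims=True)
    sd_safe = np.where(constant, 1.0, sd)
    corr = (Xc @ Xc.T) / n / np.outer(sd_safe, sd_safe)
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    return corr


def corr_distance(corrA: np.ndarray, corrB: np.ndarray, sqrt: bool = True) -> float:
    """Scaled Frobenius distance between two correlation matrices.

    d = (1/N_genes) * sqrt( sum_ij (A_ij - B_ij)^2 ).  ``sqrt=False``
    preserves the alternate no-root reading for sensitivity checks.
    """
    A = np.asarray(corrA, float)
    B = np.asarray(corrB, float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValidationError(f"correlation matrix shapes differ: {A.shape} vs {B.shape}")
    ss = float(((A - B) ** 2).sum())
    return (np.sqrt(ss) if sqrt else ss) / A.shape[0]


def shuffle_dataset(matrix, rng: np.random.Generator, mode: str = "index"):
    """Null-model shuffle of a genes x cells matrix.

    ``index`` (the default): one random permutation of the row indices and
    one of the column indices — relabels genes and destroys the temporal
    order of cells.  ``values``: independently permutes the entries within
    each row (kept as an alternative reading of the same procedure).
    """
    X = np.asarray(matrix.spins if isinstance(matrix, GeneActivityMatrix) else matrix)
    if mode == "index":
        return X[rng.permutation(X.shape[0])][:, rng.permutation(X.shape[1])]
    if mode == "values":
        out = X.copy()
        for i in range(out.shape[0]):
            out[i] = out[i][rng.permutation(X.shape[1])]
        return out
    raise ValidationError(f"unknown shuffle mode {mode!r}")


@dataclass
class CMDReport:
    """CMD value plus the distance distributions behind it."""

    value: float
    numerator: float
    denominator: float
    replicate_distances: np.ndarray   # d(input corr, each replicate corr)
    null_distances: np.ndarray        # d(input corr, each shuffled-input corr)

    def ttest_vs_null(self):
        """Two-sample t-test of replicate distances against null distances."""
        return sstats.ttest_ind(self.replicate_distances, self.null_distances)


def cmd_from_replicates(
    input_spins,
    replicates: np.ndarray,
    n_shuffle: int,
    rng: np.random.Generator,
    shuffle_mode: str = "index",
) -> CMDReport:
    """CMD of pre-generated replicate datasets against the input data.

    ``replicates`` has shape (n_replicates, n_genes, n_cells).  The score
    uses the element-wise average of the replicate correlation matrices;
    the per-replicate distances are kept for the significance t-test.
    """
    X_in = _spins_array(input_spins)
    corr_in = correlation_matrix(X_in)
    rep_corrs = np.stack([correlation_matrix(rep) for rep in replicates])
    numerator = corr_distance(corr_in, rep_corrs.mean(axis=0))
    rep_d = np.array([corr_distance(corr_in, c) for c in rep_corrs])
    null_d = np.array([
        corr_distance(corr_in, correlation_matrix(shuffle_dataset(X_in, rng, shuffle_mode)))
        for _ in range(n_shuffle)
    ])
    denominator = float(null_d.mean())
    if denominator == 0:
        raise ValidationError("degenerate null: all shuffled distances are zero")
    return CMDReport(
        value=numerator / denominator,
        numerator=numerator,
        denominator=denominator,
        replicate_distances=rep_d,
        null_distances=null_d,
    )


def cmd(
    input_spins,
    model: IsingModel,
    n_replicates: int,
    n_shuffle: int,
    rng: np.random.Generator,
    burn_in: int = 0,
    include_diagonal: bool = True,
) -> CMDReport:
    """Correlation-matrices distance of a model against the input data.

    Generates ``n_replicates`` datasets of the input's dimensions from the
    model, averages their Pearson correlation matrices, and scales the
    distance to the input correlation matrix by the mean distance between
    the input and ``n_shuffle`` shuffled copies of itself.
    """
    if n_replicates < 1 or n_shuffle < 1:
        raise ValidationError("n_replicates and n_shuffle must be >= 1")
    X_in = _spins_array(input_spins)
    reps = ising.simulate_ensemble(
        model, X_in.shape[1], n_replicates, rng, burn_in, include_diagonal
    )
    return cmd_from_replicates(X_in, reps, n_shuffle, rng)


def fci(model: IsingModel, known: KnownInteractionSet, directed: bool = True) -> float:
    """Fraction of curated edges whose inferred coupling has the right sign.

    The inferred entry for edge regulator -> target is J[target, regulator].
    In undirected mode (the MaxEnt convention) an edge counts if either
    orientation carries the curated sign.  A zero entry never counts.
    """
    if len(known) == 0:
        raise ValidationError("known interaction set is empty")
    hits = 0
    for reg, tgt, sign in known:
        i = model.gene_index(tgt)
        j = model.gene_index(reg)
        if directed:
            ok = np.sign(model.J[i, j]) == sign
        else:
            ok = np.sign(model.J[i, j]) == sign or np.sign(model.J[j, i]) == sign
        hits += bool(ok)
    return hits / len(known)


@dataclass
class CandidateGRN:
    """One random-search trial: fitted model plus its scores."""

    model: IsingModel | None
    hyperparameters: Hyperparameters
    cmd: float | None
    fci: float | None
    trial_index: int
    success: bool = True
    results: object = None          # the underlying KineticIsingResults
    cmd_report: CMDReport | None = None


def random_search(
    activity,
    config: RunConfig,
    known: KnownInteractionSet | None = None,
    seed: int | None = None,
    compute_cmd: bool = True,
) -> list[CandidateGRN]:
    """Random hyperparameter search over the configured grid.

    Draws ``config.n_trials`` hyperparameter sets uniformly with
    replacement, fits each from a zero initialisation, and attaches CMD
    (and FCI when curated edges are supplied) to every successful fit.
    Diverged fits are recorded with ``success=False`` and excluded from
    selection; if every fit diverges this raises.
    """
    seed = config.seed if seed is None else seed
    hp_rng = substream(seed, "search-hyperparams")
    ki = KineticIsing(activity)
    candidates: list[CandidateGRN] = []
    for k in range(config.n_trials):
        hp = sample_hyperparameters(config.grid, hp_rng)
        res = ki.fit(hyperparameters=hp)
        if not res.success:
            candidates.append(CandidateGRN(None, hp, None, None, k, success=False, results=res))
            continue
        model = res.to_ising_model()
        report = None
        cmd_value = None
        if compute_cmd:
            trial_rng = substream(seed, f"search-trial-{k}")
            report = cmd(activity, model, config.cmd_replicates, config.n_shuffle,
                         trial_rng, burn_in=config.burn_in,
                         include_diagonal=config.include_diagonal)
            cmd_value = report.value
        fci_value = fci(model, known) if known is not None else None
        candidates.append(CandidateGRN(model, hp, cmd_value, fci_value, k,
                                       results=res, cmd_report=report))
    if not any(c.success for c in candidates):
        raise RuntimeError("random search: every fit diverged")
    return candidates


def select_best(
    candidates: list[CandidateGRN],
    mode: str = "cmd",
    rng: np.random.Generator | None = None,
) -> CandidateGRN:
    """Pick the candidate with minimum CMD (or maximum FCI).

    Exact ties are broken by a seeded uniform draw among the tied
    candidates, so selection is reproducible given the rng.
    """
    ok = [c for c in candidates if c.success]
    if not ok:
        raise ValidationError("no successful candidates to select from")
    if mode == "cmd":
        scores = np.array([c.cmd for c in ok], dtype=float)
        best = scores.min()
    elif mode == "fci":
        scores = np.array([c.fci for c in ok], dtype=float)
        best = scores.max()
    else:
        raise ValidationError("mode must be 'cmd' or 'fci'")
    tied = [c for c, s in zip(ok, scores) if s == best]
    if len(tied) == 1:
        return tied[0]
    rng = np.random.default_rng(0) if rng is None else rng
    return tied[rng.integers(len(tied))]


@dataclass
class NullEnsemble:
    """Models fitted on shuffled data: the per-edge null distribution."""

    null_models: list[IsingModel]
    n_test: int
    n_sets: int
    n_failed: int = 0
    shuffle_seeds: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.null_models)


def fit_null_ensemble(
    activity,
    config: RunConfig,
    seed: int | None = None,
    fitter=None,
    shuffle_mode: str = "index",
) -> NullEnsemble:
    """Fit models on shuffled data: n_test shuffles x n_sets hyperparameter
    sets.

    ``fitter(spins, hp) -> IsingModel or None`` may replace the full
    likelihood fit (e.g. for bookkeeping checks); by default each shuffled
    dataset is fitted exactly like the real one.
    """
    seed = config.seed if seed is None else seed
    gene_ids = (activity.gene_ids if isinstance(activity, GeneActivityMatrix)
                else [f"g{k}" for k in range(np.asarray(activity).shape[0])])

    def default_fitter(spins, hp):
        res = KineticIsing(spins, gene_ids=gene_ids).fit(hyperparameters=hp)
        return res.to_ising_model() if res.success else None

    fitter = fitter or default_fitter
    models: list[IsingModel] = []
    n_failed = 0
    for s in range(config.n_test):
        sh_rng = substream(seed, f"shuffle-{s}")
        shuffled = shuffle_dataset(activity, sh_rng, shuffle_mode)
        hp_rng = substream(seed, f"null-hyperparams-{s}")
        for j in range(config.n_sets):
            hp = sample_hyperparameters(config.grid, hp_rng)
            model = fitter(shuffled, hp)
            if model is None:
                n_failed += 1
            else:
                models.append(model)
    return NullEnsemble(models, config.n_test, config.n_sets, n_failed)


def interaction_permutation_test(
    observed: IsingModel,
    nulls: NullEnsemble,
    edges: KnownInteractionSet,
    lower_pct: float = 5.0,
    upper_pct: float = 95.0,
) -> pd.DataFrame:
    """Flag curated edges whose observed coupling escapes the null band.

    For each edge the corresponding J entry is collected across all null
    models; the edge is significant iff the observed value lies strictly
    outside the [lower_pct, upper_pct] percentile interval.
    """
    if len(nulls) == 0:
        raise ValidationError("null ensemble is empty")
    if len(nulls) < 20:
        warnings.warn("fewer than 20 null models: percentiles are unstable", stacklevel=2)
    rows = []
    for reg, tgt, sign in edges:
        i = observed.gene_index(tgt)
        j = observed.gene_index(reg)
        null_vals = np.array([m.J[m.gene_index(tgt), m.gene_index(reg)]
                              for m in nulls.null_models])
        lo, hi = np.percentile(null_vals, [lower_pct, upper_pct])
        val = observed.J[i, j]
        rows.append({
            "regulator": reg, "target": tgt, "curated_sign": sign,
            "observed": val, "null_p_lo": lo, "null_p_hi": hi,
            "significant": bool(val < lo or val > hi),
        })
    return pd.DataFrame(rows)
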