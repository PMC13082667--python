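"""In-silico knockouts and agreement scores against experimental responses.

A knockout removes the perturbed genes' rows and columns from the inferred
coupling matrix (and their fields); the reduced model then generates
replicate gene-activity datasets exactly like the wild type.  Per-gene
responses are the difference of mean activity between knockout and
wild-type ensembles, scaled to [-1, 1] by the family-wise maximum so that
simulated responses are comparable with experimental log2 fold changes
scaled the same way (but never by a shared maximum across the two
families).  Agreement is summarised by the fraction of agreement (FoA)
over {positive, negative, null} categories at a threshold, a binomial null
for FoA significance, and Spearman rank correlation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sstats

from .containers import GeneActivityMatrix, IsingModel, ValidationError


@dataclass
class KnockoutSpec:
    """Non-empty set of genes to remove; must leave at least one gene."""

    ko_genes: tuple[str, ...]

    def __post_init__(self) -> None:
        genes = tuple(dict.fromkeys(self.ko_genes))
        if not genes:
            raise ValidationError("knockout set is empty")
        self.ko_genes = genes


def knockout_model(model: IsingModel, spec: KnockoutSpec | Iterable[str]) -> IsingModel:
    """Restrict the model to the genes that survive the knockout.

    J keeps only retained rows and columns, h only retained genes; every
    retained coupling is bit-for-bit the original.
    """
    if not isinstance(spec, KnockoutSpec):
        spec = KnockoutSpec(tuple(spec))
    ko_idx = [model.gene_index(g) for g in spec.ko_genes]
    keep = np.setdiff1d(np.arange(model.n_genes), ko_idx)
    if keep.size == 0:
        raise ValidationError("cannot knock out every gene")
    return IsingModel(
        model.J[np.ix_(keep, keep)].copy(),
        model.h[keep].copy(),
        model.gene_ids[keep].copy(),
        gamma=model.gamma,
        delta_t=model.delta_t,
    )


def _ensemble_means(sets, gene_ids=None) -> tuple[np.ndarray, np.ndarray]:
    """Mean spin per gene across all cells and replicates."""
    if isinstance(sets, GeneActivityMatrix):
        return sets.spins.mean(axis=1), sets.gene_ids
    arr = np.asarray(sets, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValidationError("expected (replicates, genes, cells) spin data")
    means = arr.mean(axis=(0, 2))
    if gene_ids is None:
        gene_ids = np.asarray([f"g{k}" for k in range(means.size)], dtype=object)
    return means, np.asarray(gene_ids, dtype=object)


def ko_wt_difference(wt_sets, ko_sets, wt_gene_ids=None, ko_gene_ids=None) -> np.ndarray:
    """Per-gene mean-activity change, knockout minus wild type.

    Both ensembles must already be restricted to the retained gene set (the
    wild-type side drops the perturbed genes before averaging).  For spin
    data each entry lies in [-2, +2].
    """
    wt_mean, wt_genes = _ensemble_means(wt_sets, wt_gene_ids)
    ko_mean, ko_genes = _ensemble_means(ko_sets, ko_gene_ids)
    if wt_mean.shape != ko_mean.shape or not np.array_equal(wt_genes, ko_genes):
        raise ValidationError("WT and KO ensembles must share the retained gene set")
    return ko_mean - wt_mean


def scale_differences(deltas_by_ko: Mapping[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Divide every response by the global max |delta| across all knockouts.

    One family-wise maximum puts every condition on a common [-1, 1] scale;
    experimental log2FC families are scaled by their own maximum, never
    mixed with the simulated one.
    """
    if not deltas_by_ko:
        raise ValidationError("need at least one knockout condition")
    global_max = max(float(np.max(np.abs(np.asarray(d, float))))
                     for d in deltas_by_ko.values())
    if global_max == 0:
        warnings.warn("all deltas are zero: scaled values are all zero", stacklevel=2)
        return {k: np.zeros_like(np.asarray(d, float)) for k, d in deltas_by_ko.items()}
    return {k: np.asarray(d, float) / global_max for k, d in deltas_by_ko.items()}


def _categorize(values: np.ndarray, thr: float) -> np.ndarray:
    """-1 / 0 / +1 category per value: negative <= -thr < null < +thr <= positive."""
    v = np.asarray(values, float)
    return np.where(v >= thr, 1, np.where(v <= -thr, -1, 0))


def foa(sim_scaled: np.ndarray, exp_scaled: np.ndarray, thr: float = 0.05) -> float:
    """Fraction of genes whose simulated and experimental responses agree.

    Each scaled response is categorised positive (>= thr), negative
    (<= -thr) or null (strictly inside); FoA is the fraction of matching
    categories over the retained genes.
    """
    sim = np.asarray(sim_scaled, float)
    exp = np.asarray(exp_scaled, float)
    if sim.shape != exp.shape:
        raise ValidationError("simulated and experimental vectors differ in length")
    return float(np.mean(_categorize(sim, thr) == _categorize(exp, thr)))


def foa_significance_threshold(n_genes: int, p: float = 1 / 3,
                               alpha: float = 0.05) -> tuple[float, bool]:
    """Smallest FoA exceeding chance under a Binomial(n, p) null.

    Returns (k*/n, attainable) with k* the least k whose exact upper tail
    P(X >= k) is <= alpha, computed by direct pmf enumeration.  When even
    k = n fails the tail bound the threshold is unattainable and (1.0,
    False) is returned.
    """
    if n_genes < 1:
        raise ValidationError("n_genes must be >= 1")
    pmf = np.array([math.comb(n_genes, k) * p ** k * (1 - p) ** (n_genes - k)
                    for k in range(n_genes + 1)])
    tails = np.minimum(np.cumsum(pmf[::-1])[::-1], 1.0)   # tails[k] = P(X >= k)
    qualifying = np.nonzero(tails <= alpha)[0]
    if qualifying.size == 0:
        return 1.0, False
    return float(qualifying[0] / n_genes), True


def rank_correlation(sim_scaled: np.ndarray, exp_scaled: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties), two-sided p.

    Returns (nan, nan) when either vector is constant, where the rank
    correlation is undefined.
    """
    sim = np.asarray(sim_scaled, float)
    exp = np.asarray(exp_scaled, float)
    if sim.size != exp.size:
        raise ValidationError("vectors differ in length")
    if sim.size < 3:
        raise ValidationError("need at least 3 paired values")
    if np.all(sim == sim[0]) or np.all(exp == exp[0]):
        warnings.warn("constant vector: Spearman correlation undefined", stacklevel=2)
        return float("nan"), float("nan")
    rho, p = sstats.spearmanr(sim, exp)
    return float(rho), float(p)


def differentiation_score(f_marker_ko: float, f_ref_ko: float,
                          f_marker_wt: float, f_ref_wt: float) -> float:
    """Late-vs-early marker ratio in KO, normalised by the same ratio in WT.

    DS = (f_marker_ko / f_ref_ko) / (f_marker_wt / f_ref_wt); DS > 1 means
    the knockout accelerated differentiation, DS < 1 delayed it.
    """
    for name, f in (("f_ref_ko", f_ref_ko), ("f_marker_wt", f_marker_wt),
                    ("f_ref_wt", f_ref_wt)):
        if f <= 0:
            raise ValidationError(f"{name} must be positive (score undefined)")
    if not all(0 <= f <= 1 for f in (f_marker_ko, f_ref_ko, f_marker_wt, f_ref_wt)):
        raise ValidationError("fractions must lie in [0, 1]")
    return (f_marker_ko / f_ref_ko) / (f_marker_wt / f_ref_wt)


def cluster_fractions(replicate_labels: Sequence[Sequence],
                      labels: Sequence | None = None) -> dict:
    """Mean +/- SEM of per-cluster cell fractions across replicates.

    ``replicate_labels`` is one sequence of per-cell cluster labels per
    replicate (use the label "excluded" for cells outside every cluster).
    ``labels`` fixes the reported cluster order; by default all observed
    labels, sorted.
    """
    reps = [np.asarray(r, dtype=object) for r in replicate_labels]
    if not reps:
        raise ValidationError("need at least one replicate")
    for k, r in enumerate(reps):
        if r.size == 0:
            raise ValidationError(f"replicate {k} is empty")
    if labels is None:
        labels = sorted({str(x) for r in reps for x in r})
    out = {}
    for lab in labels:
        fracs = np.array([np.mean(r.astype(str) == str(lab)) for r in reps])
        sem = fracs.std(ddof=1) / np.sqrt(len(reps)) if len(reps) > 1 else 0.0
        out[str(lab)] = {"mean": float(fracs.mean()), "sem": float(sem)}
    return out


@dataclass
class PerturbationReport:
    """Per-gene scaled KO-WT responses and their agreement summaries."""

    ko_name: str
    gene_ids: np.ndarray
    delta: np.ndarray
    delta_scaled: np.ndarray
    foa: float | None = None
    foa_threshold: float | None = None
    foa_threshold_attainable: bool | None = None
    spearman_rho: float | None = None
    spearman_p: float | None = None

    @property
    def n_comparable(self) -> int:
        return int(self.delta.size)


def evaluate_knockouts(
    deltas_by_ko: Mapping[str, np.ndarray],
    gene_ids_by_ko: Mapping[str, Sequence[str]],
    exp_scaled_by_ko: Mapping[str, np.ndarray] | None = None,
    thr: float = 0.05,
    alpha: float = 0.05,
) -> dict[str, PerturbationReport]:
    """Scale simulated responses family-wise and score each knockout.

    Experimental vectors must already be scaled by their own family
    maximum; they are compared, never rescaled here.
    """
    scaled = scale_differences(deltas_by_ko)
    reports = {}
    for name, delta in deltas_by_ko.items():
        report = PerturbationReport(
            ko_name=name,
            gene_ids=np.asarray(list(gene_ids_by_ko[name]), dtype=object),
            delta=np.asarray(delta, float),
            delta_scaled=scaled[name],
        )
        if exp_scaled_by_ko is not None and name in exp_scaled_by_ko:
            exp = np.asarray(exp_scaled_by_ko[name], float)
            report.foa = foa(scaled[name], exp, thr)
            t, ok = foa_significance_threshold(report.n_comparable, alpha=alpha)
            report.foa_threshold = t
            report.foa_threshold_attainable = ok
            rho, p = rank_correlation(scaled[name], exp)
            report.spearman_rho = rho
            report.spearman_p = p
        reports[name] = report
    return reports
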