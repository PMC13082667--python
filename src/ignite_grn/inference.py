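"""Inverse kinetic Ising problem: likelihood-gradient estimation of (J, h).

The estimator maximises the log-likelihood of a binary time series under
Glauber dynamics.  With gamma = delta_t = 1 the gradient has the moment-
matching form

    dL/dJ_ij = <s_i(t+1) s_j(t)>  -  <tanh(theta_i(t)) s_j(t)>
    dL/dh_i  = <s_i(t)            -   tanh(theta_i(t))>

with theta_i(t) = h_i + sum_j J_ij s_j(t) (self-couplings included during
inference; they stabilise the fit and are dropped only from the exported
GRN).  Both time averages run over the T-1 states that possess a successor.
Two first-order optimisers are provided: momentum gradient ascent (MGA)
with a step-decaying learning rate and an L1 sign penalty, and NADAM
(Nesterov-accelerated Adam) with the same schedule and penalty.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import GeneActivityMatrix, IsingModel, ValidationError

NADAM_BETA1 = 0.9
NADAM_BETA2 = 0.999
NADAM_EPS = 1e-8


@dataclass
class CorrelationStats:
    """Equal-time and one-step-lagged spin correlations of a trajectory."""

    C0: np.ndarray          # <s_i(t) s_j(t)>, averaged over all T columns
    D: np.ndarray           # <s_i(t+1) s_j(t)>, averaged over the T-1 pairs
    mean_next: np.ndarray   # <s_i(t+1)> over the pair window
    T_pairs: int


def compute_correlations(spins: GeneActivityMatrix | np.ndarray) -> CorrelationStats:
    """Equal-time C0 and one-step-lagged D correlation matrices.

    D is the discrete stand-in for C(0) + dC/dt / gamma: with unit rate and
    unit step the lagged moment <s_i(t+dt) s_j(t)> is exactly what the
    likelihood gradient needs.
    """
    S = np.asarray(spins.spins if isinstance(spins, GeneActivityMatrix) else spins, dtype=float)
    if S.ndim != 2 or S.shape[1] < 2:
        raise ValidationError("need a 2-D spin matrix with at least 2 columns")
    T = S.shape[1]
    C0 = (S @ S.T) / T
    D = (S[:, 1:] @ S[:, :-1].T) / (T - 1)
    return CorrelationStats(C0=C0, D=D, mean_next=S[:, 1:].mean(axis=1), T_pairs=T - 1)


def lr_schedule(eta0: float, dr: float, n_dr: int, epoch: int) -> float:
    """Step-decaying learning rate: eta_n = eta0 * dr ** floor(n / n_dr)."""
    if n_dr <= 0:
        raise ValidationError("n_dr must be positive")
    return eta0 * dr ** (epoch // n_dr)


@dataclass
class Hyperparameters:
    """One point of the random-search grid."""

    optimizer: str = "NADAM"
    eta0: float = 0.5
    dr: float = 0.9
    n_dr: int = 20
    xi_m: float | None = 0.9   # momentum; MGA only
    lam: float = 0.01
    n_epochs: int = 500
    penalty: str = "sign"      # 'sign' (L1 subgradient) or 'l2'

    def __post_init__(self) -> None:
        self.optimizer = self.optimizer.upper()
        if self.optimizer not in ("MGA", "NADAM"):
            raise ValidationError(f"unknown optimizer {self.optimizer!r}")
        if self.xi_m is not None and not 0 <= self.xi_m <= 1:
            raise ValidationError("momentum xi_m must lie in [0, 1]")
        if self.penalty not in ("sign", "l2"):
            raise ValidationError("penalty must be 'sign' or 'l2'")
        if self.n_epochs < 1:
            raise ValidationError("n_epochs must be >= 1")


def sample_hyperparameters(grid: Mapping[str, list], rng: np.random.Generator) -> Hyperparameters:
    """Draw one hyperparameter set uniformly (with replacement) from the grid."""
    def pick(key):
        values = grid[key]
        return values[rng.integers(len(values))]

    optimizer = pick("optimizer")
    return Hyperparameters(
        optimizer=optimizer,
        eta0=float(pick("eta0")),
        dr=float(pick("dr")),
        n_dr=int(pick("n_dr")),
        xi_m=float(pick("xi_m")) if optimizer.upper() == "MGA" else None,
        lam=float(pick("lam")),
        n_epochs=int(pick("n_epochs")),
    )


class KineticIsing:
    """Kinetic Ising model of a binary, time-ordered gene-activity matrix.

    Parameters
    ----------
    activity : GeneActivityMatrix or ndarray of +/-1
        Genes x cells spin matrix whose columns are consecutive time steps
        (pseudotime-ordered mini-bulk columns are treated as steps of
        delta_t = 1).
    gene_ids : optional sequence of labels when a bare array is given.

    Examples
    --------
    >>> model = KineticIsing(activity)
    >>> res = model.fit(optimizer="NADAM", eta0=0.5, n_epochs=500)
    >>> res.J.shape, res.h.shape
    """

    def __init__(self, activity, gene_ids=None):
        if isinstance(activity, GeneActivityMatrix):
            self.activity = activity
        else:
            arr = np.asarray(activity)
            n, t = arr.shape
            if gene_ids is None:
                gene_ids = [f"g{k}" for k in range(n)]
            cells = [f"t{k}" for k in range(t)]
            self.activity = GeneActivityMatrix(arr, gene_ids, cells)
        if self.activity.n_cells < 2:
            raise ValidationError("need at least two time points to fit dynamics")
        self._S = self.activity.spins.astype(float)
        self.gene_ids = self.activity.gene_ids
        self.stats = compute_correlations(self._S)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "KineticIsing":
        """Build from a genes x cells DataFrame of +/-1 values (columns in
        time order)."""
        return cls(df.to_numpy(), gene_ids=df.index.to_numpy(object))

    @property
    def n_genes(self) -> int:
        return self.activity.n_genes

    def gradient(self, J: np.ndarray, h: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Likelihood gradient (dL/dJ, dL/dh) at the given parameters."""
        Sp = self._S[:, :-1]
        Tp = self.stats.T_pairs
        theta = J @ Sp + h[:, None]
        tt = np.tanh(theta)
        gradJ = self.stats.D - (tt @ Sp.T) / Tp
        gradH = (Sp - tt).mean(axis=1)
        return gradJ, gradH

    def fit(self, optimizer: str = "NADAM", *, eta0: float = 0.5, dr: float = 0.9,
            n_dr: int = 20, xi_m: float | None = 0.9, lam: float = 0.01,
            n_epochs: int = 500, penalty: str = "sign",
            hyperparameters: Hyperparameters | None = None,
            start_J: np.ndarray | None = None,
            start_h: np.ndarray | None = None) -> "KineticIsingResults":
        """Maximise the likelihood from a zero initialisation.

        Returns a :class:`KineticIsingResults`; a fit that produces
        non-finite parameters is returned with ``success=False`` (candidate
        searches exclude it rather than aborting).
        """
        hp = hyperparameters or Hyperparameters(
            optimizer=optimizer, eta0=eta0, dr=dr, n_dr=n_dr,
            xi_m=xi_m, lam=lam, n_epochs=n_epochs, penalty=penalty,
        )
        n = self.n_genes
        J = np.zeros((n, n)) if start_J is None else np.array(start_J, dtype=float)
        h = np.zeros(n) if start_h is None else np.array(start_h, dtype=float)

        if hp.penalty == "sign":
            pen = np.sign
        else:
            pen = lambda x: x  # literal-L2 alternative

        gnormJ = np.full(hp.n_epochs, np.nan)
        gnormH = np.full(hp.n_epochs, np.nan)
        success = True

        if hp.optimizer == "MGA":
            xi = 0.0 if hp.xi_m is None else hp.xi_m
            vJ = np.zeros_like(J)
            vh = np.zeros_like(h)
            for epoch in range(hp.n_epochs):
                gJ, gh = self.gradient(J, h)
                gnormJ[epoch] = np.linalg.norm(gJ)
                gnormH[epoch] = np.linalg.norm(gh)
                eta = lr_schedule(hp.eta0, hp.dr, hp.n_dr, epoch)
                vJ = xi * vJ + eta * (gJ - hp.lam * pen(J))
                vh = xi * vh + eta * (gh - hp.lam * pen(h))
                J = J + vJ
                h = h + vh
                if not (np.all(np.isfinite(J)) and np.all(np.isfinite(h))):
                    success = False
                    break
        else:  # NADAM
            b1, b2, eps = NADAM_BETA1, NADAM_BETA2, NADAM_EPS
            mJ = np.zeros_like(J); vJ = np.zeros_like(J)
            mh = np.zeros_like(h); vh = np.zeros_like(h)
            for epoch in range(hp.n_epochs):
                gJ, gh = self.gradient(J, h)
                gnormJ[epoch] = np.linalg.norm(gJ)
                gnormH[epoch] = np.linalg.norm(gh)
                eta = lr_schedule(hp.eta0, hp.dr, hp.n_dr, epoch)
                t = epoch + 1
                mJ = b1 * mJ + (1 - b1) * gJ
                vJ = b2 * vJ + (1 - b2) * gJ ** 2
                mh = b1 * mh + (1 - b1) * gh
                vh = b2 * vh + (1 - b2) * gh ** 2
                mJ_hat = mJ / (1 - b1 ** t)
                vJ_hat = vJ / (1 - b2 ** t)
                mh_hat = mh / (1 - b1 ** t)
                vh_hat = vh / (1 - b2 ** t)
                # Nesterov look-ahead numerator, minus the penalty term
                numJ = b1 * mJ_hat + (1 - b1) * gJ / (1 - b1 ** t) - hp.lam * pen(J)
                numH = b1 * mh_hat + (1 - b1) * gh / (1 - b1 ** t) - hp.lam * pen(h)
                J = J + eta * numJ / (np.sqrt(vJ_hat) + eps)
                h = h + eta * numH / (np.sqrt(vh_hat) + eps)
                if not (np.all(np.isfinite(J)) and np.all(np.isfinite(h))):
                    success = False
                    break

        return KineticIsingResults(self, J, h, hp,
                                   trace={"grad_norm_J": gnormJ, "grad_norm_h": gnormH},
                                   success=success)


def fit_mga(spins, hp: Hyperparameters, rng=None) -> "KineticIsingResults":
    """Momentum-gradient-ascent fit (functional wrapper around KineticIsing)."""
    if hp.optimizer != "MGA":
        raise ValidationError("fit_mga requires hp.optimizer == 'MGA'")
    return KineticIsing(spins).fit(hyperparameters=hp)


def fit_nadam(spins, hp: Hyperparameters, rng=None) -> "KineticIsingResults":
    """NADAM fit (functional wrapper around KineticIsing)."""
    if hp.optimizer != "NADAM":
        raise ValidationError("fit_nadam requires hp.optimizer == 'NADAM'")
    return KineticIsing(spins).fit(hyperparameters=hp)


class KineticIsingResults:
    """Fitted coupling matrix and fields, with diagnostics.

    Attributes
    ----------
    J, h : fitted parameters (J includes self-couplings).
    hyperparameters : the optimiser settings used.
    trace : per-epoch gradient norms for J and h.
    success : False when the fit diverged to non-finite values.
    """

    def __init__(self, model: KineticIsing, J, h, hyperparameters, trace, success=True):
        self.model = model
        self.J = np.asarray(J, dtype=float)
        self.h = np.asarray(h, dtype=float)
        self.hyperparameters = hyperparameters
        self.trace = trace
        self.success = bool(success)
        self.gene_ids = model.gene_ids

    def to_ising_model(self, drop_diagonal: bool = False) -> IsingModel:
        """Export as a simulation-ready model; ``drop_diagonal=True`` gives
        the reported-GRN convention (no self-couplings)."""
        if not self.success:
            raise ValidationError("cannot export a diverged fit")
        m = IsingModel(self.J.copy(), self.h.copy(), self.gene_ids.copy())
        return m.without_diagonal() if drop_diagonal else m

    def simulate(self, n_columns: int, rng: np.random.Generator,
                 n_replicates: int = 1, burn_in: int = 0,
                 include_diagonal: bool = True) -> np.ndarray:
        """Generate gene-activity data from the fitted model.

        Returns int8 spins of shape (n_replicates, n_genes, n_columns).
        """
        from . import ising

        return ising.simulate_ensemble(self.to_ising_model(), n_columns,
                                       n_replicates, rng, burn_in, include_diagonal)

    def knockout(self, ko_genes) -> IsingModel:
        """Model restricted to the non-knocked-out genes."""
        from . import perturbation

        return perturbation.knockout_model(self.to_ising_model(), ko_genes)

    def gradient_norms(self) -> tuple[np.ndarray, np.ndarray]:
        return self.trace["grad_norm_J"], self.trace["grad_norm_h"]

    def summary(self) -> str:
        """Plain-text summary table in the spirit of statsmodels results."""
        hp = self.hyperparameters
        J_off = self.J - np.diag(np.diag(self.J))
        lines = [
            "Kinetic Ising inverse-problem fit",
            "=" * 46,
            f"genes:            {self.model.n_genes}",
            f"time points:      {self.model.activity.n_cells}",
            f"optimizer:        {hp.optimizer}",
            f"eta0/dr/n_dr:     {hp.eta0}/{hp.dr}/{hp.n_dr}",
            f"lambda (penalty): {hp.lam} ({hp.penalty})",
            f"epochs:           {hp.n_epochs}",
            f"converged:        {self.success}",
            f"final |grad J|:   {self.trace['grad_norm_J'][~np.isnan(self.trace['grad_norm_J'])][-1]:.3e}",
            f"final |grad h|:   {self.trace['grad_norm_h'][~np.isnan(self.trace['grad_norm_h'])][-1]:.3e}",
            f"|J| off-diag mean: {np.abs(J_off).mean():.4f}   max: {np.abs(J_off).max():.4f}",
            f"h range:          [{self.h.min():.4f}, {self.h.max():.4f}]",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (f"<KineticIsingResults genes={self.model.n_genes} "
                f"optimizer={self.hyperparameters.optimizer} success={self.success}>")
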