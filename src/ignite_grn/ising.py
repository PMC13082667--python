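"""Forward kinetic Ising model: local fields, Glauber updates, trajectories.

With gamma * delta_t = 1 the per-spin Glauber rule simplifies: the next
state of spin i is +1 with probability (1 + tanh(theta_i)) / 2 regardless of
its current value, where theta_i = h_i + sum_j J_ij s_j is the local field
computed from the *previous* full state.  All spins are resampled
independently each recorded step.
"""

from __future__ import annotations

import numpy as np

from .containers import GeneActivityMatrix, IsingModel, ValidationError


def effective_field(
    model: IsingModel, state: np.ndarray, include_diagonal: bool = True
) -> np.ndarray:
    """Local field theta_i = h_i + sum_j J_ij s_j for one state or a batch.

    ``state`` may be shape (n,) or (n, r) for r states in parallel.  With
    ``include_diagonal=False`` the self-coupling term J_ii s_i is removed,
    which shifts theta_i by exactly -J_ii * s_i.
    """
    s = np.asarray(state, dtype=float)
    if s.shape[0] != model.n_genes:
        raise ValidationError(
            f"state has {s.shape[0]} spins, model has {model.n_genes} genes"
        )
    theta = model.J @ s
    if not include_diagonal:
        theta = theta - np.diag(model.J)[:, None] * s if s.ndim == 2 else theta - np.diag(model.J) * s
    return theta + (model.h[:, None] if s.ndim == 2 else model.h)


def flip_probability(state_value: np.ndarray | float, theta: np.ndarray | float,
                     gamma_dt: float = 1.0) -> np.ndarray | float:
    """Probability that a spin flips: p = gamma*dt/2 * (1 - s*tanh(theta))."""
    return gamma_dt * 0.5 * (1.0 - np.asarray(state_value) * np.tanh(theta))


def glauber_step(
    model: IsingModel,
    state: np.ndarray,
    rng: np.random.Generator,
    include_diagonal: bool = True,
) -> np.ndarray:
    """One parallel Glauber update: every theta from the incoming state,
    then each spin independently resampled to +1 w.p. (1 + tanh(theta))/2."""
    theta = effective_field(model, state, include_diagonal)
    p_up = 0.5 * (1.0 + np.tanh(theta))
    draws = rng.random(size=theta.shape)
    return np.where(draws < p_up, 1, -1).astype(np.int8)


def random_state(n_genes: int, rng: np.random.Generator, n_replicates: int | None = None) -> np.ndarray:
    """Uniform random +/-1 initial state(s)."""
    shape = (n_genes,) if n_replicates is None else (n_genes, n_replicates)
    return np.where(rng.random(shape) < 0.5, 1, -1).astype(np.int8)


def simulate_ensemble(
    model: IsingModel,
    n_columns: int,
    n_replicates: int,
    rng: np.random.Generator,
    burn_in: int = 0,
    include_diagonal: bool = True,
) -> np.ndarray:
    """Simulate ``n_replicates`` independent trajectories in lockstep.

    Returns an int8 array of shape (n_replicates, n_genes, n_columns).
    Each replicate starts from its own uniform random state; after
    ``burn_in`` unrecorded steps, ``n_columns`` consecutive states are
    recorded, one per time step.
    """
    if n_columns < 1:
        raise ValidationError("n_columns must be >= 1")
    if burn_in < 0:
        raise ValidationError("burn_in must be non-negative")
    n = model.n_genes
    out = np.empty((n_replicates, n, n_columns), dtype=np.int8)
    state = random_state(n, rng, n_replicates)  # (n, r)
    for _ in range(burn_in):
        state = glauber_step(model, state, rng, include_diagonal)
    out[:, :, 0] = state.T
    for t in range(1, n_columns):
        state = glauber_step(model, state, rng, include_diagonal)
        out[:, :, t] = state.T
    return out


def generate_trajectory(
    model: IsingModel,
    n_columns: int,
    rng: np.random.Generator,
    burn_in: int = 0,
    include_diagonal: bool = True,
) -> GeneActivityMatrix:
    """Simulate one trajectory and wrap it as a gene-activity matrix.

    Column order is simulation time; the column index doubles as pseudotime.
    """
    spins = simulate_ensemble(model, n_columns, 1, rng, burn_in, include_diagonal)[0]
    cell_ids = np.asarray([f"t{k}" for k in range(n_columns)], dtype=object)
    return GeneActivityMatrix(
        spins, model.gene_ids.copy(), cell_ids, np.arange(n_columns, dtype=float)
    )
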