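# ignite-grn

Inference of **directed, weighted, signed gene regulatory networks (GRNs)**
from unperturbed single-cell transcriptomics, by solving the inverse problem
of an **asymmetric kinetic Ising model** — and then using the inferred model
generatively: simulating wild-type gene activity and in-silico gene
knockouts, and scoring both against reference interactions and perturbation
experiments.

It is aimed at computational biologists studying differentiation
trajectories (e.g. pluripotent stem cells transiting from naïve to
formative states) who have a gene × cell expression matrix, a per-cell
pseudotime, and a shortlist of regulators — and who want not just a network
but a dynamical model that can be perturbed.

## The model

Genes are spins \(s_i \in \{-1, +1\}\) (active / inactive). A coupling
matrix \(J\) (entry \(J_{ij}\): signed influence of gene *j* on gene *i*;
asymmetric, so edges are directed) and fields \(h_i\) (bias toward
activity) define Glauber dynamics: given the local field

\[
\theta_i(t) = h_i + \sum_j J_{ij}\, s_j(t),
\]

each spin is resampled independently each step, flipping with probability
\(p = \tfrac{\gamma\,\delta t}{2}\bigl(1 - s_i(t)\tanh\theta_i(t)\bigr)\)
(with \(\gamma = \delta t = 1\), the next state is +1 with probability
\((1+\tanh\theta_i)/2\)).

**Preprocessing** turns expression into a spin trajectory: log-normalize,
order cells by pseudotime, average pseudotime-adjacent cells into
overlapping *mini-bulks* (window *w*, step 1 — the dropout mitigation),
then binarize each gene at half its maximum over the trajectory.

**Inference** maximises the trajectory likelihood by gradient ascent:

\[
\partial\mathcal{L}/\partial J_{ij}
  = \langle s_i(t{+}1)\,s_j(t)\rangle - \langle \tanh\theta_i(t)\, s_j(t)\rangle,
\qquad
\partial\mathcal{L}/\partial h_i
  = \langle s_i(t) - \tanh\theta_i(t)\rangle ,
\]

with two optimisers (momentum gradient ascent and NADAM, both with a
step-decaying learning rate and an L1 sign penalty) and a random search
over a hyperparameter grid. Candidates are ranked by **CMD** (correlation
matrices distance: distance between the input data's Pearson correlation
matrix and that of model-generated data, scaled so shuffled-data nulls
score ≈ 1; lower is better) or, when curated edges are available, by
**FCI** (fraction of curated signed edges inferred with the right sign).

The selected model then *generates*: wild-type trajectories, and knockouts
by deleting the perturbed genes' rows/columns. Knockout responses are
scored against experimental log2 fold changes by the fraction of agreement
(FoA, with an exact-binomial significance threshold) and Spearman
correlation. An undirected maximum-entropy (partial-correlation) network
is included as a baseline.

## Worked example

Everything below runs from a synthetic study: a known sparse 10-gene model
simulates a trajectory that is dressed up as noisy, zero-inflated
expression, then pushed through the full pipeline.

```python
import numpy as np
from ignite_grn import (KineticIsing, sample_ground_truth, make_study,
                        run_preprocess, substream)
from ignite_grn.selection import cmd

rng = substream(0, "example")
truth = sample_ground_truth(10, density=0.2, coupling_scale=1.0, rng=rng)
expr, _ = make_study(truth, 20_000, dropout_rate=0.2, rng=rng)

mb, activity = run_preprocess(expr, window=5, step=1, lognorm="log1p")
res = KineticIsing(activity).fit(optimizer="MGA", eta0=0.5, dr=0.9,
                                 n_dr=20, xi_m=0.9, lam=0.01, n_epochs=500)
print(res.summary())
```

```
Kinetic Ising inverse-problem fit
==============================================
genes:            10
time points:      19996
optimizer:        MGA
eta0/dr/n_dr:     0.5/0.9/20
lambda (penalty): 0.01 (sign)
epochs:           500
converged:        True
final |grad J|:   7.539e-02
final |grad h|:   3.128e-02
|J| off-diag mean: 0.0222   max: 0.2864
h range:          [-0.2002, -0.0409]
```

Scoring the fitted network against the data and the planted truth:

```python
report = cmd(activity, res.to_ising_model(), n_replicates=50, n_shuffle=50,
             rng=substream(0, "example-cmd"))
print(f"CMD = {report.value:.3f}  (t-test vs null: p = {report.ttest_vs_null().pvalue:.2e})")

J_true, J_fit = truth.model.J, res.J.copy()
np.fill_diagonal(J_fit, 0.0)
off = ~np.eye(10, dtype=bool)
print(f"Pearson(J_true, J_fit) = {np.corrcoef(J_true[off], J_fit[off])[0, 1]:.3f}")
```

```
CMD = 0.261  (t-test vs null: p = 9.57e-79)
Pearson(J_true, J_fit) = 0.896
```

A CMD of 0.26 means data generated by the fitted model sits far closer to
the input's correlation structure than chance (CMD ≈ 1); the fitted
couplings correlate at 0.90 with the planted ones despite 20% dropout and
multiplicative noise.

The same pipeline is available from the shell:

```bash
ignite fixtures   --n-genes 10 --n-cells 20000 --seed 0 --out-dir fix/
ignite preprocess --matrix fix/expression.tsv --pseudotime fix/pseudotime.tsv \
                  --window 5 --no-lognorm --out-dir prep/
ignite infer      --activity prep/gene_activity.tsv --trials 25 --grid small \
                  --seed 0 --out-dir cand/
ignite select     --candidates cand/ --mode cmd --out best.tsv
ignite knockout   --model best.tsv --genes g0 --n-cells 20000 --out-dir ko/
```

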