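# Methods

## Model and assumptions

The package models a panel of genes as binary activity states
\(s_i \in \{-1,+1\}\) evolving under an **asymmetric kinetic Ising model**:
couplings \(J_{ij}\) (influence of gene *j* on gene *i*, in units of
temperature; not assumed symmetric, so the network is directed and signed)
and per-gene fields \(h_i\). The update rule is Glauber dynamics with rate
\(\gamma = 1\) and step \(\delta t = 1\): given
\(\theta_i = h_i + \sum_j J_{ij} s_j\), a spin's next state is +1 with
probability \((1 + \tanh\theta_i)/2\), independently per spin, with every
\(\theta\) evaluated from the previous full state. Because
\(\gamma\,\delta t = 1\), this parallel resampling reproduces exactly the
per-spin marginal of the asynchronous flip rule
\(p = \tfrac{\gamma\delta t}{2}(1 - s_i\tanh\theta_i)\).

Key modelling assumptions: parameters constant in time; one observed
trajectory whose consecutive columns (pseudotime-ordered mini-bulk
averages) are treated as unit time steps; no detailed balance is assumed —
the model is genuinely non-equilibrium, which is what permits asymmetric
(directed) couplings.

During inference the coupling matrix **includes self-couplings**: they
absorb autocorrelation the rest of the model cannot express and stabilise
the fit. They are not biologically interpretable, so the exported GRN drops
the diagonal (`to_ising_model(drop_diagonal=True)`); data generation
defaults to the full fitted model, with a switch, since the two conventions
differ and neither is canonical.

## Preprocessing

Order of operations is fixed: log-normalize → sort by pseudotime →
mini-bulk → binarize.

* **Log-normalization**: \(\bar x_{i\alpha} = \log_2(x_{i\alpha}/\sum_j
  x_{j\alpha} + 1)\). The depth-normalization step assumes the matrix spans
  enough genes for the per-cell total to be a meaningful size factor. For
  small curated panels (including the synthetic fixtures) a `log1p` mode
  applies only \(\log_2(x+1)\): dividing by the sum of a 10-gene panel
  would make each gene's value depend strongly on the panel's composition.
  The log transform matters beyond convention — the downstream half-max
  threshold is driven by each gene's maximum, and the log compresses the
  upper noise tail that would otherwise set that maximum.
* **Mini-bulk**: moving average over `window` pseudotime-adjacent cells
  with step 1; output column count \(\lfloor (N-w)/s\rfloor + 1\). This is
  the dropout mitigation: averaging neighbours fills stochastic zeros.
  Defaults: window 150 (whole-transcriptome mouse-scale data), 50 used for
  the smaller human-style dataset; both plain configuration.
* **Binarization**: \(s_i(t) = +1\) iff \(x_i(t) \ge \max_t x_i(t)/2\),
  threshold per gene over the mini-bulk matrix. An all-zero gene satisfies
  \(0 \ge 0\) and binarizes to all +1; the code warns and recommends
  filtering such genes upstream. Pseudotime ties are broken by cell id so
  sorting is deterministic.

## Inference

The log-likelihood gradient is the moment-matching difference between the
observed one-step-lagged correlation
\(D_{ij} = \langle s_i(t{+}1)s_j(t)\rangle\) and the model's conditional
expectation \(\langle\tanh\theta_i(t)\,s_j(t)\rangle\); for the fields,
\(\langle s_i(t) - \tanh\theta_i(t)\rangle\) (the same-time form of the
printed optimiser update is used deliberately; at stationarity it differs
from the \(t{+}1\) form by \(O(1/T)\)). Both averages run over the
\(T-1\) states that have a successor, so the lagged and conditional terms
share one sample.

* Initialisation: \(J = 0\), \(h = 0\) — deterministic and unbiased; the
  fit itself consumes no randomness, so a fit is reproducible from its
  hyperparameters alone.
* **MGA** (momentum gradient ascent): velocity
  \(v' = \xi_m v + \eta_n(g - \lambda\,\mathrm{sign}(\cdot))\), parameters
  += \(v'\); step-decaying learning rate
  \(\eta_n = \eta_0\,dr^{\lfloor n/n_{dr}\rfloor}\).
* **NADAM**: standard first/second moment recursions with \(\beta_1=0.9\),
  \(\beta_2=0.999\), \(\epsilon=10^{-8}\), bias correction, Nesterov
  look-ahead numerator
  \(\beta_1\hat m + (1-\beta_1)g/(1-\beta_1^n)\), denominator
  \(\sqrt{\hat v}+\epsilon\). The penalty is the same
  \(\lambda\,\mathrm{sign}(\cdot)\) subgradient as MGA (a literal
  \(\lambda\cdot\)parameter L2 variant is available via
  `penalty="l2"`); \(\mathrm{sign}(0)=0\).
* **Random search**: hyperparameter sets drawn uniformly with replacement
  from the configured grid (the full published grid ships as
  `DEFAULT_GRID`; `SMALL_GRID` is a subset for desk-scale runs). A fit
  that reaches non-finite parameters (possible at aggressive grid corners)
  is recorded as failed and excluded from selection rather than aborting
  the search.

## Scoring and selection

* **CMD**: generate replicates of the input's dimensions, average their
  Pearson correlation matrices element-wise, take
  \(d = \tfrac{1}{N}\sqrt{\sum_{ij}(A_{ij}-B_{ij})^2}\) to the input's
  correlation matrix, and divide by the mean \(d\) between the input and
  shuffled copies of itself. The square-root (Frobenius) reading of the
  distance is used — it is the version that is actually a Euclidean
  metric — with the no-root variant kept behind a flag. The shuffle
  permutes row indices and column indices (relabelling genes, destroying
  temporal order); an alternative per-row value permutation is available
  behind a flag. Constant genes (possible in knockout-reduced simulations)
  get correlation 0 with a warning instead of NaN.
* **FCI**: fraction of curated edges whose entry
  \(J_{\text{target},\text{regulator}}\) carries the curated sign; zero
  counts as wrong; undirected mode (for the MaxEnt baseline) accepts
  either orientation.
* **Selection**: argmin CMD or argmax FCI over successful candidates;
  exact ties are broken by a seeded uniform draw.
* **Permutation test**: null models are fitted on `n_test` shuffled
  datasets × `n_sets` hyperparameter draws (50 × 50 = 2500 at study
  scale); an edge is significant when its observed coupling falls strictly
  outside the null's 5th–95th percentile band.

## Knockouts and agreement scores

A knockout deletes the perturbed genes' rows and columns from \(J\) (and
their fields); the reduced model generates replicate datasets exactly as
the wild type (fresh random initial states per replicate). The per-gene
response is the KO-minus-WT difference of mean activity over all cells and
replicates; responses from all simulated KO conditions are scaled by one
family-wise max |Δ|, while experimental log2FC families are scaled by
their own maximum — the two families are never pooled.

FoA categorises scaled responses as positive (≥ thr), negative (≤ −thr) or
null (strictly inside), with thr = 0.05, and counts matching categories
over the retained genes. The printed source inequalities for these
categories are internally inconsistent; the evident intent implemented
here is the symmetric one just stated. Significance uses an exact
Binomial(n, 1/3) null: the threshold is \(k^*/n\) with \(k^*\) the least
\(k\) whose exact upper tail is ≤ 0.05. **Known deviation:** the reference
analysis reports this threshold as 0.48 for both n = 23 and n = 21;
exact enumeration gives 12/23 ≈ 0.522 and 12/21 ≈ 0.571. The enumeration
is kept (it is verified against a brute-force pmf sum for all n ≤ 50) and
the discrepancy is reported rather than reconciled.

The differentiation score
DS = (f_marker^KO / f_ref^KO) / (f_marker^WT / f_ref^WT) compares
late-marker vs early-marker positive-cell fractions within a caller-chosen
cluster; cluster assignment is injected (a label file or classifier), not
computed here.

## MaxEnt baseline

\(\rho_{ij} = -(C^{-1})_{ij}/\sqrt{(C^{-1})_{ii}(C^{-1})_{jj}}\) with C
the unbiased gene-gene covariance. These are partial correlations — the
maximum-entropy interaction structure under first- and second-moment
constraints — and are verified in tests against a regression-residual
oracle to 1e−10. Singular or near-singular covariances (fewer cells than
genes, collinear rows) raise instead of being silently ridge-regularised.

## Synthetic fixtures

`sample_ground_truth` plants a sparse random \(J\) (optional block
structure: within-group positive, between-group negative couplings, the
mutual-antagonism motif of sequential cell states) with small random
fields. `make_study` simulates a trajectory and maps spins to
pseudo-expression: active mean 10, inactive mean 1, multiplicative
lognormal noise σ = 0.3, then dropout-style zeroing with the given
probability; pseudotime is the step index. These constants are a fixture
convention — chosen once so half-max binarization is recoverable but not
trivial — not a claim about real data. The generator's values are on the
normalized-expression scale, so the pipeline consumes them with the
`log1p` transform (see Preprocessing).

What the fixtures do *not* emulate: negative-binomial count noise,
library-size variation, cell-type mixtures, or a pseudotime estimated with
error. Passing the recovery tests therefore shows the estimator and
pipeline arithmetic are correct under the stated noise model, not that any
particular biological dataset would be recovered.

The end-to-end regression uses a mini-bulk window of 5 (not the
study-scale 150): fixture columns are single Glauber steps, so the window
must stay small relative to the dynamics' correlation time or the
averaging itself would destroy the one-step statistics that inference
consumes. In real data, pseudotime-adjacent cells are nearly simultaneous
snapshots, which is what licenses the much wider window there.

## Numerical choices and problem sizes

* All RNG use flows through named substreams
  (`substream(seed, name)`, SHA-256-keyed), so changing one stage's trial
  count never perturbs another stage's stream; any run replays from
  (seed, config).
* Fits are deterministic; generation, shuffles, search draws and tie
  breaks are the only stochastic stages.
* Test and acceptance problem sizes: 10-gene planted models, trajectories
  of T = 20 000 (T = 100 000 for the gradient-at-truth check), 25-trial
  searches over `SMALL_GRID`, CMD with 10–50 replicates and 20–50
  shuffles, knockout checks with 50 replicates — sizes chosen so the whole
  suite runs in a few minutes on one CPU while keeping Monte Carlo
  tolerances (3σ binomial bounds, 5/√T gradient bounds) meaningful.
* The correlation-distance denominator warns-and-proceeds only through
  documented degeneracies; an all-zero null distance (constant data)
  raises.

## Known limitations

* Likelihood ascent reaches a local maximum; no global-optimality claim is
  made (hence the random search and the CMD/FCI selection layer).
* CMD compares only second-order (correlation) structure; two models with
  matching correlations but different higher-order statistics score alike.
* The exported GRN is *effective*, not physical: couplings absorb
  unobserved regulators (protein-level effects, chromatin state), and a
  knockout whose phenotype is driven by such layers will not be predicted
  from transcriptomic activity alone.
* Overexpression (forced activation) is not simulated; only removal-style
  knockouts are.
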