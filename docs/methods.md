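# Methods

`priorgraph` reconstructs the undirected regulatory network around a
*trans*-QTL hotspot — a genetic locus associated with many distant molecular
traits (gene expression or CpG methylation) — by combining cohort multi-omics
data with per-edge prior probabilities derived from public reference
resources. This note documents the model, the parameters that matter, the
synthetic-data generator, and the numerical and design choices.

## Locus sets

Inference is restricted to a *locus set* per hotspot to keep the number of
variables far below the sample size. Roles and windows:

| role | definition | window |
|---|---|---|
| SNP | sentinel variant of the hotspot | — |
| cis genes | genes whose interval intersects the SNP window | ±500 kb (closed window, interval intersection) |
| trans entities | the hotspot's trans-associated CpGs/genes | — |
| CpG genes | previous, next and overlapping gene per trans CpG | — |
| TFs | factors with a binding site near a trans entity | 50 bp around a CpG; promoter = 2000 bp upstream / 1000 bp downstream of the TSS, strand-aware |
| SP genes | interior genes of minimum node-cost PPI paths between trans entities and cis genes | — |

Coordinates are 0-based half-open internally (BED-native); 1-based TSV inputs
are converted at the I/O boundary. TFBS resources are pre-filtered to
blood-related cell labels by case-insensitive substring over an 18-term list.

Node scores for the path search come from a random walk with restart
(restart probability 0.5, uniform restart mass over the trans entities and
cis genes, power iteration to 1e-10). Scores are converted to nonnegative
node costs `W(v) = max(PS) − PS(v)`, which preserves the argmin paths of
"weight proportional to −PS" while remaining Dijkstra-safe. Path cost counts
interior nodes only, so a trans entity directly adjacent to a cis gene
contributes nothing; ties between minimum-cost paths are broken by the
lexicographically smallest node sequence, making the output deterministic.
Interior nodes that already carry a role (cis/trans/TF/SNP) are not re-added
as SP genes.

## Edge priors

Every unordered node pair receives exactly one prior class:

* **SNP–gene**: `1 − lFDR` of the pair's reference eQTL p-value.
* **gene–gene**: `1 − lFDR` of the Pearson co-expression p-value on
  preprocessed reference expression, restricted to PPI-connected pairs
  (TF→trans-target pairs excluded); the lFDR is estimated globally over all
  supplied pairs.
* **CpG–gene**: the (optionally cell-type-weighted) proportion of reference
  cell lines whose chromatin state at the CpG's 200-bp window is TSS-related
  ({TssA, TssAFlnk, TssBiv, BivFlnk} of the 15-state model), assigned only
  when CpG and gene are within 200 bp.
* **TF–target**: fixed 0.99 for binding-site-supported TF/trans pairs.
* **pseudo**: exactly 1e-7 for everything else. Assembled values are clipped
  to [1e-7, 0.999999] so Bernoulli sampling and prior odds stay defined.

Reference expression preprocessing: log2(x+1), per-sample quantile
normalisation, per-gene rank-based inverse-normal transform, and removal of
the projection onto the first 10 principal components (confounder removal).

**lFDR estimator.** The local false discovery rate is the posterior
probability of a null case under the two-component model with uniform null:
`lfdr(p) = η0 / f(p)`, clipped to [0, 1]. The marginal density `f` is the
Grenander estimator — the slopes of the least concave majorant of the
empirical CDF on [0, 1], left-continuous at the knots so that tied small
p-values take the slope of their own ECDF jump. The null proportion η0 is the
density plateau near p = 1, measured as the average density on (0.8, 1]
(the terminal hull segment is degenerate because the ECDF reaches 1 at the
largest observation, so the raw terminal slope is not usable). An isotonic
pass enforces monotonicity of lfdr in p. The estimator requires 200 p-values
by default (`min_pvalues`); the partial-correlation engine lowers this bound
to 30 because its input is the set of node pairs (190 pairs for 20 nodes).
Simulations with known null proportion (η0 ∈ {0.5, 0.8, 1.0}, n = 5000)
recover η0 within ±0.1.

A *density prior* is also available: the single value
`max(mean |E(G_T)| / [n(n−1)/2], 1e-7)` over sampled ground-truth graphs,
used to test how much knowing only the sparsity helps.

## Simulation benchmark

For each synthetic hotspot prior matrix `P`: a ground-truth graph `G_T` is
Bernoulli-sampled from `P` (edges only where the prior exceeds the pseudo
floor); an error ladder `G^10 … G^100` is built by degree-preserving rewiring
in which the requested fraction of original edges is replaced and every
introduced edge must carry no prior — comparing `P`'s support with `G^F`
then realises a prior error of F. Rewiring is operationalised as double-edge
swaps with stall-triggered restarts; because the constrained swap space can
be disconnected, a stalled search falls back to exact construction (an
integer program with randomised costs choosing replacement edges with the
required residual degrees among allowed pairs, enumerating kept-original
subsets exhaustively when few). Instances for which the exact search also
fails are genuinely infeasible — e.g. a 4-cycle cannot be fully rewired on 4
nodes since its complement has only two edges — and raise an explicit error;
the benchmark records such cells instead of aborting.

Data are drawn i.i.d. multivariate normal with a precision matrix supported
exactly on the scoring graph: off-diagonal entries uniform ±[0.4, 0.8] on
edges, diagonal `|λ_min| + 0.1` (diagonal dominance), covariance standardised
to unit variances. The SNP column (first node) is discretised to dosages
{0, 1, 2} by order-statistic (type-1) quantile cuts at the Hardy–Weinberg
dosage frequencies of the configured allele frequency (default 0.3).

Benchmark defaults mirror the study conditions: 612 samples, error ladder
0–100% in 10% steps, optional sample-size (50…600) and prior-completeness
(keep 10…90%) grids, 100 runs. The shipped acceptance run scales this to
20 hotspots × 1 run at n = 600 with a 34-point penalty grid, which keeps the
full two-engine ladder within a desk-scale compute budget; all seeds derive
from a single root seed and every cell's data depend only on its own key, so
prior-aware and prior-free engines are compared on identical data and folds.

What the generator does *not* emulate: methylation beta distributions,
probe-level missingness patterns, LD structure beyond a single SNP column,
and confounding — passing benchmarks show correct recovery under the
graphical-model assumptions, not robustness to array artefacts.

## Inference engines

All engines operate on rank-gaussianised data (per-column inverse-normal
transform with average ranks and offset (r − 0.5)/n), a Gaussian-copula
surrogate that lets the dosage column enter uniformly. All are deterministic
given (data, prior, seed), and are exposed both as sklearn-style estimators
(`fit`, `get_params`, trailing-underscore attributes) and as functions.

**Penalised MLE (`PriorGraphicalLasso`).** Solves
`max log det Θ − tr(SΘ) − Σ_{i≠j} Λ_ij |Θ_ij|` by block coordinate descent
with a full per-edge penalty matrix `Λ = (1 − P)·ω` (constant ω without
priors; diagonal unpenalised). A prior of 1 removes the penalty; the pseudo
prior leaves ≈ ω. The global weight ω is screened over a grid by 5-fold
cross-validation: fit on training folds, score by test-fold BIC
`−2ℓ(Θ̂; S_test, n_test) + |E| log n_test` (the edge-count term uses the
test-fold size, keeping likelihood and penalty on one scale), refit at the
argmin. Stationarity (KKT) of every fit holds to 1e-6:
`|S_ij − Σ̂_ij| ≤ Λ_ij` on zeros and `S_ij − Σ̂_ij + Λ_ij·sign(Θ_ij) = 0`
on non-zeros, which the 2-variable closed form (edge iff `|s12| > Λ12`)
confirms exactly. The default grid is {0.01, 0.015, …, 1}; the benchmark
uses a 34-point coarsening of the same range.

**Shrinkage partial correlations (`ShrinkagePartialCorrelation`).** Analytic
shrinkage of the correlation matrix toward the identity with the closed-form
intensity `λ* = Σ V̂ar(r_ij) / Σ r_ij²` (clamped to [0, 1]), inversion to
partial correlations, Fisher-z p-values with degrees of freedom
`n − (p − 2) − 3`, and edge-wise lFDR screening keeping lfdr ≤ 0.2
(equivalently posterior edge probability ≥ 0.8).

**Bayesian structure search (`BayesianStructureMCMC`).** A
Metropolis sampler over graph structures with single-edge toggle proposals:
acceptance probability `min(1, exp(−ΔBIC/2) · prior odds)` with Bernoulli
edge priors (0.5 everywhere when no prior is supplied; the chain starts from
the incidence of priors > 0.5). The marginal likelihood of a graph is
approximated through the BIC of its support-constrained Gaussian MLE
(covariance selection), computed by iterative proportional scaling over edge
and vertex cliques with Woodbury covariance updates and warm starts, so a
toggle costs little. This is a deliberately simplified surrogate for
G-Wishart birth–death samplers: it preserves the functional role of per-edge
prior probabilities, the posterior cutoff 0.9, and the prior-based start
graph at desk scale. On three nodes the sampler agrees with brute-force
enumeration over all 8 graphs (same BIC surrogate) within ±0.05 at 50 000
iterations. Defaults: 10 000 iterations, 5 000 burn-in, posterior cutoff 0.9.

**Tree-ensemble ranking (`TreeEnsembleNetwork`).** Each column is regressed
on all others with a random forest (importances normalised by sklearn);
directed weights are symmetrised by the maximum. The final network is chosen
by scale-free-topology fit: candidate cutoffs are 200 weight quantiles; for
each candidate, R² of log10 frequency vs log10 degree over 10 logarithmic
degree bins (zero bins dropped); among candidates with R² > 0.8 the one with
most edges wins, otherwise the highest-R² candidate. Candidates with fewer
than 3 usable bins are excluded from the fit (a 2-point regression is always
perfect) and only serve as a last-resort largest network. Default 100 trees
(a runtime compromise; the ranking is stable for the planted-signal regimes
tested).

## Evaluation, prioritisation, TFA

Networks are scored by the Matthews correlation coefficient over unordered
node pairs, computed from TP/TN/FP/FN with the convention MCC = 0 when any
denominator factor vanishes; node sets are reconciled by union (a node absent
from one network contributes only non-edges there). Sensitivity and
specificity use the 0/0 → 0 convention.

The graph score of an inferred hotspot network,

    S_G = −log10(D_G) · [ (|G_S| − |G̅_S|)/|G_C| + (|G_T| − |G̅_T|)/|T| ],

is computed on the connected component containing the SNP: G_S are cis genes
adjacent to the SNP or to another cis gene (1-hop adjacency — chains of cis
genes do not propagate membership); G̅_S the remaining cis genes in the
cluster; G_T trans entities reachable from a cis gene without traversing the
SNP or another trans entity *and* not directly attached to the SNP; G̅_T the
SNP-adjacent trans entities; D_G the edge density of the cluster (cluster
node count in the denominator). The score is 0 when the SNP is absent or no
cis gene shares its cluster. Ranking is by score (desc), then edge count,
node count and identifier (asc). Consensus networks keep the edge
intersection of two cohorts' networks and only nodes with surviving edges.

Transcription factor activities solve
`min_a ‖e − C a‖² + ridge‖a‖²` per sample on standardised expression, with C
the genes × TFs promoter-binding incidence. Ridge least squares replaces the
partial-least-squares estimator sometimes used for this model because it is
closed-form and has no unspecified rank hyperparameter; ridge defaults to
1e-3 (activity scale is arbitrary; only correlations matter downstream). TFs
without any measured target are dropped with a warning.

## Numerical choices and degenerate inputs

* Graphical-lasso convergence: mean-absolute-change criterion scaled by the
  mean |off-diagonal| of S, tolerance 1e-6, inner lasso tolerance 1e-7; a
  non-convergent fit raises with the primal-dual gap.
* IPS tolerance 1e-7 (max constraint residual), with periodic full
  re-inversion of the state to cancel Woodbury drift; non-PD proposals are
  rejected and counted.
* Constant columns cannot be rank-gaussianised and raise by name.
* Quantile conventions are fixed: type-1 (order statistic) for SNP
  discretisation; numpy linear interpolation for the predicted-TFBS width
  filter (strict `<` at the 95th percentile).
* Empty prediction / empty truth combinations return MCC 0 by the
  zero-denominator convention.

## Known limitations

* The Bayesian engine's BIC surrogate approximates the G-Wishart marginal
  likelihood; posterior probabilities are calibrated against its own
  enumeration oracle, not against the exact Gaussian graphical posterior.
* The prior-weighted random-forest engine family (per-split candidate
  sampling proportional to priors) is not implemented; the benchmark accepts
  external engines through its registry instead.
* Colocalisation, LD computation, cohort preprocessing and cell-type
  deconvolution are out of scope; their outputs are consumed as inputs.
* At strong-signal conditions (n = 600, 25 nodes, edge partial correlations
  from the ±[0.4, 0.8] construction) the Bayesian engine can saturate
  (MCC ≈ 1 with and without priors), compressing the measurable prior
  benefit; the penalised engine separates clearly under the same conditions.
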