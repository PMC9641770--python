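# priorgraph

Prior-guided reconstruction of the regulatory networks behind *trans*-QTL
hotspots.

A *trans*-QTL hotspot is a genetic locus associated with many molecular
traits — gene expression levels or CpG methylation — on other chromosomes.
The statistical associations alone say nothing about the regulatory cascade
(SNP → nearby cis gene → transcription factor → distant targets) that
produces them. `priorgraph` reconstructs that cascade as an undirected
Gaussian graphical model over a curated *locus set* of entities, guiding
inference with per-edge prior probabilities distilled from public reference
data, and ships the simulation benchmark used to decide which inference
strategy to trust.

It is aimed at statistical geneticists and systems biologists who have
trans-QTL results plus cohort multi-omics matrices and want mechanistic
network hypotheses with quantified robustness.

## What it does

1. **Hotspot curation** (`priorgraph.hotspots`): extract hotspots (≥ 5 trans
   targets) from association tables, collapse LD-clustered SNPs, and build
   role-tagged locus sets — sentinel SNP, cis genes (±500 kb), trans
   entities, genes around trans CpGs, TFs with binding sites near the trans
   entities (50 bp for CpGs; promoter −2000/+1000 bp for genes), and genes on
   propagation-weighted shortest PPI paths bridging the two sides.
2. **Edge priors** (`priorgraph.priors`): SNP–gene priors `1 − lFDR` from
   reference eQTL p-values (own Grenander-based local-FDR estimator),
   gene–gene priors from reference co-expression of PPI-connected pairs,
   CpG–gene priors from the proportion of reference cell lines with a
   TSS-like chromatin state at the CpG, a fixed 0.99 for TF–target pairs
   with binding evidence, and a 1e-7 pseudo-prior everywhere else.
3. **Inference engines** (`priorgraph.infer`, sklearn-style estimators):
   a graphical lasso with *per-edge* penalties `Λ = (1 − P)·ω` and 5-fold
   CV/BIC selection of ω; shrinkage partial correlations with lFDR edge
   screening; a Bayesian graph-structure MCMC with Bernoulli edge priors and
   a BIC marginal-likelihood surrogate (posterior cutoff 0.9); and a
   tree-ensemble link ranker with scale-free-topology cutoff selection.
4. **Benchmark** (`priorgraph.simulate`): sample ground-truth graphs from
   the priors, inject prior error by degree-preserving rewiring (replacement
   edges must carry no prior), simulate Gaussian data with the graph's
   precision structure, discretise the SNP column to dosages, and sweep
   error / sample-size / prior-completeness grids.
5. **Evaluation and prioritisation** (`priorgraph.evaluate`,
   `priorgraph.prioritize`): Matthews correlation coefficient

       MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))

   over node pairs against ground truth or across cohorts; the graph score

       S_G = −log10(D_G) · [(|G_S| − |G̅_S|)/|𝒢_C| + (|G_T| − |G̅_T|)/|𝒯|]

   rewarding SNP-attached cis genes and cis-mediated trans targets while
   penalising density; GWAS-catalog filtering; and consensus merging of
   cohort networks (edge intersection).
6. **TF activities** (`priorgraph.tfa`): per-sample TF activity estimates
   from target-gene expression via ridge regression on a promoter-binding
   incidence matrix, to substitute for TF expression before inference.

Everything is testable offline: `priorgraph.fixtures` generates annotation,
TFBS, chromatin-state, PPI, QTL and cohort artifacts with planted ground
truth in the standard text formats (BED/TSV).

## Worked example

From a synthetic hotspot universe to replicated networks:

```python
import numpy as np
from priorgraph import (
    FixtureSpec, make_locus_fixture, make_prior_reference, make_cohort_pair,
    assemble_prior_matrix, snp_gene_priors, gene_gene_priors, cpg_gene_priors,
    tf_target_priors, build_locus_set, penalized_cv, cross_cohort_mcc,
    confusion, mcc, graph_score,
)

spec = FixtureSpec(seed=0, n_samples=300)
fx = make_locus_fixture(spec)
ls = build_locus_set(fx.hotspot, fx.annotation, fx.tfbs, fx.ppi,
                     fx.expressed, fx.trans_positions)

eqtl, ref_expr, ppi_pairs = make_prior_reference(fx, spec, fraction=1.0)
trans = {t: (c, p, "cpg") for t, (c, p) in fx.trans_positions.items()}
ann = {g.gene_id: g for g in fx.annotation}
P = assemble_prior_matrix(
    ls,
    snp_gene=snp_gene_priors(eqtl, min_pvalues=100),
    gene_gene=gene_gene_priors(ref_expr, ppi_pairs, min_pvalues=20),
    cpg_gene=cpg_gene_priors(fx.trans_positions, fx.annotation, fx.chromhmm),
    tf_target=tf_target_priors(set(ls.tfs), trans, fx.tfbs, ann),
)

cohort_a, cohort_b = make_cohort_pair(ls, fx.true_network, spec)
grid = tuple(np.round(np.arange(0.02, 0.81, 0.02), 3))
net_a = penalized_cv(cohort_a, P, omega_grid=grid, rng=0)
net_b = penalized_cv(cohort_b, P, omega_grid=grid, rng=0)
print(f"MCC vs ground truth (cohort A): {mcc(confusion(net_a, fx.true_network)):.3f}")
print(f"cross-cohort MCC: {cross_cohort_mcc(net_a, net_b):.3f}")
print(f"graph score (cohort A network): {graph_score(net_a, ls).score:.3f}")
```

Output:

```
locus set: 17 nodes (3 cis, 5 trans CpGs, 2 TFs, 5 CpG genes, 1 SP genes)
prior matrix: 19 informative pairs of 136
inferred networks: 19 and 18 edges
MCC vs ground truth (cohort A): 1.000
cross-cohort MCC: 0.969
graph score (cohort A network): 0.990
```

Reading it: the locus-set builder recovered exactly the planted roles; the
assembled prior matrix concentrates mass on the 19 evidence-backed pairs;
with full priors and 300 samples per cohort the penalised engine recovers
the planted network perfectly in cohort A, the two cohorts' networks agree
almost completely (cross-cohort MCC 0.969), and the network scores highly
because the SNP attaches to a cis gene and the trans CpGs are reached
through cis genes and TFs rather than directly from the SNP.

A `priorgraph` command-line interface wraps the same functions
(`priorgraph hotspots`, `locusset`, `infer`, `evaluate`, `score`, `merge`,
`tfa`, `benchmark`, `fixtures`); see `priorgraph --help`.

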