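"""Data-driven edge priors for locus-set networks.

Four evidence classes map public reference data onto per-edge prior
probabilities: SNP-to-cis-gene priors from reference eQTL p-values via
``1 - lFDR``; gene-to-gene priors from reference co-expression of
PPI-connected pairs (again ``1 - lFDR``); CpG-to-gene priors from the
proportion of reference cell lines whose chromatin state at the CpG is
TSS-related; and a fixed 0.99 prior for TF-target pairs with binding-site
evidence. Everything else receives the pseudo-prior ``1e-7``.

The local false discovery rate (lFDR) is the posterior probability that a
p-value arises under the null, lfdr(p) = eta0 * f0(p) / f(p) with uniform
null f0 = 1; the marginal density f is estimated by the Grenander
(monotone-decreasing) estimator on the p-scale and eta0 from the density
plateau at p = 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .hotspots import GeneAnnotation, LocusSet, tf_target_pairs
from .network import PSEUDO_PRIOR, PRIOR_CAP, PriorMatrix, UndirectedNetwork

logger = logging.getLogger(__name__)

#: 15-state chromatin-model mnemonics.
CHROMHMM_STATES = (
    "TssA", "TssAFlnk", "TxFlnk", "Tx", "TxWk", "EnhG", "Enh", "ZNF/Rpts",
    "Het", "TssBiv", "BivFlnk", "EnhBiv", "ReprPC", "ReprPCWk", "Quies",
)
#: States counted as TSS-related ("active transcription start") for CpG priors.
TSS_STATES = frozenset({"TssA", "TssAFlnk", "TssBiv", "BivFlnk"})
#: Maximum CpG-to-gene genomic distance for a chromatin-state prior.
CPG_GENE_MAX_DIST = 200


# ---------------------------------------------------------------------------
# Local false discovery rate
# ---------------------------------------------------------------------------

@dataclass
class LfdrEstimate:
    """Grenander-based lFDR fit.

    Attributes
    ----------
    pvalues : input p-values (original order)
    lfdr : lfdr per input p-value, in [0, 1], nondecreasing in p
    eta0 : estimated null proportion (density plateau at p = 1)
    knots, slopes : piecewise-constant density representation
        (f(p) = slopes[k] on (knots[k], knots[k+1]]; left-continuous at knots
        so that tied small p-values take the slope of their own ECDF jump)
    """

    pvalues: np.ndarray
    lfdr: np.ndarray
    eta0: float
    knots: np.ndarray
    slopes: np.ndarray

    def density(self, p) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        k = np.clip(np.searchsorted(self.knots, p, side="left") - 1, 0,
                    len(self.slopes) - 1)
        return self.slopes[k]

    def evaluate(self, p) -> np.ndarray:
        """lfdr at arbitrary p in (0, 1]."""
        f = np.maximum(self.density(p), 1e-300)
        return np.clip(self.eta0 / f, 0.0, 1.0)


def _concave_majorant_slopes(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least concave majorant of points (x, y); returns hull x and segment slopes."""
    hull: list[int] = []
    for i in range(len(x)):
        while len(hull) >= 2:
            i1, i2 = hull[-2], hull[-1]
            # keep turn right (concave): slope must be nonincreasing
            cross = (x[i2] - x[i1]) * (y[i] - y[i1]) - (y[i2] - y[i1]) * (x[i] - x[i1])
            if cross >= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    hx = x[hull]
    hy = y[hull]
    slopes = np.diff(hy) / np.diff(hx)
    return hx, slopes


def estimate_lfdr(pvalues: Sequence[float], min_pvalues: int = 200,
                  plateau_start: float = 0.8) -> LfdrEstimate:
    """Estimate local false discovery rates from a batch of p-values.

    Fits the two-component model with uniform null: the marginal density f is
    the Grenander estimator (slopes of the least concave majorant of the
    empirical CDF on [0, 1]); eta0 is the density plateau near p = 1,
    measured as the average density on (plateau_start, 1] and clipped to
    [0, 1]; lfdr(p) = min(1, eta0 / f(p)) followed by an isotonic pass.
    """
    p = np.asarray(pvalues, dtype=float)
    bad = np.nonzero(~((p > 0) & (p <= 1)))[0]
    if bad.size:
        raise ValueError(f"p-values outside (0, 1] at indices {bad[:10].tolist()}")
    if p.size < min_pvalues:
        raise ValueError(
            f"need at least {min_pvalues} p-values for density estimation, got {p.size}"
        )
    order = np.argsort(p, kind="stable")
    ps = p[order]
    n = p.size
    # ECDF knots (0,0) .. (p_(i), i/n) .. (1,1), unique x keeping max y
    xs = np.concatenate(([0.0], ps, [1.0]))
    ys = np.concatenate(([0.0], np.arange(1, n + 1) / n, [1.0]))
    ux, last_idx = np.unique(xs, return_index=True)
    # np.unique keeps first occurrence; we want max y per x = last occurrence
    uy = np.maximum.reduceat(ys, last_idx)
    # reduceat over runs of equal x: indices of run starts are last_idx (sorted)
    hx, slopes = _concave_majorant_slopes(ux, uy)
    # plateau height near p = 1: average density over the tail window, which
    # is robust to the degenerate terminal hull segment (ECDF hits 1 at p_(n))
    tail = float(np.mean(ps > plateau_start))
    eta0 = float(np.clip(tail / (1.0 - plateau_start), 0.0, 1.0))
    knots = hx
    f_at = np.maximum(slopes[np.clip(np.searchsorted(knots, ps, side="left") - 1,
                                     0, len(slopes) - 1)], 1e-300)
    lf_sorted = np.clip(eta0 / f_at, 0.0, 1.0)
    lf_sorted = np.maximum.accumulate(lf_sorted)  # monotone in p
    lf = np.empty(n)
    lf[order] = lf_sorted
    return LfdrEstimate(pvalues=p, lfdr=lf, eta0=eta0, knots=knots, slopes=slopes)


# ---------------------------------------------------------------------------
# SNP-to-gene priors
# ---------------------------------------------------------------------------

def snp_gene_priors(
    eqtl_pvalues: pd.DataFrame, min_pvalues: int = 200
) -> dict[tuple[str, str], float]:
    """Priors ``1 - lfdr`` for SNP-cis-gene pairs from a reference eQTL table.

    ``eqtl_pvalues`` needs columns (snp, gene, p); the lFDR is estimated over
    all p-values in the table. Pairs absent from the table simply receive no
    entry (pseudo-prior on assembly).
    """
    est = estimate_lfdr(eqtl_pvalues["p"].to_numpy(), min_pvalues=min_pvalues)
    out: dict[tuple[str, str], float] = {}
    for (snp, gene), lf in zip(
        zip(eqtl_pvalues["snp"], eqtl_pvalues["gene"]), est.lfdr
    ):
        out[(snp, gene)] = float(1.0 - lf)
    return out


# ---------------------------------------------------------------------------
# Gene-to-gene priors (reference co-expression of PPI-connected pairs)
# ---------------------------------------------------------------------------

def preprocess_reference_expression(
    raw: pd.DataFrame, n_pcs: int = 10
) -> pd.DataFrame:
    """Normalise a samples x genes reference expression matrix.

    log2(x + 1), per-sample quantile normalisation, per-gene rank-based
    inverse-normal transform, then removal of the projection onto the first
    ``n_pcs`` principal components.
    """
    if raw.isna().any().any():
        raise ValueError("missing values in reference expression")
    n, g = raw.shape
    if n_pcs >= min(n, g):
        raise ValueError(f"n_pcs={n_pcs} must be < min(n_samples, n_genes)={min(n, g)}")
    x = np.log2(raw.to_numpy(dtype=float) + 1.0)
    # quantile normalisation across samples (rows): each sample gets the mean
    # sorted profile
    order = np.argsort(x, axis=1)
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(g)[None, :], axis=1)
    mean_profile = np.sort(x, axis=1).mean(axis=0)
    x = mean_profile[ranks]
    # per-gene rank inverse-normal transform
    r = stats.rankdata(x, axis=0, method="average")
    x = stats.norm.ppf((r - 0.5) / n)
    x -= x.mean(axis=0)
    if n_pcs > 0:
        u, s, vt = np.linalg.svd(x, full_matrices=False)
        proj = (u[:, :n_pcs] * s[:n_pcs]) @ vt[:n_pcs]
        x = x - proj
    return pd.DataFrame(x, index=raw.index, columns=raw.columns)


def gene_gene_priors(
    reference_expression: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    min_pvalues: int = 200,
) -> dict[tuple[str, str], float]:
    """Priors ``1 - lfdr`` from Pearson co-expression of eligible gene pairs.

    ``pairs`` should already be restricted to PPI-connected pairs among the
    eligible roles; the lFDR is estimated globally over the p-values of all
    supplied pairs. Pairs with a gene missing from the reference are logged
    and skipped (pseudo-prior on assembly).
    """
    expr = reference_expression
    usable: list[tuple[str, str]] = []
    for a, b in pairs:
        if a == b:
            raise ValueError(f"self pair {a!r}")
        if a in expr.columns and b in expr.columns:
            usable.append((a, b))
        else:
            logger.warning("gene pair (%s, %s) missing from reference expression", a, b)
    if not usable:
        return {}
    pvals = np.array([
        stats.pearsonr(expr[a].to_numpy(), expr[b].to_numpy()).pvalue
        for a, b in usable
    ])
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    est = estimate_lfdr(pvals, min_pvalues=min_pvalues)
    return {pair: float(1.0 - lf) for pair, lf in zip(usable, est.lfdr)}


# ---------------------------------------------------------------------------
# CpG-to-gene priors (chromatin states)
# ---------------------------------------------------------------------------

def _state_at(
    intervals: Sequence[tuple[str, int, int, str]], chrom: str, pos: int
) -> str | None:
    """Chromatin state of the half-open window containing a position."""
    for c, start, end, state in intervals:
        if c == chrom and start <= pos < end:
            return state
    return None


def cpg_state_proportions(
    cpg_positions: Mapping[str, tuple[str, int]],
    chromhmm: Mapping[str, Sequence[tuple[str, int, int, str]]],
    weights: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Per-CpG (weighted) proportion of cell lines in a TSS-related state.

    ``chromhmm`` maps cell line -> state intervals (chrom, start, end, state).
    Optional ``weights`` (e.g. population-mean blood cell-type proportions
    mapped onto cell lines) reweight the proportion; cell lines without a
    weight receive the mean of the provided weights.
    """
    lines = sorted(chromhmm)
    if weights is not None and len(weights) > 0:
        mean_w = float(np.mean(list(weights.values())))
        w = np.array([weights.get(cl, mean_w) for cl in lines], dtype=float)
    else:
        w = np.ones(len(lines))
    out: dict[str, float] = {}
    for cpg, (chrom, pos) in cpg_positions.items():
        num = den = 0.0
        for cl, wi in zip(lines, w):
            state = _state_at(chromhmm[cl], chrom, pos)
            if state is None:
                continue
            if state not in CHROMHMM_STATES:
                raise ValueError(f"unknown chromatin state mnemonic {state!r}")
            den += wi
            if state in TSS_STATES:
                num += wi
        out[cpg] = num / den if den > 0 else 0.0
    return out


def cpg_gene_priors(
    cpg_positions: Mapping[str, tuple[str, int]],
    annotation: Sequence[GeneAnnotation],
    chromhmm: Mapping[str, Sequence[tuple[str, int, int, str]]],
    weights: Mapping[str, float] | None = None,
) -> dict[tuple[str, str], float]:
    """Chromatin-state priors for CpG-gene pairs within 200 bp of each other."""
    props = cpg_state_proportions(cpg_positions, chromhmm, weights)
    out: dict[tuple[str, str], float] = {}
    for cpg, (chrom, pos) in cpg_positions.items():
        for g in annotation:
            if g.chrom != chrom:
                continue
            if g.start <= pos < g.end:
                dist = 0
            elif pos < g.start:
                dist = g.start - pos
            else:
                dist = pos - (g.end - 1)
            if dist <= CPG_GENE_MAX_DIST:
                out[(cpg, g.gene_id)] = props[cpg]
    return out


# ---------------------------------------------------------------------------
# TF-to-target priors
# ---------------------------------------------------------------------------

def tf_target_priors(
    tfs: set[str],
    trans_entities: Mapping[str, tuple[str, int, str]],
    tfbs,
    annotation: Mapping[str, GeneAnnotation],
    prior: float = 0.99,
) -> dict[tuple[str, str], float]:
    """Fixed large prior for TF-trans pairs with binding-site evidence."""
    out: dict[tuple[str, str], float] = {}
    for tf, target in tf_target_pairs(trans_entities, tfbs, annotation):
        if tf in tfs and tf != target:
            out[(tf, target)] = prior
    return out


# ---------------------------------------------------------------------------
# Assembly & density prior
# ---------------------------------------------------------------------------

def assemble_prior_matrix(
    locus_set: LocusSet,
    snp_gene: Mapping[tuple[str, str], float] | None = None,
    gene_gene: Mapping[tuple[str, str], float] | None = None,
    cpg_gene: Mapping[tuple[str, str], float] | None = None,
    tf_target: Mapping[tuple[str, str], float] | None = None,
) -> PriorMatrix:
    """Assemble the symmetric prior matrix in locus-set node order.

    Each unordered node pair may be claimed by at most one evidence class;
    a pair claimed twice raises. Unset or zero entries become the
    pseudo-prior; values are clipped to [1e-7, 0.999999]. Map entries whose
    nodes are not in the locus set are ignored.
    """
    pm = PriorMatrix(locus_set.node_order)
    node_set = set(locus_set.node_order)
    claimed: dict[tuple[str, str], str] = {}
    for cls, mapping in (
        ("snp_gene", snp_gene), ("gene_gene", gene_gene),
        ("cpg_gene", cpg_gene), ("tf_target", tf_target),
    ):
        if not mapping:
            continue
        for (a, b), v in mapping.items():
            if a not in node_set or b not in node_set or a == b:
                continue
            key = (a, b) if a < b else (b, a)
            if key in claimed:
                raise ValueError(
                    f"pair {key} claimed by both {claimed[key]!r} and {cls!r}"
                )
            claimed[key] = cls
            pm.set_prior(a, b, v, cls)
    pm.validate()
    return pm


def density_prior(sampled_graphs: Sequence[UndirectedNetwork], n_nodes: int) -> float:
    """Uniform prior reflecting the density of sampled ground-truth graphs.

    ``max(mean(|E_G|) / |E_T|, 1e-7)`` with ``|E_T| = n(n-1)/2``.
    """
    if len(sampled_graphs) == 0:
        raise ValueError("no sampled graphs")
    e_total = n_nodes * (n_nodes - 1) / 2
    mean_edges = float(np.mean([g.n_edges for g in sampled_graphs]))
    return max(mean_edges / e_total, PSEUDO_PRIOR)
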