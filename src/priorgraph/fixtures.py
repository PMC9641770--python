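"""Synthetic input generators with planted ground truth.

Everything the pipeline consumes — gene annotation, TFBS, chromatin states,
PPI edges, QTL tables, reference expression, cohort omics — can be generated
here with known structure, so locus-set construction, prior assembly,
inference and evaluation are all testable end to end without downloads.
Fixtures are deterministic: the same spec yields identical artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hotspots import (
    GeneAnnotation,
    Hotspot,
    LocusSet,
    PpiNetwork,
    QtlRecord,
    TfbsInterval,
)
from .network import PriorMatrix, UndirectedNetwork
from .simulate import OmicsDataset, discretize_snp, hwe_dosage_freqs, simulate_gaussian


@dataclass
class FixtureSpec:
    """Parameters of a planted meQTL hotspot universe."""

    n_cis: int = 3
    n_trans: int = 5          # trans CpGs
    n_tfs: int = 2
    n_sp: int = 1             # planted PPI shortest-path genes
    n_samples: int = 200
    n_ref_samples: int = 300  # reference expression samples (prior source)
    allele_freq: float = 0.3
    noise_sd: float = 0.5
    seed: int = 0

    snp_id: str = "rs1"
    snp_chrom: str = "chr1"
    snp_pos: int = 10_000_000
    trans_chrom: str = "chr2"


@dataclass
class LocusFixture:
    annotation: list[GeneAnnotation]
    tfbs: list[TfbsInterval]
    chromhmm: dict[str, list[tuple[str, int, int, str]]]
    ppi: PpiNetwork
    qtl_records: list[QtlRecord]
    trans_positions: dict[str, tuple[str, int]]
    expressed: set[str]
    locus_set: LocusSet
    true_network: UndirectedNetwork
    hotspot: Hotspot


def make_locus_fixture(spec: FixtureSpec) -> LocusFixture:
    """Build a hotspot universe whose locus-set construction is fully known.

    Plants: cis genes inside the 1 Mbp window (plus one decoy outside), one
    overlapping gene per trans CpG, TFs with binding sites within 50 bp of
    every CpG, and a PPI chain ``cis0 - SP_k - TF_j`` whose interior genes are
    the expected shortest-path genes. The true network wires the SNP to cis0,
    cis0 to each TF through the SP chain, each TF to its CpGs, and each CpG to
    its overlapping gene.
    """
    s = spec
    cis = [f"CIS{i}" for i in range(s.n_cis)]
    cpgs = [f"cg{i:05d}" for i in range(s.n_trans)]
    cpg_genes = [f"TG{i}" for i in range(s.n_trans)]
    tfs = [f"TF{j}" for j in range(s.n_tfs)]
    sps = [f"SP{k}" for k in range(s.n_sp)]

    annotation: list[GeneAnnotation] = []
    for i, g in enumerate(cis):
        start = s.snp_pos - 400_000 + i * 120_000
        annotation.append(GeneAnnotation(g, s.snp_chrom, start, start + 20_000, "+"))
    # decoy outside the cis window
    annotation.append(GeneAnnotation(
        "FAR1", s.snp_chrom, s.snp_pos + 600_000, s.snp_pos + 620_000, "+"))

    trans_positions: dict[str, tuple[str, int]] = {}
    tfbs: list[TfbsInterval] = []
    for i, (cpg, tg) in enumerate(zip(cpgs, cpg_genes)):
        pos = 1_000_000 + i * 100_000
        trans_positions[cpg] = (s.trans_chrom, pos)
        annotation.append(GeneAnnotation(tg, s.trans_chrom, pos - 500, pos + 1_500, "+"))
        for tf in tfs:
            tfbs.append(TfbsInterval(tf, s.trans_chrom, pos + 10, pos + 30,
                                     "GM12878", 0.9995))
    # decoy binding site 51 bp away from a fictitious CpG-free position
    tfbs.append(TfbsInterval("TFX", s.trans_chrom, 900_000, 900_020, "GM12878", 0.9995))
    for tf in tfs + ["TFX"]:
        start = 5_000_000 + len(tfbs) * 1_000
        annotation.append(GeneAnnotation(tf, "chr3", start, start + 10_000, "+"))
    for k, sp in enumerate(sps):
        annotation.append(GeneAnnotation(
            sp, "chr4", 1_000_000 + k * 50_000, 1_010_000 + k * 50_000, "+"))

    # PPI: chain cis0 - SP0 - ... - SP_{n-1} - each TF, plus a costly detour
    ppi_edges: list[tuple[str, str]] = []
    chain = [cis[0], *sps]
    for a, b in zip(chain, chain[1:]):
        ppi_edges.append((a, b))
    for tf in tfs:
        ppi_edges.append((chain[-1], tf))
    ppi_edges.append((cis[0], "DETOUR"))  # dead-end decoy off the chain
    annotation.append(GeneAnnotation("DETOUR", "chr4", 5_000_000, 5_010_000, "+"))
    ppi = PpiNetwork(ppi_edges)

    chromhmm = {
        f"cell{c}": _chromhmm_track(s, trans_positions, active=(c < 7))
        for c in range(10)
    }

    qtl_records = [
        QtlRecord(s.snp_id, s.snp_chrom, s.snp_pos, s.allele_freq,
                  cpg, "cpg", s.trans_chrom, trans_positions[cpg][1])
        for cpg in cpgs
    ]

    expressed = {g.gene_id for g in annotation}

    true_net_nodes: list[str] = []
    hotspot = Hotspot(s.snp_id, "meqtl", frozenset(cpgs), s.snp_chrom,
                      s.snp_pos, s.allele_freq)
    locus_set = LocusSet(
        snp=s.snp_id,
        cis_genes=frozenset(cis),
        trans_entities=frozenset(cpgs),
        cpg_genes=frozenset(cpg_genes),
        tfs=frozenset(tfs),
        sp_genes=frozenset(sps),
        qtl_type="meqtl",
    )
    true_net_nodes = list(locus_set.node_order)
    true_net = UndirectedNetwork(true_net_nodes)
    true_net.add_edge(s.snp_id, cis[0])
    for a, b in zip(chain, chain[1:]):
        true_net.add_edge(a, b)
    for tf in tfs:
        true_net.add_edge(chain[-1], tf)
        for cpg in cpgs:
            true_net.add_edge(tf, cpg)
    for cpg, tg in zip(cpgs, cpg_genes):
        true_net.add_edge(cpg, tg)

    return LocusFixture(
        annotation=annotation, tfbs=tfbs, chromhmm=chromhmm, ppi=ppi,
        qtl_records=qtl_records, trans_positions=trans_positions,
        expressed=expressed, locus_set=locus_set, true_network=true_net,
        hotspot=hotspot,
    )


def _chromhmm_track(
    spec: FixtureSpec,
    trans_positions: dict[str, tuple[str, int]],
    active: bool,
) -> list[tuple[str, int, int, str]]:
    """200-bp state windows around each CpG; TssA in 'active' cell lines."""
    track = []
    for chrom, pos in trans_positions.values():
        w0 = (pos // 200) * 200
        state = "TssA" if active else "Quies"
        track.append((chrom, w0, w0 + 200, state))
    return track


# ---------------------------------------------------------------------------
# Reference data for prior construction
# ---------------------------------------------------------------------------

def make_prior_reference(
    fixture: LocusFixture,
    spec: FixtureSpec,
    fraction: float = 1.0,
):
    """Reference eQTL table and expression so priors land on true edges.

    ``fraction`` controls which share of the true network's SNP-gene and
    gene-gene edges receive supporting evidence (the remaining true edges are
    left at the pseudo-prior). Returns (eqtl_table, reference_expression,
    gene_gene_pairs).
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(spec.seed + 1)
    ls = fixture.locus_set
    truth = fixture.true_network

    snp_edges = [e for e in truth.edges
                 if ls.snp in e and (set(e) - {ls.snp}) <= ls.cis_genes]
    gene_roles = ls.cis_genes | ls.tfs | ls.sp_genes
    gene_edges = [e for e in truth.edges if set(e) <= gene_roles]
    keep_snp = set(_subset(snp_edges, fraction, rng))
    keep_gene = set(_subset(gene_edges, fraction, rng))

    # eQTL table: strong p-values for supported SNP-cis edges, null filler
    rows = []
    for a, b in sorted(keep_snp):
        gene = b if a == ls.snp else a
        rows.append((ls.snp, gene, 10.0 ** rng.uniform(-12, -8)))
    for g in sorted(ls.cis_genes):
        if not any(g in e for e in keep_snp):
            rows.append((ls.snp, g, rng.uniform(0.2, 1.0)))
    for k in range(500):
        rows.append((f"rsNULL{k}", f"GNULL{k}", rng.uniform()))
    eqtl = pd.DataFrame(rows, columns=["snp", "gene", "p"])

    # reference expression: correlated pairs for supported gene-gene edges
    genes = sorted(gene_roles) + [f"GNULL{k}" for k in range(60)]
    n = spec.n_ref_samples
    x = rng.standard_normal((n, len(genes)))
    gi = {g: k for k, g in enumerate(genes)}
    for a, b in sorted(keep_gene):
        shared = rng.standard_normal(n)
        x[:, gi[a]] = shared + spec.noise_sd * rng.standard_normal(n)
        x[:, gi[b]] = shared + spec.noise_sd * rng.standard_normal(n)
    expr = pd.DataFrame(x, columns=genes,
                        index=[f"ref{i}" for i in range(n)])

    pairs = sorted(keep_gene)
    # null PPI pairs among filler genes give the lfdr its null component
    pairs += [(f"GNULL{2 * k}", f"GNULL{2 * k + 1}") for k in range(30)]
    return eqtl, expr, pairs


def _subset(items, fraction: float, rng: np.random.Generator) -> list:
    items = sorted(items)
    k = int(round(fraction * len(items)))
    if k == 0:
        return []
    idx = rng.choice(len(items), size=k, replace=False)
    return [items[i] for i in sorted(idx)]


# ---------------------------------------------------------------------------
# Cohort data and benchmark priors
# ---------------------------------------------------------------------------

def make_cohort_pair(
    ls: LocusSet,
    g_true: UndirectedNetwork,
    spec: FixtureSpec,
) -> tuple[OmicsDataset, OmicsDataset]:
    """Two independent cohorts drawn from the same graph distribution.

    Both datasets share the generating graph but have independent samples and
    their own SNP discretisation, emulating two-cohort replication.
    """
    root = np.random.SeedSequence(spec.seed)
    out = []
    for ss in root.spawn(2):
        rng = np.random.default_rng(ss)
        data = simulate_gaussian(g_true, spec.n_samples, rng)
        snp = data.nodes[0]
        data.values[snp] = discretize_snp(
            data.values[snp].to_numpy(), hwe_dosage_freqs(spec.allele_freq)
        )
        data.kinds[snp] = "dosage"
        out.append(data)
    return out[0], out[1]


def make_benchmark_prior(
    n_nodes: int = 25,
    n_prior_pairs: int = 50,
    rng: np.random.Generator | int | None = None,
    prior_range: tuple[float, float] = (0.5, 0.99),
) -> PriorMatrix:
    """Random hotspot-like prior matrix for the simulation benchmark.

    The first node is the SNP; ``n_prior_pairs`` random pairs receive priors
    drawn uniformly from ``prior_range`` (SNP-gene class for SNP pairs,
    gene-gene otherwise); everything else stays at the pseudo-prior.
    """
    rng = np.random.default_rng(rng)
    nodes = ["SNP"] + [f"G{i:02d}" for i in range(1, n_nodes)]
    pairs = [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1 :]]
    idx = rng.choice(len(pairs), size=min(n_prior_pairs, len(pairs)),
                     replace=False)
    P = PriorMatrix(nodes)
    for k in sorted(idx):
        a, b = pairs[k]
        cls = "snp_gene" if a == "SNP" else "gene_gene"
        P.set_prior(a, b, rng.uniform(*prior_range), cls)
    return P
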