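"""Trans-QTL hotspot extraction and locus-set construction.

A *hotspot* is a genetic locus associated with at least ``min_trans`` molecular
traits (gene expression or CpG methylation) on other chromosomes. For each
hotspot we assemble a *locus set*: the role-tagged node universe over which
networks are inferred — the sentinel SNP, genes in cis of the SNP, the trans
entities themselves, genes neighbouring trans CpGs, transcription factors with
binding sites near the trans entities, and genes on propagation-weighted
shortest PPI paths bridging the cis and trans sides.

Coordinates are handled 0-based half-open internally (BED native); 1-based
inputs are converted at the I/O boundary.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

#: Half-width of the cis window around the sentinel SNP (1 Mbp total window).
CIS_WINDOW = 500_000
#: Maximum gap between a TF binding site and a CpG position.
CPG_TFBS_WINDOW = 50
#: Promoter window around the TSS: upstream / downstream in transcript direction.
PROMOTER_UPSTREAM = 2000
PROMOTER_DOWNSTREAM = 1000

#: Cell-label terms marking blood-related samples in TFBS resources.
BLOOD_CELL_TERMS = (
    "amlpz12_leukemic", "aplpz74_leukemia", "bcell", "bjab", "bl41", "blood",
    "lcl", "erythroid", "gm", "hbp", "k562", "kasumi", "lymphoblastoid",
    "mm1s", "p493", "plasma", "sem", "thp1", "u937",
)


@dataclass(frozen=True)
class QtlRecord:
    """One trans-QTL association between a SNP and a gene or CpG target."""

    snp_id: str
    snp_chrom: str
    snp_pos: int
    maf: float
    target_id: str
    target_type: str  # "gene" or "cpg"
    target_chrom: str
    target_pos: int

    def __post_init__(self):
        if self.target_type not in ("gene", "cpg"):
            raise ValueError(f"target_type must be gene|cpg, got {self.target_type!r}")


@dataclass
class Hotspot:
    sentinel_snp: str
    qtl_type: str  # "meqtl" or "eqtl"
    trans_targets: frozenset[str]
    snp_chrom: str
    snp_pos: int
    maf: float

    @property
    def n_trans(self) -> int:
        return len(self.trans_targets)


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene interval with strand-derived TSS (0-based half-open)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    def promoter(self) -> tuple[int, int]:
        """Promoter window [start, end) in genomic coordinates, strand-aware."""
        if self.strand == "+":
            return (self.tss - PROMOTER_UPSTREAM, self.tss + PROMOTER_DOWNSTREAM + 1)
        return (self.tss - PROMOTER_DOWNSTREAM, self.tss + PROMOTER_UPSTREAM + 1)


@dataclass(frozen=True)
class TfbsInterval:
    tf_id: str
    chrom: str
    start: int
    end: int
    cell_label: str = ""
    score: float | None = None

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"TFBS {self.tf_id}: start must be < end")


class PpiNetwork:
    """Undirected protein–protein interaction edge list (no self loops)."""

    def __init__(self, edges: Iterable[tuple[str, str]] = ()):
        self.graph = nx.Graph()
        for a, b in edges:
            if a != b:
                self.graph.add_edge(a, b)

    def restrict(self, genes: set[str]) -> "PpiNetwork":
        sub = PpiNetwork()
        sub.graph = self.graph.subgraph(genes).copy()
        return sub

    @property
    def genes(self) -> set[str]:
        return set(self.graph.nodes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.graph


ROLE_ORDER = ("snp", "cis", "trans", "cpg_gene", "tf", "sp")


@dataclass
class LocusSet:
    """Role-tagged node universe for one hotspot.

    Role sets may overlap in identifiers; ``node_order`` lists every distinct
    node exactly once, first by role (SNP, cis, trans, CpG-gene, TF,
    shortest-path gene), then lexicographically within each role.
    """

    snp: str
    cis_genes: frozenset[str]
    trans_entities: frozenset[str]
    cpg_genes: frozenset[str] = frozenset()
    tfs: frozenset[str] = frozenset()
    sp_genes: frozenset[str] = frozenset()
    qtl_type: str = "meqtl"
    valid: bool = True
    node_order: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if not self.node_order:
            self.node_order = self._build_order()

    def _build_order(self) -> tuple[str, ...]:
        roles = (
            (self.snp,),
            sorted(self.cis_genes),
            sorted(self.trans_entities),
            sorted(self.cpg_genes),
            sorted(self.tfs),
            sorted(self.sp_genes),
        )
        order: list[str] = []
        seen: set[str] = set()
        for grp in roles:
            for n in grp:
                if n not in seen:
                    seen.add(n)
                    order.append(n)
        return tuple(order)

    @property
    def n_nodes(self) -> int:
        return len(self.node_order)

    def role_of(self, node: str) -> str:
        """First role (in role order) a node belongs to."""
        if node == self.snp:
            return "snp"
        for role, members in (
            ("cis", self.cis_genes), ("trans", self.trans_entities),
            ("cpg_gene", self.cpg_genes), ("tf", self.tfs), ("sp", self.sp_genes),
        ):
            if node in members:
                return role
        raise KeyError(node)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"node": self.node_order, "role": [self.role_of(n) for n in self.node_order]}
        )


# ---------------------------------------------------------------------------
# Hotspot extraction
# ---------------------------------------------------------------------------

def extract_hotspots(
    records: Sequence[QtlRecord],
    min_trans: int = 5,
    ld_clusters: Mapping[str, str] | None = None,
    mode: str = "prune",
) -> list[Hotspot]:
    """Group trans-QTL records by SNP and retain loci with enough trans targets.

    LD clusters (computed upstream) collapse correlated SNPs: ``mode="prune"``
    keeps a single representative SNP per cluster — highest MAF first, then
    largest trans-target count, then lexicographic SNP id; ``mode="merge"``
    unions the trans targets of clustered SNPs and keeps the highest-MAF SNP
    as sentinel.
    """
    if mode not in ("prune", "merge"):
        raise ValueError(f"mode must be prune|merge, got {mode!r}")
    for idx, r in enumerate(records):
        if not (0.0 <= r.maf <= 0.5):
            raise ValueError(f"record {idx}: malformed MAF {r.maf}")

    by_snp: dict[str, list[QtlRecord]] = {}
    for r in records:
        by_snp.setdefault(r.snp_id, []).append(r)

    hotspots: dict[str, Hotspot] = {}
    for snp, recs in by_snp.items():
        trans = frozenset(r.target_id for r in recs if r.snp_chrom != r.target_chrom)
        if not trans:
            continue
        ttypes = {r.target_type for r in recs}
        qtl_type = "meqtl" if "cpg" in ttypes else "eqtl"
        r0 = recs[0]
        hotspots[snp] = Hotspot(snp, qtl_type, trans, r0.snp_chrom, r0.snp_pos, r0.maf)

    if ld_clusters is not None:
        by_cluster: dict[str, list[Hotspot]] = {}
        for snp, h in hotspots.items():
            by_cluster.setdefault(ld_clusters.get(snp, snp), []).append(h)
        collapsed = []
        for members in by_cluster.values():
            members.sort(key=lambda h: (-h.maf, -h.n_trans, h.sentinel_snp))
            rep = members[0]
            if mode == "merge":
                targets = frozenset().union(*(h.trans_targets for h in members))
                rep = Hotspot(rep.sentinel_snp, rep.qtl_type, targets,
                              rep.snp_chrom, rep.snp_pos, rep.maf)
            collapsed.append(rep)
        hotspots = {h.sentinel_snp: h for h in collapsed}

    kept = [h for h in hotspots.values() if h.n_trans >= min_trans]
    kept.sort(key=lambda h: h.sentinel_snp)
    return kept


# ---------------------------------------------------------------------------
# Locus sets
# ---------------------------------------------------------------------------

def _overlaps(start: int, end: int, lo: int, hi: int) -> bool:
    """Half-open interval [start, end) intersects closed window [lo, hi]."""
    return start <= hi and end - 1 >= lo


def cis_genes_for(h: Hotspot, annotation: Sequence[GeneAnnotation]) -> set[str]:
    lo, hi = h.snp_pos - CIS_WINDOW, h.snp_pos + CIS_WINDOW
    return {
        g.gene_id for g in annotation
        if g.chrom == h.snp_chrom and _overlaps(g.start, g.end, lo, hi)
    }


def cpg_neighbor_genes(
    cpg_positions: Mapping[str, tuple[str, int]],
    annotation: Sequence[GeneAnnotation],
) -> dict[str, set[str]]:
    """Previous, next, and overlapping gene for each CpG (chrom, pos)."""
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in annotation:
        by_chrom.setdefault(g.chrom, []).append(g)
    for genes in by_chrom.values():
        genes.sort(key=lambda g: (g.start, g.end, g.gene_id))

    out: dict[str, set[str]] = {}
    for cpg, (chrom, pos) in cpg_positions.items():
        genes = by_chrom.get(chrom, [])
        hits: set[str] = set()
        prev_g, next_g = None, None
        for g in genes:
            if g.start <= pos < g.end:
                hits.add(g.gene_id)
            elif g.end <= pos:
                if prev_g is None or g.end > prev_g.end:
                    prev_g = g
            elif g.start > pos and next_g is None:
                next_g = g
        if prev_g is not None:
            hits.add(prev_g.gene_id)
        if next_g is not None:
            hits.add(next_g.gene_id)
        out[cpg] = hits
    return out


def filter_tfbs_cells(
    tfbs: Sequence[TfbsInterval], terms: Sequence[str] = BLOOD_CELL_TERMS
) -> list[TfbsInterval]:
    """Keep intervals whose cell label contains at least one term
    (case-insensitive substring match). An empty term list keeps nothing."""
    lowered = [t.lower() for t in terms]
    return [
        iv for iv in tfbs
        if any(t in iv.cell_label.lower() for t in lowered)
    ]


def _gap_to_window(start: int, end: int, point: int) -> int:
    """Distance between half-open interval [start, end) and a point (0 if inside)."""
    if start <= point < end:
        return 0
    return start - point if point < start else point - (end - 1)


def select_tfs(
    trans_entities: Mapping[str, tuple[str, int, str]],
    tfbs: Sequence[TfbsInterval],
    annotation: Mapping[str, GeneAnnotation],
) -> set[str]:
    """TFs with a binding site near a trans entity.

    ``trans_entities`` maps id -> (chrom, position, kind) with kind "cpg" or
    "gene". CpGs match binding sites within 50 bp of the CpG position; genes
    match binding sites intersecting the promoter window (2000 bp upstream,
    1000 bp downstream of the TSS, strand-aware).
    """
    out: set[str] = set()
    for iv in tfbs:
        for tid, (chrom, pos, kind) in trans_entities.items():
            if iv.chrom != chrom:
                continue
            if kind == "cpg":
                if _gap_to_window(iv.start, iv.end, pos) <= CPG_TFBS_WINDOW:
                    out.add(iv.tf_id)
                    break
            else:
                ann = annotation.get(tid)
                if ann is None:
                    continue
                lo, hi = ann.promoter()
                if _overlaps(iv.start, iv.end, lo, hi - 1):
                    out.add(iv.tf_id)
                    break
    return out


def tf_target_pairs(
    trans_entities: Mapping[str, tuple[str, int, str]],
    tfbs: Sequence[TfbsInterval],
    annotation: Mapping[str, GeneAnnotation],
) -> set[tuple[str, str]]:
    """(TF, trans-entity) pairs satisfying the binding-window criteria."""
    pairs: set[tuple[str, str]] = set()
    for iv in tfbs:
        for tid, (chrom, pos, kind) in trans_entities.items():
            if iv.chrom != chrom or iv.tf_id == tid:
                continue
            if kind == "cpg":
                if _gap_to_window(iv.start, iv.end, pos) <= CPG_TFBS_WINDOW:
                    pairs.add((iv.tf_id, tid))
            else:
                ann = annotation.get(tid)
                if ann is None:
                    continue
                lo, hi = ann.promoter()
                if _overlaps(iv.start, iv.end, lo, hi - 1):
                    pairs.add((iv.tf_id, tid))
    return pairs


# ---------------------------------------------------------------------------
# Network propagation & shortest-path genes
# ---------------------------------------------------------------------------

def propagate_node_scores(
    ppi_aug: nx.Graph,
    seeds: set[str],
    restart: float = 0.5,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> dict[str, float]:
    """Random-walk-with-restart node scores from uniform seed mass.

    Solves the fixed point ``s = restart * e + (1 - restart) * W s`` with
    column-normalised adjacency W and uniform restart vector e over the seeds,
    by power iteration. Scores are nonnegative and sum to 1.
    """
    missing = seeds - set(ppi_aug.nodes)
    if missing:
        raise KeyError(f"seed nodes absent from graph: {sorted(missing)}")
    if not seeds:
        raise ValueError("empty seed set")
    nodes = sorted(ppi_aug.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    A = nx.to_numpy_array(ppi_aug, nodelist=nodes)
    deg = A.sum(axis=0)
    # dangling nodes restart deterministically: column stays zero, mass re-injected
    with np.errstate(divide="ignore", invalid="ignore"):
        W = np.where(deg > 0, A / deg, 0.0)
    e = np.zeros(n)
    for s in seeds:
        e[idx[s]] = 1.0 / len(seeds)
    s_vec = e.copy()
    for _ in range(max_iter):
        nxt = restart * e + (1.0 - restart) * (W @ s_vec)
        nxt /= nxt.sum()
        if np.abs(nxt - s_vec).max() < tol:
            s_vec = nxt
            break
        s_vec = nxt
    return {nodes[i]: float(s_vec[i]) for i in range(n)}


def _lex_dijkstra(
    g: nx.Graph, cost: Mapping[str, float], source: str, target: str
) -> list[str] | None:
    """Minimum interior-node-cost path, ties broken by lexicographic node sequence.

    Path cost = sum of node costs over *interior* nodes (endpoints excluded).
    """
    # heap entries: (cost, path-as-tuple); first finalisation wins.
    best: dict[str, tuple[float, tuple[str, ...]]] = {}
    heap: list[tuple[float, tuple[str, ...]]] = [(0.0, (source,))]
    while heap:
        c, path = heapq.heappop(heap)
        node = path[-1]
        if node in best and (best[node][0] < c - 1e-15 or
                             (abs(best[node][0] - c) <= 1e-15 and best[node][1] <= path)):
            continue
        best[node] = (c, path)
        if node == target:
            return list(path)
        for nb in g.neighbors(node):
            if nb in path:
                continue
            step = 0.0 if nb == target else cost.get(nb, 0.0)
            heapq.heappush(heap, (c + step, path + (nb,)))
    return None


def shortest_path_genes(
    ppi_aug: nx.Graph,
    scores: Mapping[str, float],
    trans_entities: Iterable[str],
    cis_genes: Iterable[str],
) -> set[str]:
    """Interior genes of minimum node-cost paths between trans entities and cis genes.

    Node scores PS are converted to nonnegative costs ``W(v) = max(PS) - PS(v)``
    (order-equivalent to weighting by -PS, but Dijkstra-safe); the cost of a
    path counts interior nodes only, so directly adjacent pairs cost zero. One
    minimum-cost path is taken per pair, ties broken by lexicographic node
    sequence; disconnected pairs are skipped.
    """
    if not scores:
        return set()
    mx = max(scores.values())
    cost = {n: mx - scores.get(n, 0.0) for n in ppi_aug.nodes}
    trans = [t for t in sorted(set(trans_entities)) if t in ppi_aug]
    cis = [c for c in sorted(set(cis_genes)) if c in ppi_aug]
    interior: set[str] = set()
    for t in trans:
        for c in cis:
            if t == c:
                continue
            path = _lex_dijkstra(ppi_aug, cost, t, c)
            if path is not None:
                interior.update(path[1:-1])
    return interior


# ---------------------------------------------------------------------------
# Locus-set assembly
# ---------------------------------------------------------------------------

def build_locus_set(
    h: Hotspot,
    annotation: Sequence[GeneAnnotation],
    tfbs: Sequence[TfbsInterval],
    ppi: PpiNetwork,
    expressed: set[str] | None = None,
    trans_positions: Mapping[str, tuple[str, int]] | None = None,
    restart: float = 0.5,
) -> LocusSet:
    """Assemble the role-tagged locus set for one hotspot.

    ``trans_positions`` maps each trans entity to its (chrom, position); for
    meQTL hotspots these are CpG coordinates, for eQTL hotspots gene TSSs are
    taken from the annotation when missing. Hotspots whose cis genes all lack
    expression data are flagged invalid (``valid=False``).
    """
    ann_by_id = {g.gene_id: g for g in annotation}
    cis = cis_genes_for(h, annotation)
    if expressed is not None:
        cis &= expressed
    if not cis:
        return LocusSet(h.sentinel_snp, frozenset(), h.trans_targets,
                        qtl_type=h.qtl_type, valid=False)

    kind = "cpg" if h.qtl_type == "meqtl" else "gene"
    tpos: dict[str, tuple[str, int, str]] = {}
    for t in h.trans_targets:
        if trans_positions is not None and t in trans_positions:
            chrom, pos = trans_positions[t]
        elif t in ann_by_id:
            chrom, pos = ann_by_id[t].chrom, ann_by_id[t].tss
        else:
            continue
        tpos[t] = (chrom, pos, kind)

    cpg_genes: set[str] = set()
    if h.qtl_type == "meqtl":
        cpg_pos = {t: (c, p) for t, (c, p, _) in tpos.items()}
        for genes in cpg_neighbor_genes(cpg_pos, annotation).values():
            cpg_genes |= genes
        if expressed is not None:
            cpg_genes &= expressed

    tfs = select_tfs(tpos, tfbs, ann_by_id)
    if expressed is not None:
        tfs &= expressed

    # propagation graph: expressed PPI + trans CpGs attached to their TFs
    g = (ppi.restrict(expressed) if expressed is not None else ppi).graph.copy()
    if h.qtl_type == "meqtl":
        for tf, target in tf_target_pairs(tpos, tfbs, ann_by_id):
            if tf in g:
                g.add_edge(tf, target)
    seeds = (set(tpos) | cis) & set(g.nodes)
    sp: set[str] = set()
    if seeds and (set(tpos) & set(g.nodes)) and (cis & set(g.nodes)):
        scores = propagate_node_scores(g, seeds, restart=restart)
        sp = shortest_path_genes(g, scores, set(tpos), cis)
        # interior nodes already carrying a role are not re-added as SP genes
        sp -= set(tpos) | cis | tfs | {h.sentinel_snp}

    return LocusSet(
        snp=h.sentinel_snp,
        cis_genes=frozenset(cis),
        trans_entities=frozenset(h.trans_targets),
        cpg_genes=frozenset(cpg_genes) if h.qtl_type == "meqtl" else frozenset(),
        tfs=frozenset(tfs),
        sp_genes=frozenset(sp),
        qtl_type=h.qtl_type,
    )


# ---------------------------------------------------------------------------
# Predicted-TFBS post-filter
# ---------------------------------------------------------------------------

def filter_predicted_tfbs(
    scored: Sequence[TfbsInterval],
    score_cutoff: float = 0.999,
    width_quantile: float = 95.0,
) -> list[TfbsInterval]:
    """Post-filter model-predicted binding sites.

    Keeps intervals scoring at least ``score_cutoff``, merges overlapping
    intervals per TF, then drops merged intervals whose width is not strictly
    below the 95th percentile of all merged widths (linear-interpolation
    percentile, numpy default).
    """
    kept = [iv for iv in scored if iv.score is not None and iv.score >= score_cutoff]
    merged: list[TfbsInterval] = []
    by_tf: dict[tuple[str, str], list[TfbsInterval]] = {}
    for iv in kept:
        by_tf.setdefault((iv.tf_id, iv.chrom), []).append(iv)
    for (tf, chrom), ivs in sorted(by_tf.items()):
        ivs.sort(key=lambda x: (x.start, x.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:  # overlap or abut
                cur_e = max(cur_e, iv.end)
            else:
                merged.append(TfbsInterval(tf, chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        merged.append(TfbsInterval(tf, chrom, cur_s, cur_e))
    if not merged:
        return []
    widths = np.array([iv.end - iv.start for iv in merged], dtype=float)
    w95 = np.percentile(widths, width_quantile)
    return [iv for iv in merged if (iv.end - iv.start) < w95]
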