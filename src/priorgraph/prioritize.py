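"""Hotspot network prioritisation: graph score, GWAS filter, consensus merging.

The graph score S_G rewards networks in which cis genes attach to the SNP and
trans entities are reached through cis genes rather than directly from the
SNP, and penalises dense graphs:

    S_G = -log10(D_G) * [ (|G_S| - |G_S-bar|) / |Gc|
                          + (|G_T| - |G_T-bar|) / |T| ]

computed on the connected component (cluster) containing the SNP only; the
score is 0 when the SNP is absent or no cis gene lies in its cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .hotspots import LocusSet
from .network import UndirectedNetwork

logger = logging.getLogger(__name__)


@dataclass
class GraphScoreBreakdown:
    score: float
    density: float
    n_cis: int
    n_trans: int
    gs: frozenset[str]
    gs_bar: frozenset[str]
    gt: frozenset[str]
    gt_bar: frozenset[str]
    cluster_nodes: frozenset[str]


def graph_score(G: UndirectedNetwork, ls: LocusSet) -> GraphScoreBreakdown:
    """Compute the prioritisation score of an inferred hotspot network.

    Within the SNP's connected component: G_S are cis genes adjacent to the
    SNP or adjacent to another cis gene; G_S-bar the remaining cis genes in
    the cluster; G_T are trans entities reachable from a cis gene without
    traversing the SNP or another trans entity and not directly attached to
    the SNP; G_T-bar the trans entities adjacent to the SNP. Density uses the
    cluster's node count.
    """
    unknown = set(G.nodes) - set(ls.node_order)
    if unknown:
        raise ValueError(f"network nodes outside the locus set: {sorted(unknown)}")
    if not ls.cis_genes or not ls.trans_entities:
        raise ValueError("malformed locus set: needs cis genes and trans entities")

    g = G.to_networkx()
    # drop isolated nodes that merely pad the node order
    zero = frozenset()
    if ls.snp not in g or g.degree(ls.snp) == 0:
        return GraphScoreBreakdown(0.0, 0.0, len(ls.cis_genes), len(ls.trans_entities),
                                   zero, zero, zero, zero, zero)
    cluster = set(nx.node_connected_component(g, ls.snp))
    sub = g.subgraph(cluster)
    cis_in = ls.cis_genes & cluster
    if not cis_in:
        return GraphScoreBreakdown(0.0, 0.0, len(ls.cis_genes), len(ls.trans_entities),
                                   zero, zero, zero, zero, frozenset(cluster))

    gs = {
        c for c in cis_in
        if sub.has_edge(c, ls.snp)
        or any(sub.has_edge(c, other) for other in cis_in if other != c)
    }
    gs_bar = cis_in - gs

    trans_in = ls.trans_entities & cluster
    gt_bar = {t for t in trans_in if sub.has_edge(t, ls.snp)}
    gt = set()
    for t in trans_in - gt_bar:
        blocked = {ls.snp} | (trans_in - {t})
        allowed = cluster - blocked
        sub_t = sub.subgraph(allowed)
        if t not in sub_t:
            continue
        comp = nx.node_connected_component(sub_t, t)
        if comp & cis_in:
            gt.add(t)

    n_cluster = len(cluster)
    density = sub.number_of_edges() / (n_cluster * (n_cluster - 1) / 2)
    score = -np.log10(density) * (
        (len(gs) - len(gs_bar)) / len(ls.cis_genes)
        + (len(gt) - len(gt_bar)) / len(ls.trans_entities)
    )
    return GraphScoreBreakdown(
        score=float(score), density=float(density),
        n_cis=len(ls.cis_genes), n_trans=len(ls.trans_entities),
        gs=frozenset(gs), gs_bar=frozenset(gs_bar),
        gt=frozenset(gt), gt_bar=frozenset(gt_bar),
        cluster_nodes=frozenset(cluster),
    )


def gwas_filter(
    hotspot_snp: str,
    proxies: Mapping[str, Sequence[str]],
    catalog: set[str],
) -> bool:
    """True iff the hotspot SNP or any high-LD proxy/alias is in the catalog.

    ``proxies`` maps a hotspot SNP to its proxy rsIDs (R^2 > 0.8) and aliases,
    precomputed upstream. A SNP missing from the proxy table only matches
    directly (with a warning).
    """
    if hotspot_snp in catalog:
        return True
    if hotspot_snp not in proxies:
        logger.warning("hotspot SNP %s missing from proxy table", hotspot_snp)
        return False
    return any(p in catalog for p in proxies[hotspot_snp])


def merge_networks(net_a: UndirectedNetwork, net_b: UndirectedNetwork
                   ) -> UndirectedNetwork:
    """Consensus graph: edge intersection; only endpoint nodes are kept."""
    edges = net_a.edges & net_b.edges
    nodes = sorted({n for e in edges for n in e})
    return UndirectedNetwork(nodes, edges)


def rank_networks(
    entries: Sequence[tuple[str, GraphScoreBreakdown, int, int]]
) -> list[tuple[str, GraphScoreBreakdown, int, int]]:
    """Order hotspot networks: score desc, then edges asc, nodes asc, id."""
    return sorted(entries, key=lambda e: (-e[1].score, e[2], e[3], e[0]))
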