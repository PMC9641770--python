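"""Hotspot extraction, locus-set construction, propagation, path genes."""

import itertools

import networkx as nx
import numpy as np
import pytest

from priorgraph import (
    GeneAnnotation,
    Hotspot,
    PpiNetwork,
    QtlRecord,
    TfbsInterval,
    build_locus_set,
    extract_hotspots,
    filter_predicted_tfbs,
    filter_tfbs_cells,
    propagate_node_scores,
    select_tfs,
    shortest_path_genes,
)
from priorgraph.hotspots import BLOOD_CELL_TERMS, cis_genes_for


def _rec(snp, target, snp_chrom="chr1", t_chrom="chr2", maf=0.3, ttype="cpg"):
    return QtlRecord(snp, snp_chrom, 1_000_000, maf, target, ttype, t_chrom, 500_000)


class TestExtractHotspots:
    def test_min_trans_threshold(self):
        records = [_rec("rs1", f"cg{i}") for i in range(4)]
        assert extract_hotspots(records, min_trans=5) == []
        assert len(extract_hotspots(records, min_trans=4)) == 1

    def test_same_chromosome_targets_are_not_trans(self):
        records = [_rec("rs1", f"g{i}", t_chrom="chr1") for i in range(6)]
        assert extract_hotspots(records, min_trans=1) == []

    def test_malformed_maf_rejected_with_index(self):
        records = [_rec("rs1", "cg1"), _rec("rs2", "cg2", maf=0.7)]
        with pytest.raises(ValueError, match="record 1"):
            extract_hotspots(records)

    def test_empty_input(self):
        assert extract_hotspots([]) == []

    def test_prune_representative_lexicographic_key(self):
        # MAFs 0.1/0.3/0.3 with trans counts 9/6/8: the MAF-0.3 SNP with 8
        # targets wins (MAF first, then trans count)
        records = []
        for snp, maf, k in [("rsA", 0.1, 9), ("rsB", 0.3, 6), ("rsC", 0.3, 8)]:
            records += [_rec(snp, f"{snp}_cg{i}", maf=maf) for i in range(k)]
        clusters = {"rsA": "c1", "rsB": "c1", "rsC": "c1"}
        hs = extract_hotspots(records, min_trans=5, ld_clusters=clusters,
                              mode="prune")
        assert [h.sentinel_snp for h in hs] == ["rsC"]
        assert hs[0].n_trans == 8

    def test_prune_one_hotspot_per_cluster(self, rng):
        records, clusters = [], {}
        for s in range(12):
            snp = f"rs{s:02d}"
            clusters[snp] = f"c{s % 4}"
            for i in range(int(rng.integers(5, 10))):
                records.append(_rec(snp, f"{snp}cg{i}", maf=float(rng.uniform(0.05, 0.5))))
        hs = extract_hotspots(records, ld_clusters=clusters, mode="prune")
        assert len(hs) == 4
        assert len({clusters[h.sentinel_snp] for h in hs}) == 4

    def test_merge_unions_targets_keeps_max_maf_sentinel(self):
        records = [_rec("rsA", f"a{i}", maf=0.2) for i in range(5)]
        records += [_rec("rsB", f"b{i}", maf=0.4) for i in range(5)]
        records += [_rec("rsB", "a0", maf=0.4)]
        hs = extract_hotspots(records, ld_clusters={"rsA": "c", "rsB": "c"},
                              mode="merge")
        assert len(hs) == 1
        assert hs[0].sentinel_snp == "rsB"
        assert hs[0].n_trans == 10  # union of {a0..a4} and {b0..b4, a0}


class TestLocusSet:
    def test_cis_window_overlap(self):
        h = Hotspot("rs1", "meqtl", frozenset(["cg1"] * 1), "chr1", 10_000_000, 0.3)
        ann = [
            GeneAnnotation("IN", "chr1", 9_600_000, 9_700_000),
            GeneAnnotation("OUT", "chr1", 10_500_001, 10_600_000),
            GeneAnnotation("EDGE", "chr1", 10_400_000, 10_500_001),
        ]
        cis = cis_genes_for(h, ann)
        assert "IN" in cis and "EDGE" in cis and "OUT" not in cis

    def test_eqtl_hotspot_has_no_cpg_genes(self, locus_fixture):
        fx = locus_fixture
        h = Hotspot("rs1", "eqtl", frozenset(["TG0", "TG1"]), "chr1",
                    10_000_000, 0.3)
        ls = build_locus_set(h, fx.annotation, fx.tfbs, fx.ppi, fx.expressed)
        assert ls.cpg_genes == frozenset()

    def test_hotspot_without_expressed_cis_genes_is_invalid(self, locus_fixture):
        fx = locus_fixture
        expressed = fx.expressed - {"CIS0", "CIS1", "CIS2"}
        ls = build_locus_set(fx.hotspot, fx.annotation, fx.tfbs, fx.ppi,
                             expressed, fx.trans_positions)
        assert not ls.valid

    def test_planted_roles_recovered(self, locus_fixture):
        fx = locus_fixture
        ls = build_locus_set(fx.hotspot, fx.annotation, fx.tfbs, fx.ppi,
                             fx.expressed, fx.trans_positions)
        assert ls.valid
        assert ls.cis_genes == frozenset({"CIS0", "CIS1", "CIS2"})
        assert ls.tfs == frozenset({"TF0", "TF1"})
        assert ls.cpg_genes == frozenset({f"TG{i}" for i in range(5)})
        assert ls.sp_genes == frozenset({"SP0"})

    def test_node_order_deterministic_and_unique(self, locus_fixture):
        fx = locus_fixture
        ls = build_locus_set(fx.hotspot, fx.annotation, fx.tfbs, fx.ppi,
                             fx.expressed, fx.trans_positions)
        assert len(set(ls.node_order)) == len(ls.node_order)
        assert ls.node_order[0] == "rs1"
        ls2 = build_locus_set(fx.hotspot, fx.annotation, fx.tfbs, fx.ppi,
                              fx.expressed, fx.trans_positions)
        assert ls.node_order == ls2.node_order


class TestSelectTfs:
    def test_cpg_window_boundary(self):
        ann = {}
        # CpG at 1000; TFBS [1040, 1060): gap 40 <= 50 -> selected
        tfbs = [TfbsInterval("TF1", "chr2", 1040, 1060)]
        sel = select_tfs({"cg1": ("chr2", 1000, "cpg")}, tfbs, ann)
        assert sel == {"TF1"}
        # entirely > 50 bp away
        tfbs = [TfbsInterval("TF1", "chr2", 1051, 1060)]
        assert select_tfs({"cg1": ("chr2", 1000, "cpg")}, tfbs, ann) == set()

    def test_promoter_window_strand_flip(self):
        # minus-strand gene: promoter covers [tss-1000, tss+2000] genomically
        g = GeneAnnotation("GENE", "chr2", 5_000, 10_000, "-")
        assert g.tss == 9_999
        trans = {"GENE": ("chr2", g.tss, "gene")}
        hit = TfbsInterval("TFa", "chr2", 11_000, 11_100)  # tss+1001..: inside up-window
        miss = TfbsInterval("TFb", "chr2", 12_100, 12_200)  # beyond tss+2000
        sel = select_tfs(trans, [hit, miss], {"GENE": g})
        assert sel == {"TFa"}

    def test_empty_tfbs(self):
        assert select_tfs({"cg1": ("chr2", 10, "cpg")}, [], {}) == set()


class TestFilterTfbsCells:
    def test_substring_case_insensitive(self):
        iv = TfbsInterval("TF1", "chr1", 0, 10, cell_label="GM12878")
        assert filter_tfbs_cells([iv], ["gm"]) == [iv]

    def test_non_blood_label_dropped(self):
        iv = TfbsInterval("TF1", "chr1", 0, 10, cell_label="HeLa-S3")
        assert filter_tfbs_cells([iv], BLOOD_CELL_TERMS) == []

    def test_empty_terms_keep_nothing(self):
        iv = TfbsInterval("TF1", "chr1", 0, 10, cell_label="blood")
        assert filter_tfbs_cells([iv], []) == []


class TestPropagation:
    def test_single_node(self):
        g = nx.Graph()
        g.add_node("a")
        assert propagate_node_scores(g, {"a"}) == {"a": 1.0}

    def test_path_graph_matches_linear_system(self):
        g = nx.path_graph(["A", "B", "C"])
        ps = propagate_node_scores(g, {"A"}, restart=0.5)
        # exact solve of s = 0.5 e + 0.5 W s for the 3-node path
        nodes = ["A", "B", "C"]
        W = np.array([[0, 0.5, 0], [1, 0, 1], [0, 0.5, 0]], dtype=float)
        e = np.array([1.0, 0, 0])
        s = np.linalg.solve(np.eye(3) - 0.5 * W, 0.5 * e)
        s /= s.sum()
        for n, v in zip(nodes, s):
            assert ps[n] == pytest.approx(v, abs=1e-8)
        assert ps["A"] > ps["B"] > ps["C"]

    def test_scores_sum_to_one_random_graphs(self, rng):
        for _ in range(10):
            g = nx.gnp_random_graph(12, 0.3, seed=int(rng.integers(2**31)))
            g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
            seeds = {f"n{i}" for i in range(3)}
            ps = propagate_node_scores(g, seeds)
            assert sum(ps.values()) == pytest.approx(1.0, abs=1e-9)
            assert all(v >= 0 for v in ps.values())

    def test_missing_seed_raises(self):
        g = nx.path_graph(["A", "B"])
        with pytest.raises(KeyError, match="Z"):
            propagate_node_scores(g, {"A", "Z"})


def _brute_force_sp(g, cost, source, target):
    """Exhaustive minimum interior-cost path, lexicographic tie-break."""
    best = None
    for path in nx.all_simple_paths(g, source, target):
        c = sum(cost[v] for v in path[1:-1])
        key = (round(c, 12), tuple(path))
        if best is None or key < best[0]:
            best = (key, path)
    return best[1] if best else None


class TestShortestPathGenes:
    def test_adjacent_pair_contributes_nothing(self):
        g = nx.Graph([("t", "c")])
        assert shortest_path_genes(g, {"t": 0.5, "c": 0.5}, ["t"], ["c"]) == set()

    def test_higher_score_interior_preferred(self):
        g = nx.Graph([("t", "hi"), ("hi", "c"), ("t", "lo"), ("lo", "c")])
        ps = {"t": 0.3, "c": 0.3, "hi": 0.3, "lo": 0.1}
        assert shortest_path_genes(g, ps, ["t"], ["c"]) == {"hi"}

    def test_disconnected_pair_skipped(self):
        g = nx.Graph()
        g.add_nodes_from(["t", "c"])
        assert shortest_path_genes(g, {"t": 0.5, "c": 0.5}, ["t"], ["c"]) == set()

    def test_agrees_with_exhaustive_enumeration(self, rng):
        for trial in range(30):
            n = int(rng.integers(4, 9))
            g = nx.gnp_random_graph(n, 0.45, seed=int(rng.integers(2**31)))
            g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
            scores = {v: float(rng.uniform(0, 1)) for v in g.nodes}
            nodes = sorted(g.nodes)
            trans, cis = [nodes[0]], [nodes[-1]]
            got = shortest_path_genes(g, scores, trans, cis)
            mx = max(scores.values())
            cost = {v: mx - scores[v] for v in g.nodes}
            if not nx.has_path(g, trans[0], cis[0]):
                assert got == set()
                continue
            expected = set(_brute_force_sp(g, cost, trans[0], cis[0])[1:-1])
            assert got == expected


class TestFilterPredictedTfbs:
    def test_merge_overlapping(self):
        ivs = [TfbsInterval("TF", "chr1", 0, 10, score=0.9995),
               TfbsInterval("TF", "chr1", 5, 15, score=0.9995)]
        # single merged interval is below the (single-width) 95th percentile
        # check merging separately via two TFs
        out = filter_predicted_tfbs(ivs + [TfbsInterval("TF2", "chr1", 0, 100, score=1.0)])
        tf_ivs = [iv for iv in out if iv.tf_id == "TF"]
        assert [(iv.start, iv.end) for iv in tf_ivs] == [(0, 15)]

    def test_below_cutoff_dropped(self):
        ivs = [TfbsInterval("TF", "chr1", 0, 10, score=0.99)]
        assert filter_predicted_tfbs(ivs) == []

    def test_width_percentile_strict(self):
        ivs = [TfbsInterval(f"T{w}", "chr1", 0, w, score=1.0)
               for w in range(1, 21)]
        out = filter_predicted_tfbs(ivs)
        widths = {iv.end - iv.start for iv in out}
        assert 20 not in widths
        assert 19 in widths
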