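"""Readers and writers for the package's external file formats.

Conventions: BED inputs (TFBS, chromatin states) are 0-based half-open and
used as-is; TSV tables with genomic positions (QTL tables, annotation) are
1-based inclusive on disk and converted to the internal 0-based half-open
convention on read, and back on write. All tables are plain tab-separated
text with a header unless noted; lines starting with ``#`` carry metadata.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .hotspots import GeneAnnotation, LocusSet, PpiNetwork, QtlRecord, TfbsInterval
from .network import PSEUDO_PRIOR, PriorMatrix, UndirectedNetwork
from .simulate import OmicsDataset

# ---------------------------------------------------------------------------
# QTL tables
# ---------------------------------------------------------------------------

QTL_COLUMNS = ("snp_id", "snp_chrom", "snp_pos", "maf",
               "target_id", "target_type", "target_chrom", "target_pos")


def read_qtl_table(path) -> list[QtlRecord]:
    """Read a trans-QTL association TSV (1-based positions)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(QTL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"QTL table missing columns: {sorted(missing)}")
    return [
        QtlRecord(
            snp_id=str(r.snp_id), snp_chrom=str(r.snp_chrom),
            snp_pos=int(r.snp_pos) - 1, maf=float(r.maf),
            target_id=str(r.target_id), target_type=str(r.target_type),
            target_chrom=str(r.target_chrom), target_pos=int(r.target_pos) - 1,
        )
        for r in df.itertuples()
    ]


def write_qtl_table(records: Sequence[QtlRecord], path) -> None:
    df = pd.DataFrame(
        [(r.snp_id, r.snp_chrom, r.snp_pos + 1, r.maf, r.target_id,
          r.target_type, r.target_chrom, r.target_pos + 1) for r in records],
        columns=list(QTL_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene annotation (TSV or GTF)
# ---------------------------------------------------------------------------

def read_annotation_tsv(path) -> list[GeneAnnotation]:
    """Columns: gene_id, chrom, start, end, strand (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        GeneAnnotation(str(r.gene_id), str(r.chrom), int(r.start) - 1,
                       int(r.end), str(r.strand))
        for r in df.itertuples()
    ]


def write_annotation_tsv(annotation: Sequence[GeneAnnotation], path) -> None:
    df = pd.DataFrame(
        [(g.gene_id, g.chrom, g.start + 1, g.end, g.strand) for g in annotation],
        columns=["gene_id", "chrom", "start", "end", "strand"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_annotation_gtf(path) -> list[GeneAnnotation]:
    """Gene records of a GTF file (feature type ``gene``, gene_id attribute)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(
                kv.strip().split(" ", 1)
                for kv in f[8].rstrip(";").split(";")
                if " " in kv.strip()
            )
            gid = attrs.get("gene_id", "").strip('"')
            out.append(GeneAnnotation(gid, f[0], int(f[3]) - 1, int(f[4]), f[6]))
    return out


# ---------------------------------------------------------------------------
# BED: TFBS and chromatin states
# ---------------------------------------------------------------------------

def read_tfbs_bed(path) -> list[TfbsInterval]:
    """BED: chrom, start, end, tf_id[, score[, cell_label]] (no header)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("#", "track", "browser")) or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            score = None
            if len(f) > 4 and f[4] not in (".", ""):
                score = float(f[4])
            cell = f[5] if len(f) > 5 else ""
            out.append(TfbsInterval(f[3], f[0], int(f[1]), int(f[2]), cell, score))
    return out


def write_tfbs_bed(tfbs: Sequence[TfbsInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in tfbs:
            score = "." if iv.score is None else f"{iv.score:g}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.tf_id}\t{score}\t{iv.cell_label}\n")


def read_chromhmm_bed(path) -> list[tuple[str, int, int, str]]:
    """BED: chrom, start, end, state mnemonic (one file per cell line)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("#", "track")) or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            out.append((f[0], int(f[1]), int(f[2]), f[3]))
    return out


def write_chromhmm_bed(intervals: Sequence[tuple[str, int, int, str]], path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, state in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{state}\n")


def read_chromhmm_dir(directory) -> dict[str, list[tuple[str, int, int, str]]]:
    """One BED per cell line; the file stem is the cell-line name."""
    out = {}
    for p in sorted(Path(directory).glob("*.bed")):
        out[p.stem] = read_chromhmm_bed(p)
    return out


# ---------------------------------------------------------------------------
# PPI
# ---------------------------------------------------------------------------

def read_ppi_tsv(path) -> PpiNetwork:
    """Two-column TSV of gene-gene interactions (header optional)."""
    edges = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            if line.startswith("#") or not line.strip():
                continue
            a, b = line.rstrip("\n").split("\t")[:2]
            if i == 0 and {a.lower(), b.lower()} & {"gene_a", "gene_b", "protein_a"}:
                continue
            edges.append((a, b))
    return PpiNetwork(edges)


def write_ppi_tsv(ppi: PpiNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in sorted(tuple(sorted(e)) for e in ppi.graph.edges):
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# Locus sets, networks, priors, omics data
# ---------------------------------------------------------------------------

def write_locus_set(ls: LocusSet, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#qtl_type: {ls.qtl_type}\n")
        fh.write(f"#valid: {int(ls.valid)}\n")
        fh.write("node\trole\n")
        rows = [
            ("snp", [ls.snp]), ("cis", sorted(ls.cis_genes)),
            ("trans", sorted(ls.trans_entities)), ("cpg_gene", sorted(ls.cpg_genes)),
            ("tf", sorted(ls.tfs)), ("sp", sorted(ls.sp_genes)),
        ]
        for role, nodes in rows:
            for n in nodes:
                fh.write(f"{n}\t{role}\n")


def read_locus_set(path) -> LocusSet:
    qtl_type, valid = "meqtl", True
    roles: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#qtl_type:"):
                qtl_type = line.split(":", 1)[1].strip()
                continue
            if line.startswith("#valid:"):
                valid = bool(int(line.split(":", 1)[1].strip()))
                continue
            if line.startswith("#") or line.startswith("node\t") or not line.strip():
                continue
            node, role = line.rstrip("\n").split("\t")
            roles.setdefault(role, []).append(node)
    return LocusSet(
        snp=roles.get("snp", [""])[0],
        cis_genes=frozenset(roles.get("cis", ())),
        trans_entities=frozenset(roles.get("trans", ())),
        cpg_genes=frozenset(roles.get("cpg_gene", ())),
        tfs=frozenset(roles.get("tf", ())),
        sp_genes=frozenset(roles.get("sp", ())),
        qtl_type=qtl_type, valid=valid,
    )


def write_network(net: UndirectedNetwork, path) -> None:
    """Edge-list TSV; a ``#nodes:`` line preserves isolated nodes and order."""
    with open(path, "w") as fh:
        fh.write("#nodes: " + ",".join(net.nodes) + "\n")
        fh.write("node_a\tnode_b\n")
        for a, b in sorted(net.edges):
            fh.write(f"{a}\t{b}\n")


def read_network(path) -> UndirectedNetwork:
    nodes: list[str] = []
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#nodes:"):
                raw = line.split(":", 1)[1].strip()
                nodes = raw.split(",") if raw else []
                continue
            if line.startswith("#") or line.startswith("node_a\t") or not line.strip():
                continue
            a, b = line.rstrip("\n").split("\t")[:2]
            edges.append((a, b))
    if not nodes:
        nodes = sorted({n for e in edges for n in e})
    return UndirectedNetwork(nodes, edges)


def write_prior_matrix(P: PriorMatrix, path) -> None:
    """Long-format TSV (node_a, node_b, prior, class); pseudo rows omitted."""
    with open(path, "w") as fh:
        fh.write("#nodes: " + ",".join(P.nodes) + "\n")
        fh.write("node_a\tnode_b\tprior\tclass\n")
        for i, a in enumerate(P.nodes):
            for j in range(i + 1, len(P.nodes)):
                if P.values[i, j] > PSEUDO_PRIOR:
                    b = P.nodes[j]
                    fh.write(f"{a}\t{b}\t{float(P.values[i, j])!r}\t{P.classes[i, j]}\n")


def read_prior_matrix(path) -> PriorMatrix:
    nodes: list[str] = []
    rows: list[tuple[str, str, float, str]] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#nodes:"):
                nodes = line.split(":", 1)[1].strip().split(",")
                continue
            if line.startswith("#") or line.startswith("node_a\t") or not line.strip():
                continue
            a, b, v, cls = line.rstrip("\n").split("\t")
            rows.append((a, b, float(v), cls))
    if not nodes:
        nodes = sorted({n for a, b, _, _ in rows for n in (a, b)})
    P = PriorMatrix(nodes)
    for a, b, v, cls in rows:
        P.set_prior(a, b, v, cls)
    return P


def write_omics(data: OmicsDataset, path) -> None:
    """Samples x nodes TSV; a ``#dosage:`` line lists dosage columns."""
    dosage = [c for c, k in data.kinds.items() if k == "dosage"]
    with open(path, "w") as fh:
        fh.write("#dosage: " + ",".join(dosage) + "\n")
        data.values.to_csv(fh, sep="\t", index_label="sample")


def read_omics(path) -> OmicsDataset:
    dosage: list[str] = []
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#dosage:"):
            raw = first.split(":", 1)[1].strip()
            dosage = raw.split(",") if raw else []
            df = pd.read_csv(fh, sep="\t", index_col="sample")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t", index_col="sample")
    kinds = {c: ("dosage" if c in dosage else "continuous") for c in df.columns}
    return OmicsDataset(df, kinds)


def read_expression_tsv(path) -> pd.DataFrame:
    """Samples x genes expression matrix with a ``sample`` index column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression_tsv(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="sample")
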