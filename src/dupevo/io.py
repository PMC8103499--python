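"""Readers and writers for the standard file formats the pipeline speaks.

GFF3 (1-based inclusive gene models with subgenome tags), FASTA (scaffold
sequences), VCF 4.2 (genotypes with INFO MQ/DP), Bismark CX-report-style
TSVs (handled in :mod:`dupevo.methylome`), MCScanX-like collinearity text
and plain TSV tables for anchors, classes and per-gene statistics.
"""

from __future__ import annotations

import os
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .models import AnchorPair, GeneModel, GenotypeMatrix, InputError

# --- GFF3 -------------------------------------------------------------------


def write_gff3(genes: Iterable[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.scaffold, g.start)):
            attrs = f"ID={g.gene_id}"
            if g.subgenome:
                attrs += f";subgenome={g.subgenome}"
            fh.write("\t".join([g.scaffold, "dupevo", "gene", str(g.start), str(g.end),
                                ".", g.strand, ".", attrs]) + "\n")


def read_gff3(path: str, taxon: str) -> dict:
    """Read gene features from a GFF3 file into GeneModel objects.

    Ranks are assigned by start-coordinate order per scaffold. The
    ``subgenome`` attribute, when present, is carried over. Returns
    ``{gene_id: GeneModel}``.
    """
    import gffutils

    db = gffutils.create_db(path, ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    feats = [f for f in db.all_features() if f.featuretype in ("gene", "mRNA")]
    by_scaffold: dict = {}
    for f in feats:
        if f.featuretype == "mRNA" and any(x.featuretype == "gene" for x in feats):
            continue
        by_scaffold.setdefault(f.seqid, []).append(f)
    out: dict = {}
    for scaf, lst in by_scaffold.items():
        lst.sort(key=lambda f: (f.start, f.id))
        for rank, f in enumerate(lst):
            gid = f.attributes.get("ID", [f.id])[0]
            sub = f.attributes.get("subgenome", [None])[0]
            out[gid] = GeneModel(gene_id=gid, scaffold=scaf, start=f.start, end=f.end,
                                 strand=f.strand if f.strand in "+-" else "+",
                                 taxon=taxon, subgenome=sub, rank=rank)
    return out


# --- FASTA ------------------------------------------------------------------

def write_fasta(seqs: dict, path: str, width: int = 80) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sorted(seqs.items())]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> dict:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def gene_sequences(genes: Iterable[GeneModel], scaffold_seqs: dict) -> dict:
    """Extract (sense-strand) gene-body sequences from scaffold sequences."""
    out = {}
    for g in genes:
        seq = scaffold_seqs[g.scaffold][g.start - 1:g.end]
        if g.strand == "-":
            comp = str.maketrans("ACGTN", "TGCAN")
            seq = seq.translate(comp)[::-1]
        out[g.gene_id] = seq
    return out


# --- VCF --------------------------------------------------------------------

def write_vcf(matrices: dict, genes: dict, samples: list, path: str) -> None:
    """Write per-gene GenotypeMatrix objects as one VCF 4.2 per species.

    ``matrices`` maps gene_id -> GenotypeMatrix (haplotypes in accession
    order, two per accession); ``genes`` maps gene_id -> GeneModel on the
    same reference. Only sites where some haplotype differs from the
    reference (or that carry filter-relevant metadata) are emitted.
    """
    contigs = sorted({g.scaffold for g in genes.values()})
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines.append('##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">')
    lines.append('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))

    rows = []
    for gid in sorted(matrices):
        m = matrices[gid]
        g = genes[gid]
        if m.ref_seq is None:
            raise InputError(f"gene {gid}: reference sequence required to write VCF")
        for j, pos in enumerate(m.positions):
            ref = m.ref_seq[pos - 1]
            col = m.alleles[:, j]
            alts = sorted({b for b in col if b not in ("N", ref)})
            if not alts:
                alts_field = "."
                code = {ref: 0}
            else:
                alts_field = ",".join(alts)
                code = {ref: 0, **{b: i + 1 for i, b in enumerate(alts)}}
            gts = []
            for a in range(0, len(col), 2):
                h1 = "." if col[a] == "N" else str(code[col[a]])
                h2 = "." if col[a + 1] == "N" else str(code[col[a + 1]])
                gts.append(f"{h1}/{h2}")
            rows.append((g.scaffold, g.start + pos - 1, ref, alts_field,
                         f"MQ={m.mq[j]:.2f};DP={int(m.dp[j])}", gts))
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        for scaf, pos, ref, alts, info, gts in rows:
            fh.write(f"{scaf}\t{pos}\t.\t{ref}\t{alts}\t.\tPASS\t{info}\tGT\t"
                     + "\t".join(gts) + "\n")


# --- anchors and classes ----------------------------------------------------

def write_anchor_table(anchors: Iterable[AnchorPair], path: str) -> None:
    pd.DataFrame([(a.gene_id_1, a.gene_id_2, a.similarity_score) for a in anchors],
                 columns=["gene1", "gene2", "score"]).to_csv(path, sep="\t", index=False)


def read_anchor_table(path: str) -> list:
    df = pd.read_csv(path, sep="\t")
    need = {"gene1", "gene2", "score"}
    if not need <= set(df.columns):
        raise InputError(f"anchor table must have columns {sorted(need)}")
    return [AnchorPair(r.gene1, r.gene2, float(r.score)) for r in df.itertuples()]


def write_collinearity(blocks: list, path: str) -> None:
    """MCScanX-like collinearity text: a header line per block, one line
    per anchor."""
    with open(path, "w") as fh:
        for b in blocks:
            fh.write(f"## Alignment {b.block_id}: score={b.score:.2f} "
                     f"{b.scaffold_1}&{b.scaffold_2} {b.orientation} n={b.n_anchors}\n")
            for i, a in enumerate(b.anchors):
                fh.write(f"{b.block_id}-{i}:\t{a.gene_id_1}\t{a.gene_id_2}\t"
                         f"{a.similarity_score:g}\n")


def write_subgenome_map(genes: dict, path: str) -> None:
    rows = [(g.gene_id, g.subgenome) for g in genes.values() if g.subgenome]
    pd.DataFrame(sorted(rows), columns=["gene_id", "subgenome"]).to_csv(
        path, sep="\t", index=False)


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
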