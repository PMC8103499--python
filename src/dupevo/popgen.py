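"""Per-gene population-genetic statistics.

Nucleotide diversity (pi) and absolute divergence (dxy) are computed by
direct pairwise haplotype comparison with pairwise deletion of missing
calls; the denominator is the full gene length in bp so that monomorphic
sites (absent from VCFs) count toward the per-site rate. Selection pressure
is estimated with the Nei-Gojobori (1986) counting method with Jukes-Cantor
correction. Presence/absence of a gene in a resequenced accession panel is
decided from relative read depth.
"""

from __future__ import annotations

import functools
import itertools
import math
from typing import Optional

import numpy as np

from .models import GenotypeMatrix, InputError

# --- genetic code -----------------------------------------------------------

from Bio.Data import CodonTable as _CodonTable

_STANDARD = _CodonTable.unambiguous_dna_by_id[1]
CODON_AA: dict = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    CODON_AA[_stop] = "*"
NONSTOP_CODONS: tuple = tuple(sorted(c for c, aa in CODON_AA.items() if aa != "*"))
NUCLEOTIDES = "ACGT"


# --- variant filtering ------------------------------------------------------

def filter_variants(matrix: GenotypeMatrix, min_mq: float = 30.0, min_dp: int = 3) -> GenotypeMatrix:
    """Retain only sites with MQ > ``min_mq`` AND DP > ``min_dp`` (both strict).

    The gene length is unchanged: dropping a low-quality variant site returns
    it to the monomorphic denominator, it does not shorten the gene.
    """
    keep = (matrix.mq > min_mq) & (matrix.dp > min_dp)
    return GenotypeMatrix(
        gene_id=matrix.gene_id,
        species=matrix.species,
        alleles=matrix.alleles[:, keep],
        positions=matrix.positions[keep],
        mq=matrix.mq[keep],
        dp=matrix.dp[keep],
        gene_length_bp=matrix.gene_length_bp,
        ref_seq=matrix.ref_seq,
    )


# --- pi and dxy -------------------------------------------------------------

def _base_counts(alleles: np.ndarray) -> np.ndarray:
    """Per-site counts of A,C,G,T (missing 'N' ignored); shape (4, n_sites)."""
    return np.stack([(alleles == b).sum(axis=0) for b in NUCLEOTIDES])


def nucleotide_diversity(matrix: GenotypeMatrix) -> float:
    """Average pairwise differences per site within a population.

    pi = sum over haplotype pairs of per-site mismatches (pairs with a
    missing call at a site are skipped at that site) divided by
    n_pairs * gene_length_bp. Returns NaN for fewer than two haplotypes.
    """
    n = matrix.n_haplotypes
    if n < 2:
        return float("nan")
    n_pairs = n * (n - 1) // 2
    if matrix.n_sites == 0:
        return 0.0
    counts = _base_counts(matrix.alleles)
    called = counts.sum(axis=0)
    # pairs both-called minus matching pairs, per site
    mismatches = (called * (called - 1) - (counts * (counts - 1)).sum(axis=0)) / 2.0
    return float(mismatches.sum() / (n_pairs * matrix.gene_length_bp))


def _expand_to_union(matrix: GenotypeMatrix, union_pos: np.ndarray) -> np.ndarray:
    """Allele matrix over union positions; absent sites filled from ref_seq."""
    out = np.full((matrix.n_haplotypes, len(union_pos)), "N", dtype="<U1")
    if matrix.ref_seq is not None:
        ref = np.array(list(matrix.ref_seq), dtype="<U1")
        out[:] = ref[union_pos - 1][None, :]
    idx = np.searchsorted(union_pos, matrix.positions)
    out[:, idx] = matrix.alleles
    return out


def dxy(matrix_a: GenotypeMatrix, matrix_b: GenotypeMatrix) -> float:
    """Average pairwise differences per site between two populations.

    dxy = sum over inter-population haplotype pairs of mismatches divided by
    n_a * n_b * gene_length. Sites stored in only one matrix are expanded
    using that companion's reference sequence (a site absent from a VCF is
    reference-homozygous). Symmetric in its arguments.
    """
    if matrix_a.gene_length_bp != matrix_b.gene_length_bp:
        raise InputError(
            f"dxy requires matrices on the same gene coordinates "
            f"({matrix_a.gene_id}: {matrix_a.gene_length_bp} vs "
            f"{matrix_b.gene_id}: {matrix_b.gene_length_bp} bp)")
    L = matrix_a.gene_length_bp
    if L == 0:
        return float("nan")
    union = np.union1d(matrix_a.positions, matrix_b.positions).astype(int)
    if matrix_a.ref_seq is not None and matrix_b.ref_seq is not None \
            and matrix_a.ref_seq != matrix_b.ref_seq:
        # matrices called against different references (e.g. orthologs on two
        # assemblies): sites where the references disagree are fixed
        # interspecific differences even when no sample varies there
        ra = np.array(list(matrix_a.ref_seq), dtype="<U1")
        rb = np.array(list(matrix_b.ref_seq), dtype="<U1")
        union = np.union1d(union, np.flatnonzero(ra != rb) + 1).astype(int)
    if len(union) == 0:
        return 0.0
    a = _expand_to_union(matrix_a, union)
    b = _expand_to_union(matrix_b, union)
    ca = _base_counts(a)
    cb = _base_counts(b)
    pairs = ca.sum(axis=0) * cb.sum(axis=0)
    matches = (ca * cb).sum(axis=0)
    n_pairs = matrix_a.n_haplotypes * matrix_b.n_haplotypes
    return float((pairs - matches).sum() / (n_pairs * L))


# --- Nei-Gojobori dN/dS -----------------------------------------------------

def _codon_check(seq: str, name: str) -> list:
    if len(seq) % 3 != 0:
        raise InputError(f"{name}: length {len(seq)} is not a multiple of 3")
    codons = [seq[i:i + 3].upper() for i in range(0, len(seq), 3)]
    for i, c in enumerate(codons):
        if c not in CODON_AA:
            raise InputError(f"{name}: unknown codon {c!r} at codon {i}")
        if CODON_AA[c] == "*":
            raise InputError(f"{name}: stop codon {c} at codon {i}")
    return codons


@functools.lru_cache(maxsize=None)
def _syn_sites(codon: str) -> float:
    """Number of synonymous sites in a codon (0..3).

    Each position contributes the fraction of its three possible changes that
    are synonymous; changes creating a stop codon count as nonsynonymous.
    """
    aa = CODON_AA[codon]
    s = 0.0
    for i in range(3):
        for b in NUCLEOTIDES:
            if b == codon[i]:
                continue
            alt = codon[:i] + b + codon[i + 1:]
            if CODON_AA[alt] == aa:
                s += 1.0 / 3.0
    return s


@functools.lru_cache(maxsize=None)
def _pathway_counts(c1: str, c2: str) -> tuple:
    """Average synonymous/nonsynonymous difference counts between two codons.

    Codons differing at k positions are scored over all k! mutational
    pathways; pathways passing through a stop codon are excluded (when every
    pathway is blocked, all pathways are used, steps involving stops scored
    as nonsynonymous).
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0

    def walk(order, allow_stops):
        cur = c1
        sd = nd = 0.0
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1:]
            if CODON_AA[nxt] == "*" and not allow_stops:
                return None
            if CODON_AA[nxt] == CODON_AA[cur] and CODON_AA[nxt] != "*" and CODON_AA[cur] != "*":
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        return sd, nd

    results = [r for r in (walk(o, False) for o in itertools.permutations(diff)) if r is not None]
    if not results:
        results = [walk(o, True) for o in itertools.permutations(diff)]
    sd = sum(r[0] for r in results) / len(results)
    nd = sum(r[1] for r in results) / len(results)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """Jukes-Cantor distance d = -(3/4) ln(1 - (4/3) p); NaN when p >= 3/4."""
    if p < 0:
        raise InputError("proportion of differences must be non-negative")
    if p >= 0.75:
        return float("nan")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ng86_dnds(seq1: str, seq2: str) -> tuple:
    """Nei-Gojobori (1986) dN, dS and dN/dS for two in-frame coding sequences.

    Returns ``(dn, ds, dn_ds)``; ``dn_ds`` is NaN when dS = 0 (undefined
    ratio). Raises InputError on length mismatch or stop codons.
    """
    if len(seq1) != len(seq2):
        raise InputError(f"sequence length mismatch: {len(seq1)} vs {len(seq2)}")
    cod1 = _codon_check(seq1, "seq1")
    cod2 = _codon_check(seq2, "seq2")
    s1 = sum(_syn_sites(c) for c in cod1)
    s2 = sum(_syn_sites(c) for c in cod2)
    S = (s1 + s2) / 2.0
    N = len(seq1) - S
    sd = nd = 0.0
    for a, b in zip(cod1, cod2):
        d_s, d_n = _pathway_counts(a, b)
        sd += d_s
        nd += d_n
    ps = sd / S if S > 0 else 0.0
    pn = nd / N if N > 0 else 0.0
    ds = jukes_cantor(ps)
    dn = jukes_cantor(pn)
    dn_ds = dn / ds if (ds == ds and ds > 0 and dn == dn) else float("nan")
    return dn, ds, dn_ds


# --- presence/absence from read depth ---------------------------------------

def gene_presence_by_depth(per_gene_mean_depth: float, genome_median_depth: float,
                           rel_threshold: float = 0.2) -> bool:
    """A gene is present when its mean depth reaches ``rel_threshold`` x the
    genome-wide median depth."""
    if per_gene_mean_depth < 0 or genome_median_depth < 0:
        raise InputError("read depths must be non-negative")
    if genome_median_depth == 0:
        raise InputError("genome median depth is zero; presence is undefined")
    return bool(per_gene_mean_depth >= rel_threshold * genome_median_depth)


# --- VCF reader -------------------------------------------------------------

def read_vcf_genotypes(vcf_path: str, genes: list, species: str,
                       gene_seqs: Optional[dict] = None) -> dict:
    """Read a (possibly uncompressed) VCF 4.2 into per-gene GenotypeMatrix.

    ``genes`` is a list of GeneModel on the same reference; only biallelic-or-
    multiallelic SNP records falling inside a gene body are used. Site
    positions are converted to 1-based coordinates within the gene. INFO MQ
    and DP populate the per-site metadata. ``gene_seqs`` optionally maps
    gene_id to its reference sequence (enables dxy site expansion).
    """
    from cyvcf2 import VCF

    by_scaffold: dict = {}
    for g in genes:
        by_scaffold.setdefault(g.scaffold, []).append(g)
    for lst in by_scaffold.values():
        lst.sort(key=lambda g: g.start)

    per_gene: dict = {g.gene_id: {"pos": [], "alle": [], "mq": [], "dp": []} for g in genes}
    gene_of: dict = {g.gene_id: g for g in genes}

    vcf = VCF(vcf_path)
    n_hap = 2 * len(vcf.samples)
    for v in vcf:
        lst = by_scaffold.get(v.CHROM)
        if not lst:
            continue
        if len(v.REF) != 1 or any(len(a) != 1 for a in v.ALT):
            continue  # SNPs only
        # locate containing gene
        starts = [g.start for g in lst]
        i = np.searchsorted(starts, v.POS, side="right") - 1
        if i < 0 or v.POS > lst[i].end:
            continue
        g = lst[i]
        bases = [v.REF] + list(v.ALT)
        row = []
        for gt in v.genotypes:
            for a in gt[:2]:
                row.append("N" if a is None or a < 0 else bases[a])
        rec = per_gene[g.gene_id]
        rec["pos"].append(v.POS - g.start + 1)
        rec["alle"].append(row)
        rec["mq"].append(float(v.INFO.get("MQ", np.nan)))
        rec["dp"].append(int(v.INFO.get("DP", 0)))
    vcf.close()

    out = {}
    for gid, rec in per_gene.items():
        g = gene_of[gid]
        order = np.argsort(rec["pos"]) if rec["pos"] else np.array([], dtype=int)
        alle = (np.array(rec["alle"], dtype="<U1").T[:, order]
                if rec["alle"] else np.empty((n_hap, 0), dtype="<U1"))
        out[gid] = GenotypeMatrix(
            gene_id=gid, species=species,
            alleles=alle,
            positions=np.array(rec["pos"], dtype=int)[order],
            mq=np.array(rec["mq"], dtype=float)[order],
            dp=np.array(rec["dp"], dtype=int)[order],
            gene_length_bp=g.length,
            ref_seq=None if gene_seqs is None else gene_seqs.get(gid),
        )
    return out
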