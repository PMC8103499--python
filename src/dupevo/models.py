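"""Shared domain types for the duplicated-gene evolution toolkit.

The core objects mirror what the analysis operates on: gene models with an
ordinal rank on their scaffold, homolog anchor pairs, chained collinearity
blocks, diploid/tetraploid ortholog groups, per-gene haplotype matrices, and
per-cytosine bisulfite count matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd


class ConfigurationError(ValueError):
    """Raised when a simulation or pipeline configuration is invalid."""


class InputError(ValueError):
    """Raised when user-supplied input data violates a precondition."""


@dataclass(frozen=True)
class GeneModel:
    """A gene's location and identity.

    ``rank`` is the 0-based ordinal position of the gene among all genes on
    its scaffold; synteny chaining works in this rank space, not in bp.
    ``subgenome`` is ``"A"``/``"B"`` for allotetraploid genes and ``None``
    for diploid/outgroup genes.
    """

    gene_id: str
    scaffold: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str
    taxon: str
    subgenome: Optional[str]
    rank: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise InputError(f"gene {self.gene_id}: start > end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class AnchorPair:
    """An unordered homolog pair with a similarity score (e.g. a BLAST hit)."""

    gene_id_1: str
    gene_id_2: str
    similarity_score: float

    def __post_init__(self) -> None:
        if self.gene_id_1 == self.gene_id_2:
            raise InputError(f"anchor pairs a gene with itself: {self.gene_id_1}")
        if self.similarity_score < 0:
            raise InputError("anchor similarity score must be non-negative")

    @property
    def key(self) -> tuple:
        return tuple(sorted((self.gene_id_1, self.gene_id_2)))


@dataclass
class SyntenyBlock:
    """A chained run of collinear anchors between two scaffolds.

    ``anchors`` are AnchorPairs ordered along side 1; gene ranks are strictly
    increasing on side 1 and strictly monotone (increasing for ``same``
    orientation, decreasing for ``inverted``) on side 2.
    """

    block_id: str
    anchors: list  # list[AnchorPair], ordered along side 1
    scaffold_1: str
    scaffold_2: str
    taxon_1: str
    taxon_2: str
    orientation: str  # "same" | "inverted"
    score: float

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)

    def gene_ids(self) -> set:
        out = set()
        for a in self.anchors:
            out.add(a.gene_id_1)
            out.add(a.gene_id_2)
        return out


@dataclass
class OrthoGroup:
    """A diploid/tetraploid ortholog group derived from collinear blocks.

    ``category``: ``singleton`` (one subgenome copy retained, diploid ortholog
    present), ``doublet`` (copies in both subgenomes, diploid ortholog absent)
    or ``triplet`` (doublet plus the diploid ortholog). Doublet totals in the
    classical sense are doublet + triplet.
    """

    group_id: str
    diploid_gene: Optional[str]
    tetraploid_copies: dict  # subgenome -> gene_id
    category: str

    def __post_init__(self) -> None:
        if self.category == "singleton" and len(self.tetraploid_copies) != 1:
            raise InputError("singleton group must have exactly one tetraploid copy")
        if self.category in ("doublet", "triplet") and set(self.tetraploid_copies) != {"A", "B"}:
            raise InputError("doublet/triplet group must have copies in both subgenomes")
        if self.category == "triplet" and self.diploid_gene is None:
            raise InputError("triplet group requires the diploid ortholog")


@dataclass
class DuplicationClassLabel:
    """A single-gene duplication-mode label with its supporting evidence."""

    gene_id: str
    label: str  # ancient_collinear/conserved_eudicot/dispersed/proximal/tandem/transposed/segmental/lineage_specific
    evidence: tuple = ()


@dataclass
class GenotypeMatrix:
    """Haplotype x site allele matrix for one gene in one species.

    ``alleles`` holds single-character bases with ``"N"`` for missing calls;
    only variable (or metadata-flagged) sites are stored, ``positions`` being
    1-based coordinates within the gene. ``gene_length_bp`` is the full gene
    length including monomorphic sites, which is the denominator for per-site
    statistics (VCFs omit invariant sites). ``ref_seq``, when present, is the
    mapping-reference gene sequence used to expand sites absent from a
    companion matrix in between-population comparisons.
    """

    gene_id: str
    species: str
    alleles: np.ndarray  # (n_haplotypes, n_sites) dtype <U1
    positions: np.ndarray  # (n_sites,) int, 1-based within gene, strictly increasing
    mq: np.ndarray  # (n_sites,) float
    dp: np.ndarray  # (n_sites,) int
    gene_length_bp: int
    ref_seq: Optional[str] = None

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype="<U1")
        self.positions = np.asarray(self.positions, dtype=int)
        self.mq = np.asarray(self.mq, dtype=float)
        self.dp = np.asarray(self.dp, dtype=int)
        if self.alleles.ndim != 2:
            raise InputError("allele matrix must be 2-D (haplotypes x sites)")
        n_sites = self.alleles.shape[1]
        if not (len(self.positions) == len(self.mq) == len(self.dp) == n_sites):
            raise InputError("site metadata length mismatch")
        if n_sites > 1 and not np.all(np.diff(self.positions) > 0):
            raise InputError("site positions must be strictly increasing")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]


class MethylomeMatrix:
    """Per-cytosine bisulfite counts for a set of samples on one reference.

    ``sites`` is a DataFrame with columns ``scaffold, pos, strand, context``
    and optionally ``gene_id``; ``meth`` and ``total`` are (n_sites,
    n_samples) integer arrays of methylated and total read counts aligned to
    ``sites`` rows and ``samples`` order. ``sample_species`` maps sample name
    to species.
    """

    def __init__(self, sites: pd.DataFrame, meth: np.ndarray, total: np.ndarray,
                 samples: list, sample_species: dict):
        self.sites = sites.reset_index(drop=True)
        self.meth = np.asarray(meth, dtype=np.int64)
        self.total = np.asarray(total, dtype=np.int64)
        self.samples = list(samples)
        self.sample_species = dict(sample_species)
        if self.meth.shape != self.total.shape:
            raise InputError("meth/total shape mismatch")
        if self.meth.shape != (len(self.sites), len(self.samples)):
            raise InputError("count matrix shape does not match sites x samples")
        if (self.meth < 0).any() or (self.meth > self.total).any():
            raise InputError("methylated counts must satisfy 0 <= meth <= total")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def subset_sites(self, mask: np.ndarray) -> "MethylomeMatrix":
        mask = np.asarray(mask, dtype=bool)
        return MethylomeMatrix(self.sites.loc[mask], self.meth[mask], self.total[mask],
                               self.samples, self.sample_species)

    def subset_samples(self, samples: list) -> "MethylomeMatrix":
        idx = [self.samples.index(s) for s in samples]
        return MethylomeMatrix(self.sites, self.meth[:, idx], self.total[:, idx],
                               samples, {s: self.sample_species[s] for s in samples})
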