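"""Collinearity chaining and duplicate-gene classification.

Homolog anchor pairs are chained into collinear blocks by weighted
longest-chain dynamic programming in gene-rank space (the approach of
MCScanX-style tools), and every gene is then classified into the
duplicate-gene taxonomy used for allopolyploid genome analyses:

* ortholog groups between a diploid and the two subgenomes of an
  allotetraploid (singleton / doublet / triplet),
* small-scale duplication modes (segmental > tandem > proximal >
  transposed > dispersed, applied in that priority order),
* collinearity-depth labels (ancient_collinear for genes covered by more
  than four blocks; conserved_eudicot for genes collinear with a
  conserved outgroup eudicot genome),
* gene families by reciprocal-best-hit clustering, flagging families
  private to the focal taxa (lineage_specific).
"""

from __future__ import annotations

import itertools
import logging
from collections import defaultdict
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .models import AnchorPair, DuplicationClassLabel, GeneModel, InputError, OrthoGroup, SyntenyBlock

logger = logging.getLogger(__name__)

SSD_PRIORITY = ("segmental", "tandem", "proximal", "transposed", "dispersed")


# --- anchor chaining --------------------------------------------------------

def _pair_side(g1: GeneModel, g2: GeneModel) -> bool:
    """True if (g1, g2) is already in canonical side order."""
    return (g1.taxon, g1.scaffold, g1.rank) <= (g2.taxon, g2.scaffold, g2.rank)


def _best_chain(points: list, max_gene_gap: int, gap_penalty: float, inverted: bool):
    """Highest-scoring monotone chain over (r1, r2, score, anchor) points.

    Strictly increasing in r1 and in r2 (r2 decreasing when ``inverted``),
    adjacent rank gaps bounded by ``max_gene_gap`` on both sides, linear gap
    penalty. Ties broken by smaller total rank gap, then lexicographically
    smallest starting gene id (determinism contract).
    """
    pts = [(r1, -r2 if inverted else r2, s, a) for r1, r2, s, a in points]
    pts.sort(key=lambda p: (p[0], p[1], p[3].key))
    n = len(pts)
    if n == 0:
        return None

    def better(cand, cur):
        # prefer higher score, then smaller total gap, then smaller start id
        if cand[0] != cur[0]:
            return cand[0] > cur[0]
        if cand[1] != cur[1]:
            return cand[1] < cur[1]
        return cand[2] < cur[2]

    # per node: (score, total_gap, start_key, prev_index)
    best = [None] * n
    for i, (r1, r2, s, a) in enumerate(pts):
        cur = (s, 0, a.key, -1)
        for j in range(i):
            q1, q2, _, _ = pts[j]
            if q1 >= r1 or q2 >= r2:
                continue
            if (r1 - q1) > max_gene_gap or (r2 - q2) > max_gene_gap:
                continue
            gap = (r1 - q1 - 1) + (r2 - q2 - 1)
            cand = (best[j][0] + s - gap_penalty * gap, best[j][1] + gap, best[j][2], j)
            if better(cand, cur):
                cur = cand
        best[i] = cur
    end = min(range(n), key=lambda i: (-best[i][0], best[i][1], best[i][2]))
    chain = []
    i = end
    while i >= 0:
        chain.append(pts[i])
        i = best[i][3]
    chain.reverse()
    return best[end][0], chain


def chain_anchors(anchors: Iterable[AnchorPair], genes: dict,
                  min_block_anchors: int = 5, max_gene_gap: int = 25,
                  gap_penalty: float = 1.0) -> list:
    """Chain homolog anchors into collinear blocks.

    ``genes`` maps gene_id -> GeneModel (ranks must be assigned). Anchors are
    grouped by scaffold pair and greedily decomposed into maximum-score
    monotone chains (both orientations tried); chains shorter than
    ``min_block_anchors`` are discarded. Each anchor joins at most one block.

    Within a self comparison (both genes on the same scaffold of the same
    taxon), anchors with rank separation <= ``max_gene_gap`` are excluded
    from chaining: local tandem/proximal arrays otherwise masquerade as short
    collinear blocks.
    """
    groups: dict = defaultdict(list)
    for a in anchors:
        if a.gene_id_1 not in genes:
            raise InputError(f"anchor references unknown gene {a.gene_id_1!r}")
        if a.gene_id_2 not in genes:
            raise InputError(f"anchor references unknown gene {a.gene_id_2!r}")
        g1, g2 = genes[a.gene_id_1], genes[a.gene_id_2]
        if not _pair_side(g1, g2):
            g1, g2 = g2, g1
        if g1.taxon == g2.taxon and g1.scaffold == g2.scaffold:
            if abs(g1.rank - g2.rank) <= max_gene_gap:
                continue  # tandem-array self hit, not block evidence
        key = (g1.taxon, g1.scaffold, g2.taxon, g2.scaffold)
        groups[key].append((g1.rank, g2.rank, a.similarity_score, a))

    blocks = []
    counter = itertools.count(1)
    for key in sorted(groups):
        t1, s1, t2, s2 = key
        pool = {id(a): (r1, r2, s, a) for r1, r2, s, a in groups[key]}
        # deduplicate unordered-duplicate anchors
        seen = set()
        for k in list(pool):
            ak = pool[k][3].key
            if ak in seen:
                del pool[k]
            else:
                seen.add(ak)
        while pool:
            candidates = []
            for inverted in (False, True):
                res = _best_chain(list(pool.values()), max_gene_gap, gap_penalty, inverted)
                if res is not None:
                    candidates.append((res[0], -len(res[1]), inverted, res[1]))
            if not candidates:
                break
            candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
            score, _, inverted, chain = candidates[0]
            if len(chain) < min_block_anchors:
                break
            blocks.append(SyntenyBlock(
                block_id=f"block{next(counter):04d}",
                anchors=[p[3] for p in chain],
                scaffold_1=s1, scaffold_2=s2, taxon_1=t1, taxon_2=t2,
                orientation="inverted" if inverted else "same",
                score=score,
            ))
            for p in chain:
                pool.pop(id(p[3]), None)
    return blocks


# --- collinear depth --------------------------------------------------------

def collinear_depth(blocks: list, genes: dict, eudicot_taxa: Optional[set] = None,
                    ancient_min_depth: int = 4) -> pd.DataFrame:
    """Count, per gene, the distinct collinear blocks covering it.

    Genes covered by strictly more than ``ancient_min_depth`` blocks are
    labeled ancient_collinear; genes appearing in at least one block against
    a taxon in ``eudicot_taxa`` are labeled conserved_eudicot.
    """
    eudicot_taxa = set(eudicot_taxa or ())
    depth: dict = defaultdict(int)
    conserved: set = set()
    for b in blocks:
        members = b.gene_ids()
        for gid in members:
            depth[gid] += 1
        if b.taxon_1 in eudicot_taxa or b.taxon_2 in eudicot_taxa:
            for a in b.anchors:
                for gid in (a.gene_id_1, a.gene_id_2):
                    g = genes.get(gid)
                    if g is not None and g.taxon not in eudicot_taxa:
                        conserved.add(gid)
    rows = [{
        "gene_id": gid,
        "depth": depth.get(gid, 0),
        "ancient_collinear": depth.get(gid, 0) > ancient_min_depth,
        "conserved_eudicot": gid in conserved,
    } for gid in sorted(genes)]
    return pd.DataFrame(rows, columns=["gene_id", "depth", "ancient_collinear", "conserved_eudicot"])


# --- WGD ortholog groups ----------------------------------------------------

class _UnionFind:
    def __init__(self):
        self.parent = {}

    def find(self, x):
        p = self.parent.setdefault(x, x)
        if p != x:
            self.parent[x] = p = self.find(p)
        return p

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def classify_wgd_groups(blocks: list, genes: dict, diploid_taxon: str,
                        tetraploid_taxon: str) -> list:
    """Derive singleton/doublet/triplet ortholog groups from collinear blocks.

    Group membership is the connected component over anchors that lie inside
    diploid<->tetraploid blocks or cross-subgenome (A<->B) blocks within the
    tetraploid. Where duplicated segments contribute more than one tetraploid
    member per subgenome, the member with the highest summed anchor score is
    kept as that subgenome's representative copy.

    singleton: one subgenome represented and the diploid ortholog present;
    doublet: both subgenomes represented, diploid ortholog absent;
    triplet: both subgenomes represented and the diploid ortholog present.
    """
    uf = _UnionFind()
    edge_score: dict = defaultdict(float)
    for b in blocks:
        taxa = {b.taxon_1, b.taxon_2}
        for a in b.anchors:
            g1, g2 = genes[a.gene_id_1], genes[a.gene_id_2]
            cross_taxon = {g1.taxon, g2.taxon} == {diploid_taxon, tetraploid_taxon}
            cross_sub = (g1.taxon == g2.taxon == tetraploid_taxon
                         and g1.subgenome != g2.subgenome)
            if not (cross_taxon or cross_sub):
                continue
            for g in (g1, g2):
                if g.taxon == tetraploid_taxon and g.subgenome not in ("A", "B"):
                    raise InputError(f"tetraploid gene {g.gene_id} lacks a subgenome tag")
            uf.union(a.gene_id_1, a.gene_id_2)
            edge_score[a.gene_id_1] += a.similarity_score
            edge_score[a.gene_id_2] += a.similarity_score

    comps: dict = defaultdict(list)
    for gid in uf.parent:
        comps[uf.find(gid)].append(gid)

    groups = []
    for i, root in enumerate(sorted(comps), start=1):
        members = comps[root]
        dips = sorted((g for g in members if genes[g].taxon == diploid_taxon),
                      key=lambda g: (-edge_score[g], g))
        diploid_gene = dips[0] if dips else None
        copies: dict = {}
        for sub in ("A", "B"):
            cand = sorted((g for g in members
                           if genes[g].taxon == tetraploid_taxon and genes[g].subgenome == sub),
                          key=lambda g: (-edge_score[g], g))
            if cand:
                copies[sub] = cand[0]
        if not copies:
            continue
        if len(copies) == 2:
            category = "triplet" if diploid_gene is not None else "doublet"
        else:
            if diploid_gene is None:
                continue  # a lone tetraploid copy with no diploid anchor is not a group
            category = "singleton"
        groups.append(OrthoGroup(group_id=f"og{i:05d}", diploid_gene=diploid_gene,
                                 tetraploid_copies=copies, category=category))
    return groups


# --- SSD mode classification ------------------------------------------------

def classify_ssd_modes(genes: dict, self_anchors: Iterable[AnchorPair], blocks: list,
                       tetraploid_taxon: str, diploid_taxon: str,
                       proximal_max_rank_gap: int = 10) -> list:
    """Assign one small-scale-duplication mode per duplicated gene.

    Candidate pairs are same-subgenome anchor pairs within the tetraploid
    (cross-subgenome pairs are WGD-derived homoeologs and carry no SSD
    signal). Priority per pair: segmental (the pair is an anchor of an
    intra-genome collinear block) > tandem (rank gap 1 on one scaffold) >
    proximal (rank gap <= ``proximal_max_rank_gap``) > transposed (exactly
    one of the two copies collinear with the diploid outgroup, the label
    going to the non-collinear, novel-locus copy) > dispersed. A gene's
    label is its highest-priority mode over all its pairs.
    """
    segmental_pairs = set()
    collinear_with_outgroup = set()
    for b in blocks:
        if b.taxon_1 == b.taxon_2 == tetraploid_taxon:
            for a in b.anchors:
                segmental_pairs.add(a.key)
        if {b.taxon_1, b.taxon_2} == {diploid_taxon, tetraploid_taxon}:
            for gid in b.gene_ids():
                if genes[gid].taxon == tetraploid_taxon:
                    collinear_with_outgroup.add(gid)

    rank = {m: i for i, m in enumerate(SSD_PRIORITY)}
    best: dict = {}

    def offer(gid, mode, partner):
        cur = best.get(gid)
        if cur is None or rank[mode] < rank[cur[0]]:
            best[gid] = (mode, partner)

    seen = set()
    for a in self_anchors:
        if a.key in seen:
            continue
        seen.add(a.key)
        g1 = genes.get(a.gene_id_1)
        g2 = genes.get(a.gene_id_2)
        if g1 is None or g2 is None:
            raise InputError(f"anchor references unknown gene in pair {a.key}")
        if g1.taxon != tetraploid_taxon or g2.taxon != tetraploid_taxon:
            continue
        if g1.subgenome != g2.subgenome:
            continue  # homoeologous (WGD) pair
        if a.key in segmental_pairs:
            mode = "segmental"
        elif g1.scaffold == g2.scaffold and abs(g1.rank - g2.rank) == 1:
            mode = "tandem"
        elif g1.scaffold == g2.scaffold and 1 < abs(g1.rank - g2.rank) <= proximal_max_rank_gap:
            mode = "proximal"
        else:
            in1 = g1.gene_id in collinear_with_outgroup
            in2 = g2.gene_id in collinear_with_outgroup
            if in1 != in2:
                novel = g2 if in1 else g1
                offer(novel.gene_id, "transposed", (g1.gene_id if novel is g2 else g2.gene_id))
                continue
            mode = "dispersed"
        offer(g1.gene_id, mode, g2.gene_id)
        offer(g2.gene_id, mode, g1.gene_id)

    return [DuplicationClassLabel(gene_id=g, label=m, evidence=(p,))
            for g, (m, p) in sorted(best.items())]


# --- gene families ----------------------------------------------------------

def cluster_families(genes: dict, hits: Iterable[AnchorPair], focal_taxa: set) -> tuple:
    """Cluster genes into families over the reciprocal best-scoring hit graph.

    Returns ``(families, lineage_specific)`` where ``families`` maps gene_id
    to family id and ``lineage_specific`` is the set of family ids whose
    members all belong to ``focal_taxa``. An empty hit table yields all
    single-gene families (with a warning).
    """
    hits = list(hits)
    if not hits:
        logger.warning("empty hit table: every gene becomes a single-gene family")
    # best hit per (gene, partner taxon); score ties broken by smaller gene id
    best_hit: dict = {}
    for a in hits:
        for x, y in ((a.gene_id_1, a.gene_id_2), (a.gene_id_2, a.gene_id_1)):
            if x not in genes or y not in genes:
                raise InputError(f"hit references unknown gene in pair {a.key}")
            key = (x, genes[y].taxon)
            cur = best_hit.get(key)
            if cur is None or a.similarity_score > cur[1] or \
                    (a.similarity_score == cur[1] and y < cur[0]):
                best_hit[key] = (y, a.similarity_score)

    uf = _UnionFind()
    for gid in genes:
        uf.find(gid)
    for (x, taxon), (y, _) in best_hit.items():
        back = best_hit.get((y, genes[x].taxon))
        if back is not None and back[0] == x:
            uf.union(x, y)

    comps: dict = defaultdict(list)
    for gid in genes:
        comps[uf.find(gid)].append(gid)
    families: dict = {}
    lineage_specific: set = set()
    for i, root in enumerate(sorted(comps), start=1):
        fam = f"fam{i:05d}"
        taxa = set()
        for gid in comps[root]:
            families[gid] = fam
            taxa.add(genes[gid].taxon)
        if taxa and taxa <= set(focal_taxa):
            lineage_specific.add(fam)
    return families, lineage_specific
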