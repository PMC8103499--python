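"""Seed-reproducible synthetic allopolyploid species-complex generator.

Emulates, at desk scale, the study design the downstream analyses assume:
one allotetraploidization shared by three descendant tetraploid species
(ginseng, quinquefolius, japonicus) plus a diploid relative (notoginseng)
and a conserved eudicot outgroup genome. After the tetraploidization the
two subgenomes (A/B) lose genes independently (fractionation), and five
modes of small-scale duplication (tandem, proximal, transposed, dispersed,
segmental) plant extra copies. Sequences evolve by Jukes-Cantor
substitution on the fixed tree ((ginseng, quinquefolius, japonicus),
notoginseng) with per-gene purifying-selection acceptance of
nonsynonymous changes; population haplotypes carry species-specific
planted nucleotide diversity; methylomes are binomial read counts around
hierarchical gene/copy/species means with planted DMGs and inherited
subgenome asymmetry. Every planted property is recorded in a TruthTable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .models import ConfigurationError, GeneModel, AnchorPair, MethylomeMatrix, GenotypeMatrix
from .popgen import CODON_AA, NONSTOP_CODONS, nucleotide_diversity, filter_variants

TETRAPLOID_SPECIES = ("ginseng", "quinquefolius", "japonicus")
DIPLOID_SPECIES = "notoginseng"
ALL_SPECIES = TETRAPLOID_SPECIES + (DIPLOID_SPECIES,)
TETRAPLOID_TAXON = "ginseng"  # assembled tetraploid reference
DIPLOID_TAXON = "notoginseng"  # assembled diploid reference
OUTGROUP_TAXON = "outgroup_eudicot"
FOCAL_TAXA = {TETRAPLOID_TAXON, DIPLOID_TAXON}
MAPPING_REFERENCE = {
    "ginseng": TETRAPLOID_TAXON,
    "quinquefolius": TETRAPLOID_TAXON,
    "japonicus": TETRAPLOID_TAXON,
    "notoginseng": DIPLOID_TAXON,
}
SSD_MODES = ("tandem", "proximal", "transposed", "dispersed", "segmental")
CONTEXTS = ("CG", "CHG", "CHH")

#: per-branch substitution probabilities per site, before divergence_scale
BASE_BRANCH = {
    "stem": 0.020,       # ancestral root -> tetraploid ancestor
    "subgenome": 0.015,  # parental-diploid split creating subgenomes A/B
    "ginseng": 0.008,
    "quinquefolius": 0.008,
    "japonicus": 0.008,
    "notoginseng": 0.030,
    "outgroup": 0.100,
}

NUCS = "ACGT"


def _default_meth_class_means():
    return {
        "default": {"CG": 0.60, "CHG": 0.45, "CHH": 0.12},
        "ancient_collinear": {"CG": 0.30, "CHG": 0.22, "CHH": 0.05},
        "dispersed": {"CG": 0.85, "CHG": 0.70, "CHH": 0.35},
        "singleton": {"CG": 0.72, "CHG": 0.57, "CHH": 0.20},
        "doublet": {"CG": 0.55, "CHG": 0.40, "CHH": 0.10},
        "triplet": {"CG": 0.55, "CHG": 0.40, "CHH": 0.10},
    }


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study design (see docs/methods.md)."""

    seed: int = 0
    n_ancestral_genes: int = 200
    n_scaffolds: int = 2
    gene_length_bp: int = 300
    intergenic_bp: int = 100
    fractionation_prob: float = 0.2
    fractionation_bias: float = 0.5  # share of post-WGD losses hitting subgenome B
    diploid_loss_prob: float = 0.2
    conserved_outgroup_frac: float = 0.8
    ssd_counts: dict = field(default_factory=lambda: {
        "tandem": 3, "proximal": 3, "transposed": 3, "dispersed": 3, "segmental": 1})
    segment_genes: int = 6
    ancient_runs: int = 1
    ancient_run_genes: int = 6
    ancient_extra_copies: int = 5
    n_lineage_specific: int = 8
    ssd_divergence: float = 0.02
    proximal_max_gap: int = 8
    species_pi: dict = field(default_factory=lambda: {
        "ginseng": 0.0004, "quinquefolius": 0.0022, "japonicus": 0.0039,
        "notoginseng": 0.0010})
    divergence_scale: dict = field(default_factory=dict)
    pi_gene_sd: dict = field(default_factory=lambda: {"singleton": 0.8, "default": 0.2})
    pi_gene_mult: dict = field(default_factory=lambda: {"singleton": 1.5, "default": 1.0})
    omega_class: dict = field(default_factory=lambda: {
        "ancient_collinear": (0.08, 0.02), "dispersed": (0.60, 0.35),
        "singleton": (0.35, 0.15), "default": (0.20, 0.08)})
    meth_class_means: dict = field(default_factory=_default_meth_class_means)
    meth_gene_sd: dict = field(default_factory=lambda: {"singleton": 0.12, "default": 0.05})
    meth_copy_sd: float = 0.10
    meth_species_sd: float = 0.06
    meth_clade_sd: float = 0.05
    meth_species_copy_sd: float = 0.03
    meth_replicate_sd: float = 0.02
    n_dmg: int = 4
    dmg_high: float = 0.85
    dmg_low: float = 0.15
    asym_frac: float = 0.2
    asym_offset: float = 0.4
    n_accessions: dict = field(default_factory=lambda: {s: 4 for s in ALL_SPECIES})
    n_meth_replicates: int = 2
    read_depth_mean: float = 30.0
    low_quality_frac: float = 0.05
    missing_rate: float = 0.02
    n_absent: dict = field(default_factory=lambda: {"quinquefolius": 4, "japonicus": 4})
    depth_median: float = 30.0

    def validate(self) -> None:
        probs = {
            "fractionation_prob": self.fractionation_prob,
            "fractionation_bias": self.fractionation_bias,
            "diploid_loss_prob": self.diploid_loss_prob,
            "conserved_outgroup_frac": self.conserved_outgroup_frac,
            "asym_frac": self.asym_frac, "low_quality_frac": self.low_quality_frac,
            "missing_rate": self.missing_rate, "dmg_high": self.dmg_high,
            "dmg_low": self.dmg_low,
        }
        for k, v in probs.items():
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{k} must be a probability in [0, 1], got {v}")
        counts = {
            "n_ancestral_genes": self.n_ancestral_genes, "n_scaffolds": self.n_scaffolds,
            "gene_length_bp": self.gene_length_bp, "intergenic_bp": self.intergenic_bp,
            "segment_genes": self.segment_genes, "ancient_runs": self.ancient_runs,
            "ancient_run_genes": self.ancient_run_genes,
            "ancient_extra_copies": self.ancient_extra_copies,
            "n_lineage_specific": self.n_lineage_specific, "n_dmg": self.n_dmg,
            "n_meth_replicates": self.n_meth_replicates,
        }
        for k, v in counts.items():
            if v < 0:
                raise ConfigurationError(f"{k} must be >= 0, got {v}")
        if self.n_ancestral_genes < 1 or self.n_scaffolds < 1:
            raise ConfigurationError("need at least one ancestral gene and one scaffold")
        if self.gene_length_bp % 3 != 0 or self.gene_length_bp < 30:
            raise ConfigurationError("gene_length_bp must be a multiple of 3 and >= 30")
        unknown = set(self.ssd_counts) - set(SSD_MODES)
        if unknown:
            raise ConfigurationError(f"unknown SSD modes in ssd_counts: {sorted(unknown)}")
        if any(v < 0 for v in self.ssd_counts.values()):
            raise ConfigurationError("ssd_counts must be >= 0")
        if sum(self.ssd_counts.values()) >= self.n_ancestral_genes:
            raise ConfigurationError("ssd counts must sum to less than n_ancestral_genes")
        for sp in ALL_SPECIES:
            if self.species_pi.get(sp, 0) < 0:
                raise ConfigurationError(f"species_pi[{sp}] must be >= 0")
        if not (0 < self.asym_offset <= 1):
            raise ConfigurationError("asym_offset must be in (0, 1]")


@dataclass
class TruthTable:
    """Everything planted by the generator, for downstream verification."""

    genes: pd.DataFrame            # gene_id, taxon, scaffold, subgenome, family, origin, meth_class
    groups: pd.DataFrame           # family, category, diploid_gene, gene_A, gene_B
    ssd_events: pd.DataFrame       # mode, donor, copy, family
    ancient_genes: list
    lineage_families: dict         # family -> [gene ids]
    category_counts: dict
    n_losses: int
    n_gains: int
    dmg: dict = field(default_factory=dict)    # (sp1, sp2) -> [(gene_sp1, gene_sp2)]
    asym: pd.DataFrame = field(default_factory=pd.DataFrame)
    realized_pi: dict = field(default_factory=dict)


@dataclass
class SimulatedGenomes:
    config: SimulationConfig
    genes: dict        # taxon -> {gene_id: GeneModel}
    gene_order: dict   # taxon -> {scaffold: [gene ids in rank order]}
    ref_seqs: dict     # taxon -> {gene_id: str}
    species_seqs: dict  # species -> {gene_id: str} consensus on its mapping reference
    anchors: list      # list[AnchorPair] across and within taxa

    def scaffold_sequence(self, taxon: str, scaffold: str, rng: np.random.Generator) -> str:
        """Assemble a scaffold sequence (random intergenic spacers + genes)."""
        cfg = self.config
        parts = []
        for gid in self.gene_order[taxon][scaffold]:
            parts.append("".join(rng.choice(list(NUCS), size=cfg.intergenic_bp)))
            parts.append(self.ref_seqs[taxon][gid])
        parts.append("".join(rng.choice(list(NUCS), size=cfg.intergenic_bp)))
        return "".join(parts)


@dataclass
class PopulationData:
    matrices: dict     # species -> {gene_id: GenotypeMatrix}
    depth: pd.DataFrame  # gene_id, species, mean_depth
    median_depth: dict
    absent: dict       # species -> set of gene ids


@dataclass
class MethylomeData:
    matrices: dict     # species -> MethylomeMatrix


# --- sequence evolution -----------------------------------------------------

def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(NONSTOP_CODONS), size=n_codons)
    return "".join(NONSTOP_CODONS[i] for i in idx)


def _mutate(seq: str, d: float, omega: float, rng: np.random.Generator) -> str:
    """Jukes-Cantor substitutions at rate d with purifying selection.

    Each site mutates with probability d to a uniform different base;
    proposals creating a stop codon are rejected, amino-acid-changing
    proposals are accepted with probability omega.
    """
    hit = np.flatnonzero(rng.random(len(seq)) < d)
    if len(hit) == 0:
        return seq
    s = list(seq)
    for pos in hit:
        cur = s[pos]
        alts = [b for b in NUCS if b != cur]
        new = alts[rng.integers(0, 3)]
        c0 = pos - pos % 3
        codon_old = "".join(s[c0:c0 + 3])
        codon_new = codon_old[:pos - c0] + new + codon_old[pos - c0 + 1:]
        if CODON_AA[codon_new] == "*":
            continue
        if CODON_AA[codon_new] != CODON_AA[codon_old] and rng.random() > omega:
            continue
        s[pos] = new
    return "".join(s)


# --- genome simulation ------------------------------------------------------

class _Entry:
    __slots__ = ("gene_id", "family", "origin", "subgenome")

    def __init__(self, gene_id, family, origin, subgenome):
        self.gene_id = gene_id
        self.family = family
        self.origin = origin
        self.subgenome = subgenome


def _find(scaffolds: dict, gene_id: str):
    for name, lst in scaffolds.items():
        for i, e in enumerate(lst):
            if e.gene_id == gene_id:
                return name, i
    raise KeyError(gene_id)


def simulate_genomes(config: SimulationConfig):
    """Simulate annotated genomes, sequences, homolog anchors and truth.

    Returns ``(genomes, truth)``. The tetraploid reference carries a
    subgenome tag on every gene; every SSD event is recorded in the truth
    with its mode; ranks are consecutive per scaffold and coordinates lie
    within scaffold bounds.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))
    n = config.n_ancestral_genes
    fams = [f"g{i:05d}" for i in range(n)]
    splits = np.array_split(np.arange(n), config.n_scaffolds)

    diploid_present = rng.random(n) >= config.diploid_loss_prob
    # fractionation: each copy is lost independently; the overall loss rate is
    # fractionation_prob per copy, split between subgenomes by
    # fractionation_bias (bias 0.5 = unbiased loss at rate f per copy)
    f = config.fractionation_prob
    lostA = rng.random(n) < min(1.0, 2.0 * f * (1.0 - config.fractionation_bias))
    lostB = rng.random(n) < min(1.0, 2.0 * f * config.fractionation_bias)
    presentA, presentB = ~lostA, ~lostB

    outgroup_present = rng.random(n) < config.conserved_outgroup_frac

    tet: dict = {}
    for sub in ("A", "B"):
        present = presentA if sub == "A" else presentB
        for k, idxs in enumerate(splits):
            tet[f"tet_s{k + 1}{sub}"] = [
                _Entry(f"Pg{sub}_{fams[i]}", fams[i], "wgd", sub)
                for i in idxs if present[i]]
    dip = {f"dip_s{k + 1}": [_Entry(f"Pn_{fams[i]}", fams[i], "wgd", None)
                             for i in idxs if diploid_present[i]]
           for k, idxs in enumerate(splits)}
    out = {f"out_s{k + 1}": [_Entry(f"Out_{fams[i]}", fams[i], "wgd", None)
                             for i in idxs if outgroup_present[i]]
           for k, idxs in enumerate(splits)}

    protected: dict = {}
    used: set = set()
    events = []
    ancient_genes: list = []
    novel_fams: dict = {}

    def scaffolds_of(sub):
        return sorted(s for s, lst in tet.items() if lst and lst[0].subgenome == sub)

    def ok_insert(scaf, idx):
        for a, b in protected.get(scaf, []):
            lst = tet[scaf]
            ids = [e.gene_id for e in lst]
            try:
                ia, ib = ids.index(a), ids.index(b)
            except ValueError:
                continue
            if min(ia, ib) < idx <= max(ia, ib):
                return False
        return True

    def random_insert(sub, entry_or_list, exclude_scaf=None, max_tries=200):
        cands = [s for s in scaffolds_of(sub) if s != exclude_scaf and not s.startswith("tet_anc")]
        if not cands:
            cands = [s for s in scaffolds_of(sub) if s != exclude_scaf]
        for _ in range(max_tries):
            scaf = cands[rng.integers(0, len(cands))]
            idx = int(rng.integers(0, len(tet[scaf]) + 1))
            if ok_insert(scaf, idx):
                block = entry_or_list if isinstance(entry_or_list, list) else [entry_or_list]
                tet[scaf][idx:idx] = block
                return scaf, idx
        raise ConfigurationError("could not place a duplicate copy; genome too constrained")

    def eligible_donors(sub=None, require_diploid=False):
        pool = []
        for scaf in sorted(tet):
            for e in tet[scaf]:
                if e.origin != "wgd" or e.gene_id in used:
                    continue
                if sub is not None and e.subgenome != sub:
                    continue
                if require_diploid and not diploid_present[fam_index[e.family]]:
                    continue
                pool.append(e)
        return pool

    def pick_run(length, sub):
        """A run of `length` consecutive unused ancestral-locus genes."""
        cands = []
        for scaf in scaffolds_of(sub):
            lst = tet[scaf]
            for i in range(len(lst) - length + 1):
                window = lst[i:i + length]
                if all(e.origin == "wgd" and e.gene_id not in used for e in window):
                    cands.append((scaf, i))
        if not cands:
            raise ConfigurationError(
                f"no run of {length} unused collinear genes available for planting")
        scaf, i = cands[rng.integers(0, len(cands))]
        return scaf, i

    fam_index = {f: i for i, f in enumerate(fams)}

    # segmental duplications: copy a run of genes to another scaffold
    for e_i in range(config.ssd_counts.get("segmental", 0)):
        sub = ("A", "B")[rng.integers(0, 2)]
        scaf, i = pick_run(config.segment_genes, sub)
        donors = tet[scaf][i:i + config.segment_genes]
        copies = [_Entry(f"{d.gene_id}_sg{e_i + 1}", d.family, "segmental", sub)
                  for d in donors]
        random_insert(sub, copies, exclude_scaf=scaf)
        for d, c in zip(donors, copies):
            used.update({d.gene_id, c.gene_id})
            events.append({"mode": "segmental", "donor": d.gene_id,
                           "copy": c.gene_id, "family": d.family})

    # ancient-collinear emulation: extra collinear copies of a run, each on
    # its own scaffold, so run members are covered by > 4 blocks
    for r in range(config.ancient_runs):
        if config.ancient_extra_copies == 0 or config.ancient_run_genes == 0:
            break
        scaf, i = pick_run(config.ancient_run_genes, "A")
        donors = tet[scaf][i:i + config.ancient_run_genes]
        for d in donors:
            used.add(d.gene_id)
        ancient_genes.extend(d.gene_id for d in donors)
        for c_i in range(config.ancient_extra_copies):
            copies = [_Entry(f"{d.gene_id}_ac{r + 1}_{c_i + 1}", d.family, "ancient_copy", "A")
                      for d in donors]
            tet[f"tet_anc{r + 1}_{c_i + 1}A"] = copies
            ancient_genes.extend(c.gene_id for c in copies)
            for c in copies:
                used.add(c.gene_id)

    def plant_single(mode, suffix, e_i, max_tries=100):
        sub = ("A", "B")[rng.integers(0, 2)]
        pool = eligible_donors(sub=sub, require_diploid=(mode == "transposed"))
        if not pool:
            pool = eligible_donors(require_diploid=(mode == "transposed"))
        if not pool:
            raise ConfigurationError(f"ssd counts exceed the eligible gene pool ({mode})")
        for _ in range(max_tries):
            donor = pool[rng.integers(0, len(pool))]
            scaf, idx = _find(tet, donor.gene_id)
            copy = _Entry(f"{donor.gene_id}_{suffix}{e_i + 1}", donor.family, mode,
                          donor.subgenome)
            if mode == "tandem":
                if not ok_insert(scaf, idx + 1):
                    continue
                tet[scaf].insert(idx + 1, copy)
                protected.setdefault(scaf, []).append((donor.gene_id, copy.gene_id))
            elif mode == "proximal":
                gap = int(rng.integers(2, config.proximal_max_gap + 1))
                pos = idx + gap
                if pos > len(tet[scaf]) or not ok_insert(scaf, pos):
                    continue  # keep the planted rank gap strictly in (1, max]
                tet[scaf].insert(pos, copy)
                protected.setdefault(scaf, []).append((donor.gene_id, copy.gene_id))
            elif mode == "transposed":
                random_insert(donor.subgenome, copy, exclude_scaf=scaf)
            used.update({donor.gene_id, copy.gene_id})
            events.append({"mode": mode, "donor": donor.gene_id,
                           "copy": copy.gene_id, "family": donor.family})
            return
        raise ConfigurationError(f"could not place a {mode} duplicate after {max_tries} tries")

    for e_i in range(config.ssd_counts.get("tandem", 0)):
        plant_single("tandem", "td", e_i)
    for e_i in range(config.ssd_counts.get("proximal", 0)):
        plant_single("proximal", "px", e_i)
    for e_i in range(config.ssd_counts.get("transposed", 0)):
        plant_single("transposed", "tp", e_i)

    # dispersed: a novel two-copy family at unrelated positions
    for e_i in range(config.ssd_counts.get("dispersed", 0)):
        fam = f"nov{e_i + 1:03d}"
        sub = ("A", "B")[rng.integers(0, 2)]
        c1 = _Entry(f"Pg{sub}_{fam}a", fam, "dispersed", sub)
        c2 = _Entry(f"Pg{sub}_{fam}b", fam, "dispersed", sub)
        s1, _ = random_insert(sub, c1)
        random_insert(sub, c2, exclude_scaf=s1)
        novel_fams[fam] = "dispersed"
        used.update({c1.gene_id, c2.gene_id})
        events.append({"mode": "dispersed", "donor": c1.gene_id,
                       "copy": c2.gene_id, "family": fam})

    # lineage-specific families: one tetraploid + one diploid member, absent
    # from the outgroup
    lineage_families: dict = {}
    for e_i in range(config.n_lineage_specific):
        fam = f"lin{e_i + 1:03d}"
        sub = ("A", "B")[rng.integers(0, 2)]
        te = _Entry(f"Pg{sub}_{fam}", fam, "lineage", sub)
        random_insert(sub, te)
        dscafs = sorted(dip)
        dscaf = dscafs[rng.integers(0, len(dscafs))]
        de = _Entry(f"Pn_{fam}", fam, "lineage", None)
        dip[dscaf].insert(int(rng.integers(0, len(dip[dscaf]) + 1)), de)
        novel_fams[fam] = "lineage"
        lineage_families[fam] = [te.gene_id, de.gene_id]

    # --- truth: group categories
    cat = []
    for i in range(n):
        a, b, d = presentA[i], presentB[i], diploid_present[i]
        if a and b:
            cat.append("triplet" if d else "doublet")
        elif (a or b) and d:
            cat.append("singleton")
        elif a or b:
            cat.append("orphan")
        else:
            cat.append("no_tetraploid")
    group_rows = []
    for i, f in enumerate(fams):
        if cat[i] in ("singleton", "doublet", "triplet"):
            group_rows.append({
                "family": f, "category": cat[i],
                "diploid_gene": f"Pn_{f}" if diploid_present[i] else None,
                "gene_A": f"PgA_{f}" if presentA[i] else None,
                "gene_B": f"PgB_{f}" if presentB[i] else None,
            })
    groups_df = pd.DataFrame(group_rows,
                             columns=["family", "category", "diploid_gene", "gene_A", "gene_B"])

    ancient_set = set(ancient_genes)
    ancient_fams = {e.family for lst in tet.values() for e in lst
                    if e.gene_id in ancient_set}

    def fam_class(f):
        if f in novel_fams and novel_fams[f] == "dispersed":
            return "dispersed"
        if f in ancient_fams:
            return "ancient_collinear"
        if f in fam_index:
            c = cat[fam_index[f]]
            if c in ("singleton", "doublet", "triplet"):
                return c
        return "default"

    # --- per-family evolutionary parameters
    def branch(b):
        return BASE_BRANCH[b] * config.divergence_scale.get(b, 1.0)

    omega: dict = {}
    all_fams = fams + sorted(novel_fams)
    for f in all_fams:
        cls = fam_class(f)
        mu, sd = config.omega_class.get(cls, config.omega_class["default"])
        omega[f] = float(np.clip(rng.normal(mu, sd), 0.02, 1.5))

    # --- sequence evolution
    n_codons = config.gene_length_bp // 3
    ref_seqs = {TETRAPLOID_TAXON: {}, DIPLOID_TAXON: {}, OUTGROUP_TAXON: {}}
    species_seqs = {sp: {} for sp in ALL_SPECIES}

    fam_nodes: dict = {}
    for i, f in enumerate(fams):
        w = omega[f]
        root = _random_cds(rng, n_codons)
        t = _mutate(root, branch("stem"), w, rng)
        fam_nodes[f] = {
            "root": root,
            "A": _mutate(t, branch("subgenome"), w, rng),
            "B": _mutate(t, branch("subgenome"), w, rng),
        }
        if diploid_present[i]:
            seq = _mutate(root, branch("notoginseng"), w, rng)
            ref_seqs[DIPLOID_TAXON][f"Pn_{f}"] = seq
            species_seqs[DIPLOID_SPECIES][f"Pn_{f}"] = seq
        if outgroup_present[i]:
            ref_seqs[OUTGROUP_TAXON][f"Out_{f}"] = _mutate(root, branch("outgroup"), w, rng)
    for f in sorted(novel_fams):
        root = _random_cds(rng, n_codons)
        fam_nodes[f] = {"root": root, "A": root, "B": root}
        if novel_fams[f] == "lineage":
            seq = _mutate(root, branch("notoginseng"), omega[f], rng)
            ref_seqs[DIPLOID_TAXON][f"Pn_{f}"] = seq
            species_seqs[DIPLOID_SPECIES][f"Pn_{f}"] = seq

    for scaf in sorted(tet):
        for e in tet[scaf]:
            w = omega[e.family]
            base = fam_nodes[e.family][e.subgenome]
            if e.origin != "wgd":
                base = _mutate(base, config.ssd_divergence, w, rng)
            for sp in TETRAPLOID_SPECIES:
                tip = _mutate(base, branch(sp), w, rng)
                species_seqs[sp][e.gene_id] = tip
                if sp == "ginseng":
                    ref_seqs[TETRAPLOID_TAXON][e.gene_id] = tip

    # --- finalize gene models
    genes = {TETRAPLOID_TAXON: {}, DIPLOID_TAXON: {}, OUTGROUP_TAXON: {}}
    gene_order = {TETRAPLOID_TAXON: {}, DIPLOID_TAXON: {}, OUTGROUP_TAXON: {}}
    meta_rows = []
    L = config.gene_length_bp
    step = L + config.intergenic_bp
    for taxon, scafs in ((TETRAPLOID_TAXON, tet), (DIPLOID_TAXON, dip), (OUTGROUP_TAXON, out)):
        for scaf in sorted(scafs):
            order = []
            for rank, e in enumerate(scafs[scaf]):
                start = rank * step + config.intergenic_bp + 1
                gm = GeneModel(gene_id=e.gene_id, scaffold=scaf, start=start,
                               end=start + L - 1, strand="+", taxon=taxon,
                               subgenome=e.subgenome, rank=rank)
                genes[taxon][e.gene_id] = gm
                order.append(e.gene_id)
                meta_rows.append({
                    "gene_id": e.gene_id, "taxon": taxon, "scaffold": scaf,
                    "subgenome": e.subgenome, "family": e.family, "origin": e.origin,
                    "meth_class": ("dispersed" if e.origin == "dispersed" else
                                   "ancient_collinear" if e.gene_id in ancient_set else
                                   fam_class(e.family) if e.origin in ("wgd",) else "default"),
                })
            gene_order[taxon][scaf] = order

    # --- homolog hit/anchor table (all annotated members of each family)
    members: dict = {}
    for row in meta_rows:
        members.setdefault(row["family"], []).append((row["gene_id"], row["taxon"]))

    def seq_of(gid, taxon):
        return ref_seqs[taxon][gid]

    anchors = []
    for f in sorted(members):
        mem = sorted(members[f])
        for (g1, t1), (g2, t2) in itertools.combinations(mem, 2):
            s1, s2 = seq_of(g1, t1), seq_of(g2, t2)
            ident = float(np.mean(np.frombuffer(s1.encode(), dtype="u1")
                                  == np.frombuffer(s2.encode(), dtype="u1")))
            anchors.append(AnchorPair(g1, g2, round(100.0 * ident, 2)))

    truth = TruthTable(
        genes=pd.DataFrame(meta_rows),
        groups=groups_df,
        ssd_events=pd.DataFrame(events, columns=["mode", "donor", "copy", "family"]),
        ancient_genes=sorted(ancient_set),
        lineage_families={**lineage_families,
                          **{e["family"]: [e["donor"], e["copy"]]
                             for e in events if e["mode"] == "dispersed"}},
        category_counts=dict(pd.Series(cat).value_counts()),
        n_losses=int(lostA.sum() + lostB.sum()),
        n_gains=sum(1 for r in meta_rows
                    if r["taxon"] == TETRAPLOID_TAXON and r["origin"] != "wgd"),
    )
    genomes = SimulatedGenomes(config=config, genes=genes, gene_order=gene_order,
                               ref_seqs=ref_seqs, species_seqs=species_seqs,
                               anchors=anchors)
    return genomes, truth


# --- population variant simulation ------------------------------------------

def simulate_population_variants(genomes: SimulatedGenomes, truth: TruthTable,
                                 config: Optional[SimulationConfig] = None) -> PopulationData:
    """Simulate per-species haplotype matrices with planted diversity.

    Haplotypes carry the species consensus sequence plus biallelic
    polymorphisms planted at per-site rate 2*pi (allele frequency 1/2 in
    expectation), giving unbiased expected per-gene pi. A configurable
    fraction of sites is planted with failing MQ/DP metadata and noisy
    genotypes so the variant filter has something to remove. Mean read
    depths per gene (for presence/absence analysis) are drawn around the
    genome median, with planted absent genes near zero.
    """
    config = config or genomes.config
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    L = config.gene_length_bp
    base_idx = {b: i for i, b in enumerate(NUCS)}

    # per-gene diversity multiplier, shared across species
    fam_cat = dict(zip(truth.groups["family"], truth.groups["category"]))
    gmeta = truth.genes.set_index("gene_id")
    pi_factor: dict = {}
    for taxon in (TETRAPLOID_TAXON, DIPLOID_TAXON):
        for gid in sorted(genomes.genes[taxon]):
            fam = gmeta.loc[gid, "family"]
            cls = "singleton" if fam_cat.get(fam) == "singleton" else "default"
            sd = config.pi_gene_sd.get(cls, config.pi_gene_sd["default"])
            mult = config.pi_gene_mult.get(cls, config.pi_gene_mult["default"])
            pi_factor[gid] = mult * float(np.exp(rng.normal(0.0, sd) - sd * sd / 2.0))

    matrices: dict = {}
    absent: dict = {sp: set() for sp in ALL_SPECIES}
    depth_rows = []
    median_depth = {sp: float(config.depth_median) for sp in ALL_SPECIES}

    for sp in ALL_SPECIES:
        n_acc = int(config.n_accessions.get(sp, 0))
        if n_acc <= 0:
            raise ConfigurationError(f"species {sp} has no accessions configured")
        n_hap = 2 * n_acc
        ref_taxon = MAPPING_REFERENCE[sp]
        ref_gene_ids = sorted(genomes.genes[ref_taxon])
        if sp in config.n_absent and config.n_absent[sp] > 0:
            pool = [g for g in ref_gene_ids]
            k = min(config.n_absent[sp], len(pool))
            absent[sp] = set(rng.choice(pool, size=k, replace=False))
        pi_t = float(config.species_pi.get(sp, 0.0))

        out: dict = {}
        for gid in ref_gene_ids:
            ref = genomes.ref_seqs[ref_taxon][gid]
            if gid in absent[sp]:
                depth_rows.append({"gene_id": gid, "species": sp,
                                   "mean_depth": float(rng.uniform(0.0, 0.08 * median_depth[sp]))})
                continue
            depth_rows.append({"gene_id": gid, "species": sp,
                               "mean_depth": float(rng.normal(median_depth[sp],
                                                              0.08 * median_depth[sp]))})
            cons = genomes.species_seqs[sp].get(gid)
            if cons is None:
                continue
            cons_arr = np.array(list(cons), dtype="<U1")
            ref_arr = np.array(list(ref), dtype="<U1")

            p_poly = min(0.5, 2.0 * pi_t * pi_factor[gid])
            poly = rng.random(L) < p_poly
            fixed = cons_arr != ref_arr
            keep = poly | fixed
            pos = np.flatnonzero(keep) + 1
            n_sites = len(pos)
            alle = np.tile(cons_arr[keep], (n_hap, 1))
            # planted polymorphism at frequency ~ 1/2
            poly_here = poly[keep]
            for j in np.flatnonzero(poly_here):
                cur = alle[0, j]
                alts = [b for b in NUCS if b != cur]
                derived = alts[rng.integers(0, 3)]
                carriers = rng.random(n_hap) < 0.5
                alle[carriers, j] = derived
            mq = np.clip(rng.normal(55.0, 5.0, n_sites), 31.0, None)
            dp = np.maximum(rng.poisson(config.read_depth_mean, n_sites), 4)

            # planted low-quality noise records
            free = np.flatnonzero(~keep)
            n_bad = rng.binomial(len(free), config.low_quality_frac) if len(free) else 0
            if n_bad > 0:
                bad_pos = np.sort(rng.choice(free, size=n_bad, replace=False))
                bad_alle = np.tile(cons_arr[bad_pos], (n_hap, 1))
                for j in range(n_bad):
                    cur = bad_alle[0, j]
                    alts = [b for b in NUCS if b != cur]
                    derived = alts[rng.integers(0, 3)]
                    carriers = rng.random(n_hap) < 0.5
                    bad_alle[carriers, j] = derived
                bad_mq = np.empty(n_bad)
                bad_dp = np.empty(n_bad, dtype=int)
                fail_mq = rng.random(n_bad) < 0.5
                bad_mq[fail_mq] = rng.uniform(5.0, 30.0, fail_mq.sum())
                bad_dp[fail_mq] = np.maximum(rng.poisson(config.read_depth_mean, fail_mq.sum()), 4)
                bad_mq[~fail_mq] = np.clip(rng.normal(55.0, 5.0, (~fail_mq).sum()), 31.0, None)
                bad_dp[~fail_mq] = rng.integers(0, 4, (~fail_mq).sum())

                pos = np.concatenate([pos, bad_pos + 1])
                order = np.argsort(pos)
                alle = np.concatenate([alle, bad_alle], axis=1)[:, order]
                mq = np.concatenate([mq, bad_mq])[order]
                dp = np.concatenate([dp, bad_dp])[order]
                pos = pos[order]

            if config.missing_rate > 0 and alle.size:
                alle[rng.random(alle.shape) < config.missing_rate] = "N"

            out[gid] = GenotypeMatrix(gene_id=gid, species=sp, alleles=alle,
                                      positions=pos, mq=mq, dp=dp,
                                      gene_length_bp=L, ref_seq=ref)
        matrices[sp] = out

    # realized per-species mean pi after the standard filter
    for sp in ALL_SPECIES:
        vals = [nucleotide_diversity(filter_variants(m)) for m in matrices[sp].values()]
        vals = [v for v in vals if v == v]
        truth.realized_pi[sp] = float(np.mean(vals)) if vals else float("nan")

    depth = pd.DataFrame(depth_rows, columns=["gene_id", "species", "mean_depth"])
    return PopulationData(matrices=matrices, depth=depth,
                          median_depth=median_depth, absent=absent)


# --- methylome simulation ---------------------------------------------------

def _cytosine_sites(seq: str):
    """Gene-body cytosines on both strands with CG/CHG/CHH context."""
    out = []  # (offset, strand, context)
    L = len(seq)
    for i, b in enumerate(seq):
        if b == "C":
            if i + 1 >= L:
                continue
            if seq[i + 1] == "G":
                ctx = "CG"
            elif i + 2 >= L:
                continue
            elif seq[i + 2] == "G":
                ctx = "CHG"
            else:
                ctx = "CHH"
            out.append((i, "+", ctx))
        elif b == "G":
            if i - 1 < 0:
                continue
            if seq[i - 1] == "C":
                ctx = "CG"
            elif i - 2 < 0:
                continue
            elif seq[i - 2] == "C":
                ctx = "CHG"
            else:
                ctx = "CHH"
            out.append((i, "-", ctx))
    return out


def simulate_methylomes(genomes: SimulatedGenomes, truth: TruthTable,
                        config: Optional[SimulationConfig] = None) -> MethylomeData:
    """Simulate per-sample bisulfite count matrices with planted structure.

    Per-site counts are binomial draws at Poisson coverage around a
    hierarchical gene-level mean: class mean (by true duplicate class) +
    gene effect + inherited subgenome-copy effect (shared by the three
    tetraploid species — the asymmetry signature) + species effect +
    tetraploid-clade effect + replicate effect. DMGs are planted per
    species pair with a level difference dmg_high - dmg_low; a fraction
    asym_frac of doublet groups gets a fixed A-B offset with the same sign
    in all three tetraploids. Updates ``truth.dmg`` and ``truth.asym``.
    """
    config = config or genomes.config
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 2]))
    gmeta = truth.genes.set_index("gene_id")

    # --- choose planted DMG genes per species pair
    fam_cat = dict(zip(truth.groups["family"], truth.groups["category"]))
    triplet_fams = sorted(truth.groups.loc[truth.groups["category"] == "triplet", "family"])
    tet_gene_ids = sorted(genomes.genes[TETRAPLOID_TAXON])
    used_fams: set = set()
    dmg_truth: dict = {}
    pairs = list(itertools.combinations(ALL_SPECIES, 2))
    for sp1, sp2 in pairs:
        chosen = []
        if DIPLOID_SPECIES in (sp1, sp2):
            cands = [f for f in triplet_fams if f not in used_fams]
            if len(cands) < config.n_dmg:
                raise ConfigurationError(
                    f"cannot plant {config.n_dmg} DMGs for pair ({sp1},{sp2}): "
                    f"only {len(cands)} unused triplet families")
            for f in rng.choice(cands, size=config.n_dmg, replace=False):
                used_fams.add(f)
                chosen.append((f"PgA_{f}", f"Pn_{f}"))
        else:
            cands = [g for g in tet_gene_ids
                     if gmeta.loc[g, "family"] not in used_fams]
            if len(cands) < config.n_dmg:
                raise ConfigurationError(
                    f"cannot plant {config.n_dmg} DMGs for pair ({sp1},{sp2})")
            for g in rng.choice(cands, size=config.n_dmg, replace=False):
                used_fams.add(gmeta.loc[g, "family"])
                chosen.append((g, g))
        dmg_truth[(sp1, sp2)] = chosen
    truth.dmg = dmg_truth

    override: dict = {}  # (gene_id, species) -> level
    for (sp1, sp2), genes_list in dmg_truth.items():
        for g1, g2 in genes_list:
            override[(g1, sp1)] = config.dmg_high
            override[(g2, sp2)] = config.dmg_low

    # --- planted subgenome asymmetry on doublet/triplet groups
    doublet_fams = sorted(truth.groups.loc[
        truth.groups["category"].isin(["doublet", "triplet"]), "family"])
    asym_cands = [f for f in doublet_fams if f not in used_fams]
    n_asym = int(round(config.asym_frac * len(asym_cands)))
    asym_fams = sorted(rng.choice(asym_cands, size=n_asym, replace=False)) if n_asym else []
    asym_sign = {f: (1 if rng.random() < 0.5 else -1) for f in asym_fams}
    truth.asym = pd.DataFrame(
        [{"family": f, "gene_A": f"PgA_{f}", "gene_B": f"PgB_{f}", "sign": asym_sign[f]}
         for f in asym_fams], columns=["family", "gene_A", "gene_B", "sign"])

    # --- hierarchical effects
    fams_all = sorted(set(gmeta["family"]))
    u_eff, t_eff, v_eff, w_eff, sc_eff = {}, {}, {}, {}, {}
    for f in fams_all:
        cls = "singleton" if fam_cat.get(f) == "singleton" else "default"
        sd_u = config.meth_gene_sd.get(cls, config.meth_gene_sd["default"])
        for ctx in CONTEXTS:
            u_eff[(f, ctx)] = rng.normal(0.0, sd_u)
            t_eff[(f, ctx)] = rng.normal(0.0, config.meth_clade_sd)
            for sub in ("A", "B"):
                if f in asym_sign:
                    v_eff[(f, sub, ctx)] = asym_sign[f] * config.asym_offset / 2.0 * (1 if sub == "A" else -1)
                else:
                    v_eff[(f, sub, ctx)] = rng.normal(0.0, config.meth_copy_sd)
            for sp in ALL_SPECIES:
                w_eff[(f, sp, ctx)] = rng.normal(0.0, config.meth_species_sd)
                for sub in ("A", "B"):
                    sc_eff[(f, sub, sp, ctx)] = rng.normal(0.0, config.meth_species_copy_sd)

    def gene_mean(gid, sp, ctx):
        if (gid, sp) in override:
            return override[(gid, sp)]
        row = gmeta.loc[gid]
        f = row["family"]
        cls = row["meth_class"]
        base = config.meth_class_means.get(cls, config.meth_class_means["default"])[ctx]
        m = base + u_eff[(f, ctx)] + w_eff[(f, sp, ctx)]
        if sp in TETRAPLOID_SPECIES:
            m += t_eff[(f, ctx)]
            sub = row["subgenome"]
            if sub in ("A", "B"):
                m += v_eff[(f, sub, ctx)] + sc_eff[(f, sub, sp, ctx)]
        return m

    # --- per-site counts
    matrices: dict = {}
    for sp in ALL_SPECIES:
        ref_taxon = MAPPING_REFERENCE[sp]
        samples = [f"{sp}_r{j + 1}" for j in range(int(config.n_meth_replicates))]
        site_rows = []
        p_cols = {s: [] for s in samples}
        for scaf in sorted(genomes.gene_order[ref_taxon]):
            for gid in genomes.gene_order[ref_taxon][scaf]:
                gm = genomes.genes[ref_taxon][gid]
                seq = genomes.ref_seqs[ref_taxon][gid]
                sites = _cytosine_sites(seq)
                means = {ctx: gene_mean(gid, sp, ctx) for ctx in CONTEXTS}
                rep_shift = {s: {ctx: rng.normal(0.0, config.meth_replicate_sd)
                                 for ctx in CONTEXTS} for s in samples}
                for off, strand, ctx in sites:
                    site_rows.append((scaf, gm.start + off, strand, ctx, gid))
                for s in samples:
                    p_cols[s].extend(
                        float(np.clip(means[ctx] + rep_shift[s][ctx], 0.0, 1.0))
                        for _, _, ctx in sites)
        sites_df = pd.DataFrame(site_rows,
                                columns=["scaffold", "pos", "strand", "context", "gene_id"])
        n_sites = len(sites_df)
        meth = np.zeros((n_sites, len(samples)), dtype=np.int64)
        total = np.zeros_like(meth)
        for j, s in enumerate(samples):
            cov = rng.poisson(config.read_depth_mean, n_sites)
            p = np.asarray(p_cols[s])
            meth[:, j] = rng.binomial(cov, p)
            total[:, j] = cov
        matrices[sp] = MethylomeMatrix(sites_df, meth, total, samples,
                                       {s: sp for s in samples})
    return MethylomeData(matrices=matrices)
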