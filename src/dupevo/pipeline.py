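"""End-to-end pipeline orchestration.

Stages run in dependency order (simulate -> classify -> popgen ->
methylome -> compare), each reading and writing plain-text files under the
output directory, with a manifest of SHA-256 checksums for reproducibility
checks. A single YAML config (strict schema: unknown and duplicate keys
rejected) drives everything; every stage can also be run on its own.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import os
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .compare import (compare_classes, enrichment_hypergeometric,
                      fractionation_bias_test, subgenome_asymmetry)
from .methylome import (assign_genes, call_dmgs, filter_sites, gene_methylation_levels,
                        profile_correlation, read_cx_reports, write_cx_report)
from .models import ConfigurationError, InputError, OrthoGroup
from .popgen import (dxy, filter_variants, gene_presence_by_depth, ng86_dnds,
                     nucleotide_diversity, read_vcf_genotypes)
from .synteny import (chain_anchors, classify_ssd_modes, classify_wgd_groups,
                      cluster_families, collinear_depth)
from .synthetic import (ALL_SPECIES, DIPLOID_SPECIES, DIPLOID_TAXON, FOCAL_TAXA,
                        MAPPING_REFERENCE, OUTGROUP_TAXON, TETRAPLOID_SPECIES,
                        TETRAPLOID_TAXON, SimulationConfig, simulate_genomes,
                        simulate_methylomes, simulate_population_variants)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "classify", "popgen", "methylome", "compare")


class PipelineError(RuntimeError):
    """A stage dependency or execution failure."""


# --- configuration ----------------------------------------------------------

def _simulate_defaults() -> dict:
    cfg = SimulationConfig()
    return {f: getattr(cfg, f) for f in cfg.__dataclass_fields__ if f != "seed"}


def default_config() -> dict:
    return {
        "seed": 0,
        "outdir": "dupevo_out",
        "log_level": "INFO",
        "threads": 1,
        "stages": {s: True for s in STAGES},
        "simulate": _simulate_defaults(),
        "classify": {"min_block_anchors": 5, "max_gene_gap": 25, "gap_penalty": 1.0,
                     "proximal_max_rank_gap": 10, "ancient_min_depth": 4},
        "popgen": {"min_mq": 30.0, "min_dp": 3, "presence_rel_threshold": 0.2,
                   "max_dxy_genes": 400},
        "methylome": {"min_total_depth": 10, "n_windows": 20, "delta_within_max": 0.10,
                      "delta_between_min": 0.50, "frac_windows_min": 0.10,
                      "alpha": 0.01, "contexts": ["CG"]},
        "compare": {"alpha": 0.05},
    }


class _StrictLoader(yaml.SafeLoader):
    pass


def _strict_mapping(loader, node, deep=False):
    mapping = {}
    for k_node, v_node in node.value:
        key = loader.construct_object(k_node, deep=deep)
        if key in mapping:
            raise ConfigurationError(
                f"duplicate config key {key!r} at line {k_node.start_mark.line + 1}")
        mapping[key] = loader.construct_object(v_node, deep=deep)
    return mapping


_StrictLoader.add_constructor(yaml.resolver.BaseResolver.DEFAULT_MAPPING_TAG, _strict_mapping)


def _merge(defaults, user, path=""):
    if not isinstance(user, dict):
        raise ConfigurationError(f"config section {path or '<root>'} must be a mapping")
    unknown = set(user) - set(defaults)
    if unknown:
        raise ConfigurationError(
            f"unknown config key{'s' if len(unknown) > 1 else ''} "
            f"{sorted(unknown)} in section {path or '<root>'}")
    out = {}
    for k, v in defaults.items():
        if k not in user:
            out[k] = v
        elif isinstance(v, dict) and not k == "stages" and path == "" and k in (
                "simulate", "classify", "popgen", "methylome", "compare"):
            out[k] = _merge(v, user[k], f"{path}{k}.")
        elif isinstance(v, dict) and isinstance(user[k], dict):
            merged = dict(v)
            bad = set(user[k]) - set(v)
            if k in ("stages",) and bad:
                raise ConfigurationError(f"unknown stage name(s) {sorted(bad)}")
            merged.update(user[k])
            out[k] = merged
        else:
            out[k] = user[k]
    return out


def validate_config(path: Optional[str] = None, overrides: Optional[dict] = None) -> dict:
    """Load, default-fill and validate a pipeline config.

    Unknown keys, duplicate keys and out-of-range values raise
    ConfigurationError naming the offending key; a missing path yields the
    full default config.
    """
    user: dict = {}
    if path is not None:
        try:
            with open(path) as fh:
                user = yaml.load(fh, Loader=_StrictLoader) or {}
        except yaml.YAMLError as e:
            mark = getattr(e, "problem_mark", None)
            line = f" at line {mark.line + 1}" if mark else ""
            raise ConfigurationError(f"cannot parse config {path}{line}: {e}") from e
    cfg = _merge(default_config(), user)
    if overrides:
        cfg.update({k: v for k, v in overrides.items() if v is not None})
    # cross-field validation
    sim = SimulationConfig(seed=int(cfg["seed"]), **cfg["simulate"])
    sim.validate()
    for key in ("alpha",):
        a = cfg["methylome"][key]
        if not (0 < a < 1):
            raise ConfigurationError(f"methylome.{key} must be in (0, 1), got {a}")
    if not (0 < cfg["compare"]["alpha"] < 1):
        raise ConfigurationError("compare.alpha must be in (0, 1)")
    bad_ctx = set(cfg["methylome"]["contexts"]) - {"CG", "CHG", "CHH"}
    if bad_ctx:
        raise ConfigurationError(f"methylome.contexts: unknown context(s) {sorted(bad_ctx)}")
    return cfg


def _sim_config(cfg: dict) -> SimulationConfig:
    return SimulationConfig(seed=int(cfg["seed"]), **cfg["simulate"])


def _require(outdir, *relpaths):
    missing = [p for p in relpaths if not os.path.exists(os.path.join(outdir, p))]
    if missing:
        raise PipelineError(
            f"missing upstream output(s) {missing}; run the producing stage first")


# --- stage: simulate --------------------------------------------------------

def stage_simulate(cfg: dict) -> list:
    out = cfg["outdir"]
    sim = _sim_config(cfg)
    genomes, truth = simulate_genomes(sim)
    pop = simulate_population_variants(genomes, truth, sim)
    meth = simulate_methylomes(genomes, truth, sim)
    written = []

    gdir = dio.ensure_dir(os.path.join(out, "genomes"))
    rng = np.random.default_rng(np.random.SeedSequence([int(sim.seed), 3]))
    for taxon in (TETRAPLOID_TAXON, DIPLOID_TAXON, OUTGROUP_TAXON):
        gff = os.path.join(gdir, f"{taxon}.gff3")
        dio.write_gff3(genomes.genes[taxon].values(), gff)
        written.append(gff)
        fasta = os.path.join(gdir, f"{taxon}.fasta")
        scafs = {s: genomes.scaffold_sequence(taxon, s, rng)
                 for s in sorted(genomes.gene_order[taxon])}
        dio.write_fasta(scafs, fasta)
        written.append(fasta)
    p = os.path.join(gdir, "anchors.tsv")
    dio.write_anchor_table(genomes.anchors, p)
    written.append(p)
    p = os.path.join(gdir, "subgenome_map.tsv")
    dio.write_subgenome_map(genomes.genes[TETRAPLOID_TAXON], p)
    written.append(p)

    vdir = dio.ensure_dir(os.path.join(out, "vcf"))
    for sp in ALL_SPECIES:
        samples = [f"{sp}_acc{i + 1}" for i in range(sim.n_accessions[sp])]
        p = os.path.join(vdir, f"{sp}.vcf")
        dio.write_vcf(pop.matrices[sp], genomes.genes[MAPPING_REFERENCE[sp]], samples, p)
        written.append(p)
    p = os.path.join(vdir, "depth.tsv")
    pop.depth.to_csv(p, sep="\t", index=False)
    written.append(p)
    p = os.path.join(vdir, "median_depth.tsv")
    pd.DataFrame(sorted(pop.median_depth.items()),
                 columns=["species", "median_depth"]).to_csv(p, sep="\t", index=False)
    written.append(p)

    mdir = dio.ensure_dir(os.path.join(out, "methylomes"))
    sheet = []
    for sp in ALL_SPECIES:
        m = meth.matrices[sp]
        for s in m.samples:
            p = os.path.join(mdir, f"{s}.cx.tsv")
            write_cx_report(m, s, p)
            written.append(p)
            sheet.append({"sample": s, "species": sp,
                          "replicate": int(s.rsplit("_r", 1)[1]),
                          "reference": MAPPING_REFERENCE[sp]})
    p = os.path.join(mdir, "samples.tsv")
    pd.DataFrame(sheet).to_csv(p, sep="\t", index=False)
    written.append(p)

    adir = dio.ensure_dir(os.path.join(out, "annotation"))
    tet_ids = sorted(genomes.genes[TETRAPLOID_TAXON])
    labels = pd.DataFrame({
        "gene_id": tet_ids,
        "category": [f"K{(i % 12) + 1:02d}" for i in range(len(tet_ids))]})
    p = os.path.join(adir, "functional_labels.tsv")
    labels.to_csv(p, sep="\t", index=False)
    written.append(p)

    tdir = dio.ensure_dir(os.path.join(out, "truth"))
    truth.genes.to_csv(os.path.join(tdir, "genes.tsv"), sep="\t", index=False)
    truth.groups.to_csv(os.path.join(tdir, "groups.tsv"), sep="\t", index=False)
    truth.ssd_events.to_csv(os.path.join(tdir, "ssd_events.tsv"), sep="\t", index=False)
    truth.asym.to_csv(os.path.join(tdir, "asym.tsv"), sep="\t", index=False)
    dmg_rows = [{"species_1": a, "species_2": b, "gene_1": g1, "gene_2": g2}
                for (a, b), lst in sorted(truth.dmg.items()) for g1, g2 in lst]
    pd.DataFrame(dmg_rows, columns=["species_1", "species_2", "gene_1", "gene_2"]).to_csv(
        os.path.join(tdir, "dmg.tsv"), sep="\t", index=False)
    pd.DataFrame(sorted(truth.realized_pi.items()), columns=["species", "pi"]).to_csv(
        os.path.join(tdir, "realized_pi.tsv"), sep="\t", index=False)
    written += [os.path.join(tdir, f) for f in
                ("genes.tsv", "groups.tsv", "ssd_events.tsv", "asym.tsv", "dmg.tsv",
                 "realized_pi.tsv")]
    return written


# --- stage: classify --------------------------------------------------------

def _load_genes(outdir):
    genes = {}
    per_taxon = {}
    for taxon in (TETRAPLOID_TAXON, DIPLOID_TAXON, OUTGROUP_TAXON):
        path = os.path.join(outdir, "genomes", f"{taxon}.gff3")
        if not os.path.exists(path):
            continue
        per_taxon[taxon] = dio.read_gff3(path, taxon)
        genes.update(per_taxon[taxon])
    return genes, per_taxon


def stage_classify(cfg: dict) -> list:
    out = cfg["outdir"]
    _require(out, "genomes/anchors.tsv", f"genomes/{TETRAPLOID_TAXON}.gff3",
             f"genomes/{DIPLOID_TAXON}.gff3")
    pc = cfg["classify"]
    genes, _ = _load_genes(out)
    anchors = dio.read_anchor_table(os.path.join(out, "genomes", "anchors.tsv"))
    blocks = chain_anchors(anchors, genes, min_block_anchors=pc["min_block_anchors"],
                           max_gene_gap=pc["max_gene_gap"], gap_penalty=pc["gap_penalty"])
    groups = classify_wgd_groups(blocks, genes, DIPLOID_TAXON, TETRAPLOID_TAXON)
    depth = collinear_depth(blocks, genes, eudicot_taxa={OUTGROUP_TAXON},
                            ancient_min_depth=pc["ancient_min_depth"])
    ssd = classify_ssd_modes(genes, anchors, blocks, TETRAPLOID_TAXON, DIPLOID_TAXON,
                             proximal_max_rank_gap=pc["proximal_max_rank_gap"])
    fams, lineage = cluster_families(genes, anchors, FOCAL_TAXA)

    cdir = dio.ensure_dir(os.path.join(out, "classify"))
    written = []
    p = os.path.join(cdir, "collinearity.txt")
    dio.write_collinearity(blocks, p)
    written.append(p)
    p = os.path.join(cdir, "orthogroups.tsv")
    pd.DataFrame([{"group_id": g.group_id, "category": g.category,
                   "diploid_gene": g.diploid_gene,
                   "gene_A": g.tetraploid_copies.get("A"),
                   "gene_B": g.tetraploid_copies.get("B")} for g in groups]).to_csv(
        p, sep="\t", index=False)
    written.append(p)

    ssd_label = {l.gene_id: l.label for l in ssd}
    cat_of = {}
    for g in groups:
        for gid in g.tetraploid_copies.values():
            cat_of[gid] = g.category
        if g.diploid_gene:
            cat_of[g.diploid_gene] = g.category
    depth = depth.set_index("gene_id")
    rows = []
    for gid in sorted(genes):
        g = genes[gid]
        rows.append({
            "gene_id": gid, "taxon": g.taxon, "scaffold": g.scaffold,
            "subgenome": g.subgenome, "category": cat_of.get(gid),
            "ssd_mode": ssd_label.get(gid),
            "depth": int(depth.loc[gid, "depth"]),
            "ancient_collinear": bool(depth.loc[gid, "ancient_collinear"]),
            "conserved_eudicot": bool(depth.loc[gid, "conserved_eudicot"]),
            "family": fams.get(gid), "lineage_specific": fams.get(gid) in lineage,
        })
    p = os.path.join(cdir, "gene_classes.tsv")
    pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
    written.append(p)
    return written


# --- stage: popgen ----------------------------------------------------------

def _load_orthogroups(outdir):
    path = os.path.join(outdir, "classify", "orthogroups.tsv")
    df = pd.read_csv(path, sep="\t")
    return df.where(pd.notna(df), None)


def invert_ortholog_map(dip_of: dict) -> dict:
    """Diploid -> tetraploid ortholog map with a deterministic representative.

    Both subgenome copies of a group map to the same diploid gene; the
    inverse keeps the lexicographically smallest tetraploid id (the
    subgenome-A copy under the default naming).
    """
    inv: dict = {}
    for t, d in sorted(dip_of.items()):
        inv.setdefault(d, t)
    return inv


def stage_popgen(cfg: dict) -> list:
    out = cfg["outdir"]
    _require(out, "vcf", "classify/orthogroups.tsv", "genomes")
    pc = cfg["popgen"]
    genes, per_taxon = _load_genes(out)
    seqs = {}
    for taxon in (TETRAPLOID_TAXON, DIPLOID_TAXON):
        scafs = dio.read_fasta(os.path.join(out, "genomes", f"{taxon}.fasta"))
        seqs[taxon] = dio.gene_sequences(per_taxon[taxon].values(), scafs)

    matrices = {}
    for sp in ALL_SPECIES:
        ref = MAPPING_REFERENCE[sp]
        raw = read_vcf_genotypes(os.path.join(out, "vcf", f"{sp}.vcf"),
                                 list(per_taxon[ref].values()), sp, gene_seqs=seqs[ref])
        matrices[sp] = {g: filter_variants(m, pc["min_mq"], pc["min_dp"])
                        for g, m in raw.items()}

    depth_df = pd.read_csv(os.path.join(out, "vcf", "depth.tsv"), sep="\t")
    med = pd.read_csv(os.path.join(out, "vcf", "median_depth.tsv"), sep="\t")
    med = dict(zip(med["species"], med["median_depth"]))
    present = {}
    for r in depth_df.itertuples():
        present[(r.gene_id, r.species)] = gene_presence_by_depth(
            r.mean_depth, med[r.species], pc["presence_rel_threshold"])

    rows = []
    for sp in ALL_SPECIES:
        for gid in sorted(matrices[sp]):
            m = matrices[sp][gid]
            rows.append({"gene_id": gid, "species": sp,
                         "pi": nucleotide_diversity(m),
                         "present": present.get((gid, sp), True)})
    pdir = dio.ensure_dir(os.path.join(out, "popgen"))
    written = []
    p = os.path.join(pdir, "gene_stats.tsv")
    pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
    written.append(p)

    # dxy over all species pairs; cross-reference pairs go through the
    # diploid ortholog from the orthogroup table
    og = _load_orthogroups(out)
    dip_of = {}
    for r in og.itertuples():
        for gid in (r.gene_A, r.gene_B):
            if gid is not None and r.diploid_gene is not None:
                dip_of[gid] = r.diploid_gene
    drows = []
    for sp1, sp2 in itertools.combinations(ALL_SPECIES, 2):
        same_ref = MAPPING_REFERENCE[sp1] == MAPPING_REFERENCE[sp2]
        if same_ref:
            shared = sorted(set(matrices[sp1]) & set(matrices[sp2]))[:pc["max_dxy_genes"]]
            pairs = [(g, g) for g in shared]
        else:
            # orient the tetraploid->diploid ortholog map to (sp1, sp2)
            omap = dip_of if MAPPING_REFERENCE[sp1] == TETRAPLOID_TAXON \
                else invert_ortholog_map(dip_of)
            pairs = sorted((g, omap[g]) for g in omap
                           if g in matrices[sp1] and omap[g] in matrices[sp2])
            pairs = pairs[:pc["max_dxy_genes"]]
        for g1, g2 in pairs:
            drows.append({"gene_id": g1, "gene_id_2": g2, "species_1": sp1,
                          "species_2": sp2,
                          "dxy": dxy(matrices[sp1][g1], matrices[sp2][g2])})
    p = os.path.join(pdir, "dxy.tsv")
    pd.DataFrame(drows).to_csv(p, sep="\t", index=False)
    written.append(p)

    # NG86 dN/dS between each tetraploid gene and its diploid ortholog
    nrows = []
    for gid, dip in sorted(dip_of.items()):
        s1 = seqs[TETRAPLOID_TAXON].get(gid)
        s2 = seqs[DIPLOID_TAXON].get(dip)
        if s1 is None or s2 is None or len(s1) != len(s2):
            continue
        try:
            dn, ds, r = ng86_dnds(s1, s2)
        except InputError:
            continue
        nrows.append({"gene_id": gid, "partner": dip, "dn": dn, "ds": ds, "dn_ds": r})
    p = os.path.join(pdir, "dnds.tsv")
    pd.DataFrame(nrows, columns=["gene_id", "partner", "dn", "ds", "dn_ds"]).to_csv(
        p, sep="\t", index=False)
    written.append(p)
    return written


# --- stage: methylome -------------------------------------------------------

def _load_methylomes(cfg):
    out = cfg["outdir"]
    sheet = pd.read_csv(os.path.join(out, "methylomes", "samples.tsv"), sep="\t")
    _, per_taxon = _load_genes(out)
    matrices = {}
    for sp, sub in sheet.groupby("species"):
        paths = {r.sample: os.path.join(out, "methylomes", f"{r.sample}.cx.tsv")
                 for r in sub.itertuples()}
        m = read_cx_reports(paths, {r.sample: sp for r in sub.itertuples()})
        ref = sub["reference"].iloc[0]
        matrices[sp] = assign_genes(m, per_taxon[ref].values())
    return matrices, per_taxon


def stage_methylome(cfg: dict) -> list:
    out = cfg["outdir"]
    _require(out, "methylomes/samples.tsv", "genomes")
    mc = cfg["methylome"]
    matrices, per_taxon = _load_methylomes(cfg)

    mdir = dio.ensure_dir(os.path.join(out, "methylome"))
    written = []
    levels = []
    for sp in sorted(matrices):
        filt = filter_sites(matrices[sp], mc["min_total_depth"])
        levels.append(gene_methylation_levels(filt))
    levels = pd.concat(levels, ignore_index=True)
    p = os.path.join(mdir, "gene_levels.tsv")
    levels.to_csv(p, sep="\t", index=False)
    written.append(p)

    og = _load_orthogroups(out) if os.path.exists(
        os.path.join(out, "classify", "orthogroups.tsv")) else None
    dip_of = {}
    if og is not None:
        for r in og.itertuples():
            for gid in (r.gene_A, r.gene_B):
                if gid is not None and r.diploid_gene is not None:
                    dip_of[gid] = r.diploid_gene

    calls = []
    for sp1, sp2 in itertools.combinations(sorted(matrices), 2):
        ref1, ref2 = (MAPPING_REFERENCE.get(sp, TETRAPLOID_TAXON) for sp in (sp1, sp2))
        if ref1 == ref2:
            gene_map = None
        elif ref1 == TETRAPLOID_TAXON:
            gene_map = dip_of
        else:
            gene_map = invert_ortholog_map(dip_of)
        if gene_map is not None and not gene_map:
            continue  # no ortholog map available for cross-reference pair
        g1 = per_taxon[ref1]
        g2 = per_taxon[ref2]
        calls.append(call_dmgs(matrices[sp1], matrices[sp2], g1, g2, gene_map=gene_map,
                               contexts=mc["contexts"], n_windows=mc["n_windows"],
                               min_total_depth=mc["min_total_depth"],
                               delta_within_max=mc["delta_within_max"],
                               delta_between_min=mc["delta_between_min"],
                               frac_windows_min=mc["frac_windows_min"],
                               alpha=mc["alpha"]))
    calls = pd.concat(calls, ignore_index=True) if calls else pd.DataFrame()
    p = os.path.join(mdir, "dmg_calls.tsv")
    calls.to_csv(p, sep="\t", index=False)
    written.append(p)

    # sample-sample Spearman correlation of per-gene levels, per context;
    # cross-reference sample pairs are matched through the diploid ortholog
    crows = []
    for ctx in mc["contexts"]:
        sub = levels[levels["context"] == ctx]
        piv = sub.pivot_table(index="gene_id", columns="sample", values="level")
        samples = sorted(piv.columns)
        sp_of = dict(zip(levels["sample"], levels["species"]))
        for s1, s2 in itertools.combinations(samples, 2):
            r1 = MAPPING_REFERENCE.get(sp_of[s1], TETRAPLOID_TAXON)
            r2 = MAPPING_REFERENCE.get(sp_of[s2], TETRAPLOID_TAXON)
            if r1 == r2:
                rho = profile_correlation(piv[s1], piv[s2])
            elif dip_of:
                omap = dip_of if r1 == TETRAPLOID_TAXON else invert_ortholog_map(dip_of)
                x = piv[s1].dropna()
                mapped = pd.Series({g: omap.get(g) for g in x.index}).dropna()
                y = piv[s2].reindex(mapped.values)
                rho = profile_correlation(x.reindex(mapped.index).to_numpy(),
                                          y.to_numpy())
            else:
                continue
            crows.append({"context": ctx, "sample_1": s1, "sample_2": s2,
                          "species_1": sp_of[s1], "species_2": sp_of[s2],
                          "within_species": sp_of[s1] == sp_of[s2], "rho": rho})
    p = os.path.join(mdir, "profile_correlations.tsv")
    pd.DataFrame(crows).to_csv(p, sep="\t", index=False)
    written.append(p)
    return written


# --- stage: compare ---------------------------------------------------------

def stage_compare(cfg: dict) -> list:
    out = cfg["outdir"]
    _require(out, "classify/gene_classes.tsv", "classify/orthogroups.tsv",
             "popgen/gene_stats.tsv", "methylome/gene_levels.tsv")
    classes = pd.read_csv(os.path.join(out, "classify", "gene_classes.tsv"), sep="\t")
    og = _load_orthogroups(out)
    gstats = pd.read_csv(os.path.join(out, "popgen", "gene_stats.tsv"), sep="\t")
    dnds = pd.read_csv(os.path.join(out, "popgen", "dnds.tsv"), sep="\t")
    levels = pd.read_csv(os.path.join(out, "methylome", "gene_levels.tsv"), sep="\t")
    mc = cfg["methylome"]

    # per-gene statistic table for the tetraploid reference genes
    tet = classes[classes["taxon"] == TETRAPLOID_TAXON].set_index("gene_id")
    stats_df = pd.DataFrame(index=tet.index)
    for sp in TETRAPLOID_SPECIES:
        pi = gstats[gstats["species"] == sp].set_index("gene_id")["pi"]
        stats_df[f"pi_{sp}"] = pi
    stats_df["dn_ds"] = dnds.set_index("gene_id")["dn_ds"]
    for ctx in mc["contexts"]:
        lv = levels[(levels["species"] == "ginseng") & (levels["context"] == ctx)]
        stats_df[f"meth_{ctx}"] = lv.groupby("gene_id")["level"].mean()
    stats_df = stats_df.reset_index()

    class_map = {}
    for r in tet.itertuples():
        labels = {"overall"}
        if isinstance(r.category, str):
            labels.add(r.category)
        if isinstance(r.ssd_mode, str):
            labels.add(r.ssd_mode)
        if r.ancient_collinear:
            labels.add("ancient_collinear")
        if r.conserved_eudicot:
            labels.add("conserved_eudicot")
        if r.lineage_specific:
            labels.add("lineage_specific")
        class_map[r.Index] = labels
    statistics = [c for c in stats_df.columns if c != "gene_id"]
    table = compare_classes(stats_df, class_map, statistics)
    cdir = dio.ensure_dir(os.path.join(out, "compare"))
    written = []
    p = os.path.join(cdir, "class_comparison.tsv")
    table.to_csv(p, sep="\t", index=False)
    written.append(p)

    # subgenome asymmetry on doublet/triplet groups across the tetraploids
    ctx0 = mc["contexts"][0]
    lv = levels[levels["context"] == ctx0]
    per_sp = lv.groupby(["gene_id", "species"])["level"].mean().reset_index()
    sub_rows = []
    for r in og.itertuples():
        if r.category not in ("doublet", "triplet"):
            continue
        for sub, gid in (("A", r.gene_A), ("B", r.gene_B)):
            if gid is None:
                continue
            m = per_sp[per_sp["gene_id"] == gid]
            for rr in m.itertuples():
                if rr.species in TETRAPLOID_SPECIES:
                    sub_rows.append({"group_id": r.group_id, "species": rr.species,
                                     "subgenome": sub, "level": rr.level})
    asym = subgenome_asymmetry(pd.DataFrame(sub_rows,
                                            columns=["group_id", "species", "subgenome", "level"]),
                               TETRAPLOID_SPECIES)
    p = os.path.join(cdir, "asymmetry_genes.tsv")
    asym["per_gene"].to_csv(p, sep="\t")
    written.append(p)
    p = os.path.join(cdir, "asymmetry_summary.json")
    with open(p, "w") as fh:
        json.dump({k: asym[k] for k in
                   ("sign_consistency_fraction", "n_excluded",
                    "mean_within_species_between_subgenome",
                    "mean_between_species_same_subgenome")}, fh, indent=2, sort_keys=True)
    written.append(p)

    groups = [OrthoGroup(group_id=r.group_id, diploid_gene=r.diploid_gene,
                         tetraploid_copies={s: g for s, g in
                                            (("A", r.gene_A), ("B", r.gene_B)) if g},
                         category=r.category) for r in og.itertuples()]
    frac = fractionation_bias_test(groups)
    p = os.path.join(cdir, "fractionation.json")
    with open(p, "w") as fh:
        json.dump(frac, fh, indent=2, sort_keys=True)
    written.append(p)

    # enrichment of DMGs against the functional label table, when available
    enr_path = os.path.join(out, "annotation", "functional_labels.tsv")
    dmg_path = os.path.join(out, "methylome", "dmg_calls.tsv")
    erows = []
    if os.path.exists(enr_path) and os.path.exists(dmg_path):
        ann = pd.read_csv(enr_path, sep="\t")
        dmg = pd.read_csv(dmg_path, sep="\t")
        if len(dmg):
            for (sp1, sp2, ctx), sub in dmg.groupby(["species_1", "species_2", "context"]):
                universe = set(sub["gene_id"])
                hits = set(sub.loc[sub["is_dmg"], "gene_id"])
                if not hits:
                    continue
                e = enrichment_hypergeometric(hits, ann, universe)
                e["species_1"], e["species_2"], e["context"] = sp1, sp2, ctx
                erows.append(e)
    enr = pd.concat(erows, ignore_index=True) if erows else pd.DataFrame(
        columns=["category", "k", "K", "n", "N", "p", "q"])
    p = os.path.join(cdir, "enrichment.tsv")
    enr.to_csv(p, sep="\t", index=False)
    written.append(p)
    return written


# --- runner -----------------------------------------------------------------

_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "classify": stage_classify,
    "popgen": stage_popgen,
    "methylome": stage_methylome,
    "compare": stage_compare,
}


def _sha256(path):
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: dict) -> dict:
    """Run the enabled stages in dependency order and write a manifest.

    Returns the manifest: relative output path -> SHA-256 checksum. Rerun
    with the same config and seed reproduces identical checksums.
    """
    logging.basicConfig(level=getattr(logging, str(cfg["log_level"]).upper(), logging.INFO))
    out = cfg["outdir"]
    dio.ensure_dir(out)
    written = []
    for stage in STAGES:
        if not cfg["stages"].get(stage, False):
            logger.info("stage %s disabled", stage)
            continue
        logger.info("running stage %s", stage)
        written += _STAGE_FUNCS[stage](cfg)
    manifest = {os.path.relpath(p, out): _sha256(p) for p in sorted(written)}
    mpath = os.path.join(out, "manifest.json")
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
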