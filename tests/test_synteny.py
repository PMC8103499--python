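"""Anchor chaining, collinear depth, ortholog groups, SSD modes, families."""

import numpy as np
import pandas as pd
import pytest

from dupevo import SimulationConfig, simulate_genomes
from dupevo.models import AnchorPair, InputError, SyntenyBlock
from dupevo.synteny import (_best_chain, chain_anchors, classify_ssd_modes,
                            classify_wgd_groups, cluster_families, collinear_depth)

from _oracles import best_chain_brute
from conftest import anchors_from, make_genes


def two_taxon_genes(n1, n2, taxon2="ty"):
    g1 = make_genes([(f"a{i}", "s1") for i in range(n1)], taxon="tx")
    g2 = make_genes([(f"b{i}", "t1") for i in range(n2)], taxon=taxon2)
    return {**g1, **g2}


class TestChainAnchors:
    def test_perfect_diagonal(self):
        genes = two_taxon_genes(5, 5)
        anchors = anchors_from([(f"a{i}", f"b{i}") for i in range(5)])
        blocks = chain_anchors(anchors, genes, min_block_anchors=5)
        assert len(blocks) == 1
        assert blocks[0].n_anchors == 5
        assert blocks[0].orientation == "same"
        assert blocks[0].score == pytest.approx(250.0)

    def test_off_diagonal_anchor_excluded(self):
        genes = two_taxon_genes(5, 41)
        anchors = anchors_from([(f"a{i}", f"b{i}") for i in range(5)] + [("a2", "b40")])
        blocks = chain_anchors(anchors, genes, min_block_anchors=5, max_gene_gap=5)
        assert len(blocks) == 1
        assert "b40" not in blocks[0].gene_ids()
        # score equals the exhaustive optimum over all monotone chains
        pts = [(genes[a.gene_id_1].rank, genes[a.gene_id_2].rank, a.similarity_score)
               for a in anchors]
        assert blocks[0].score == pytest.approx(best_chain_brute(pts, 5, 1.0))

    def test_anti_diagonal_is_inverted(self):
        genes = two_taxon_genes(5, 5)
        anchors = anchors_from([(f"a{i}", f"b{4 - i}") for i in range(5)])
        blocks = chain_anchors(anchors, genes, min_block_anchors=5)
        assert len(blocks) == 1
        assert blocks[0].orientation == "inverted"

    def test_unknown_gene_rejected(self):
        genes = two_taxon_genes(2, 2)
        with pytest.raises(InputError, match="ghost"):
            chain_anchors([AnchorPair("a0", "ghost", 1.0)], genes)

    def test_chain_score_equals_exhaustive_optimum(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            n = int(rng.integers(2, 13))
            r1 = rng.choice(30, size=n, replace=False)
            r2 = rng.choice(30, size=n, replace=False)
            scores = rng.uniform(1, 10, n)
            pts = list(zip(r1.tolist(), r2.tolist(), scores.tolist()))
            anchors = [AnchorPair(f"x{i}", f"y{i}", s) for i, (_, _, s) in enumerate(pts)]
            points = [(a, b, s, anc) for (a, b, s), anc in zip(pts, anchors)]
            best = max(
                res[0]
                for inv in (False, True)
                for res in [_best_chain(points, 8, 0.7, inv)]
                if res is not None)
            assert best == pytest.approx(best_chain_brute(pts, 8, 0.7))


def blocks_covering(gene_counts, genes):
    """Helper: synthesise blocks so that gene g appears in gene_counts[g]
    distinct blocks."""
    blocks = []
    i = 0
    for gid, k in gene_counts.items():
        for _ in range(k):
            partner = f"p{i}"
            blocks.append(SyntenyBlock(
                block_id=f"b{i}", anchors=[AnchorPair(gid, partner, 1.0)],
                scaffold_1="s", scaffold_2=f"t{i}", taxon_1=genes[gid].taxon,
                taxon_2="other", orientation="same", score=1.0))
            i += 1
    return blocks


class TestCollinearDepth:
    def test_ancient_label_boundary(self):
        genes = make_genes([("g5", "s"), ("g4", "s"), ("g0", "s")])
        counts = {"g5": 5, "g4": 4, "g0": 0}
        blocks = blocks_covering(counts, genes)
        for b in blocks:  # register partner genes
            for a in b.anchors:
                genes.setdefault(a.gene_id_2, make_genes([(a.gene_id_2, "t")],
                                                         taxon="other")[a.gene_id_2])
        df = collinear_depth(blocks, genes).set_index("gene_id")
        assert df.loc["g5", "depth"] == 5 and bool(df.loc["g5", "ancient_collinear"])
        assert df.loc["g4", "depth"] == 4 and not df.loc["g4", "ancient_collinear"]
        assert df.loc["g0", "depth"] == 0
        assert not df.loc["g0", "conserved_eudicot"]

    def test_conserved_eudicot_from_outgroup_block(self):
        genes = two_taxon_genes(5, 5, taxon2="grape")
        anchors = anchors_from([(f"a{i}", f"b{i}") for i in range(5)])
        blocks = chain_anchors(anchors, genes, min_block_anchors=5)
        df = collinear_depth(blocks, genes, eudicot_taxa={"grape"}).set_index("gene_id")
        assert df.loc["a0", "conserved_eudicot"]
        assert not df.loc["b0", "conserved_eudicot"]  # outgroup genes unlabeled


def diploid_tetraploid_scene(drop_b_for=(), drop_dip_for=()):
    """Six collinear genes in diploid + subgenomes A and B, with optional
    missing copies."""
    n = 6
    spec = []
    sub = {}
    for i in range(n):
        spec.append((f"d{i}", "dip1"))
    for i in range(n):
        spec.append((f"A{i}", "tetA"))
        sub[f"A{i}"] = "A"
    for i in range(n):
        if f"B{i}" not in drop_b_for:
            spec.append((f"B{i}", "tetB"))
            sub[f"B{i}"] = "B"
    genes = {}
    genes.update(make_genes([s for s in spec if s[1] == "dip1"], taxon="dip"))
    genes.update(make_genes([s for s in spec if s[1] == "tetA"], taxon="tet",
                            subgenome="A"))
    genes.update(make_genes([s for s in spec if s[1] == "tetB"], taxon="tet",
                            subgenome="B"))
    pairs = []
    for i in range(n):
        if f"d{i}" not in drop_dip_for:
            pairs.append((f"d{i}", f"A{i}"))
            if f"B{i}" not in drop_b_for:
                pairs.append((f"d{i}", f"B{i}"))
        if f"B{i}" not in drop_b_for:
            pairs.append((f"A{i}", f"B{i}"))
    anchors = anchors_from(pairs)
    blocks = chain_anchors(anchors, genes, min_block_anchors=4)
    return genes, anchors, blocks


class TestWgdGroups:
    def test_full_complement_is_triplet(self):
        genes, _, blocks = diploid_tetraploid_scene()
        groups = classify_wgd_groups(blocks, genes, "dip", "tet")
        assert len(groups) == 6
        assert all(g.category == "triplet" for g in groups)

    def test_missing_subgenome_copy_is_singleton(self):
        genes, _, blocks = diploid_tetraploid_scene(drop_b_for={"B2"})
        groups = classify_wgd_groups(blocks, genes, "dip", "tet")
        by_dip = {g.diploid_gene: g for g in groups}
        assert by_dip["d2"].category == "singleton"
        assert set(by_dip["d2"].tetraploid_copies) == {"A"}

    def test_missing_subgenome_tag_rejected(self):
        genes, _, blocks = diploid_tetraploid_scene()
        untagged = {gid: (g if g.taxon != "tet" else
                          type(g)(g.gene_id, g.scaffold, g.start, g.end, g.strand,
                                  g.taxon, None, g.rank))
                    for gid, g in genes.items()}
        with pytest.raises(InputError, match="subgenome"):
            classify_wgd_groups(blocks, untagged, "dip", "tet")


class TestSsdModes:
    def setup_method(self):
        spec = ([(f"g{i}", "s1") for i in range(20)]
                + [(f"h{i}", "s2") for i in range(20)])
        self.genes = make_genes(spec, taxon="tet", subgenome="A")

    def classify(self, anchors, blocks=()):
        return {l.gene_id: l.label for l in classify_ssd_modes(
            self.genes, anchors, list(blocks), "tet", "dip",
            proximal_max_rank_gap=10)}

    def test_tandem_adjacent(self):
        lab = self.classify(anchors_from([("g7", "g8")]))
        assert lab["g7"] == lab["g8"] == "tandem"

    def test_proximal_gap_within_threshold(self):
        lab = self.classify(anchors_from([("g7", "g12")]))
        assert lab["g7"] == lab["g12"] == "proximal"

    def test_dispersed_fall_through(self):
        lab = self.classify(anchors_from([("g7", "h3")]))
        assert lab["g7"] == lab["h3"] == "dispersed"

    def test_transposed_labels_novel_locus_copy(self):
        # g7 is collinear with the diploid outgroup, h3 is not
        outgroup_block = SyntenyBlock(
            block_id="b0", anchors=[AnchorPair("g7", "d7", 1.0)],
            scaffold_1="s1", scaffold_2="dip1", taxon_1="tet", taxon_2="dip",
            orientation="same", score=1.0)
        self.genes.update(make_genes([("d7", "dip1")], taxon="dip"))
        lab = self.classify(anchors_from([("g7", "h3")]), blocks=[outgroup_block])
        assert lab.get("h3") == "transposed"
        assert "g7" not in lab  # the ancestral-locus donor keeps its WGD status

    def test_homoeologous_pairs_excluded(self):
        other = make_genes([("b0", "sB")], taxon="tet", subgenome="B")
        genes = {**self.genes, **other}
        labels = classify_ssd_modes(genes, anchors_from([("g0", "b0")]), [],
                                    "tet", "dip")
        assert labels == []


class TestClusterFamilies:
    def test_lineage_specific_definition(self, small_sim, all_genes):
        _, genomes, truth = small_sim
        fams, lineage = cluster_families(all_genes, genomes.anchors,
                                         {"ginseng", "notoginseng"})
        # every planted focal-only family recovered as lineage-specific
        for fam, members in truth.lineage_families.items():
            ids = {fams[g] for g in members}
            assert len(ids) == 1
            assert ids.pop() in lineage
        # families with an outgroup member are never lineage-specific
        out_genes = [g for g in all_genes.values() if g.taxon == "outgroup_eudicot"]
        for g in out_genes[:50]:
            assert fams[g.gene_id] not in lineage

    def test_empty_hit_table_warns_singletons(self, all_genes, caplog):
        import logging
        with caplog.at_level(logging.WARNING):
            fams, lineage = cluster_families(all_genes, [], {"ginseng"})
        assert "empty hit table" in caplog.text
        assert len(set(fams.values())) == len(all_genes)


class TestSimulationRecovery:
    def test_group_counts_and_ssd_modes_recovered(self, small_sim, all_genes):
        _, genomes, truth = small_sim
        blocks = chain_anchors(genomes.anchors, all_genes)
        groups = classify_wgd_groups(blocks, all_genes, "notoginseng", "ginseng")
        obs = pd.Series([g.category for g in groups]).value_counts().to_dict()
        exp = truth.groups["category"].value_counts().to_dict()
        assert obs == exp

        labels = {l.gene_id: l.label for l in classify_ssd_modes(
            all_genes, genomes.anchors, blocks, "ginseng", "notoginseng")}
        hits = sum(labels.get(e.copy) == e.mode
                   for e in truth.ssd_events.itertuples())
        assert hits / len(truth.ssd_events) >= 0.9

    def test_ancient_collinear_recovered(self, small_sim, all_genes):
        _, genomes, truth = small_sim
        blocks = chain_anchors(genomes.anchors, all_genes)
        df = collinear_depth(blocks, all_genes,
                             eudicot_taxa={"outgroup_eudicot"}).set_index("gene_id")
        tet_ids = set(genomes.genes["ginseng"])
        observed = {g for g in tet_ids if df.loc[g, "ancient_collinear"]}
        assert observed == set(truth.ancient_genes)

    def test_singleton_fraction_monotone_in_fractionation(self):
        fracs = []
        for f in (0.1, 0.4):
            cfg = SimulationConfig(seed=3, n_ancestral_genes=300, fractionation_prob=f,
                                   ancient_runs=0, n_lineage_specific=0)
            _, truth = simulate_genomes(cfg)
            counts = truth.groups["category"].value_counts()
            fracs.append(counts.get("singleton", 0) / counts.sum())
        assert fracs[0] < fracs[1]
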