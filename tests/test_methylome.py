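"""Methylation levels, CMH/Fisher kernels, DMG calling, correlations."""

import logging
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dupevo import SimulationConfig, simulate_genomes, simulate_methylomes
from dupevo.methylome import (assign_genes, bh_adjust, call_dmgs, cmh_test,
                              filter_sites, fisher_exact_2x2,
                              gene_methylation_levels, profile_correlation,
                              read_cx_reports, weighted_methylation_level,
                              write_cx_report)
from dupevo.models import InputError, MethylomeMatrix

from _oracles import bh_brute, cmh_brute, fisher_brute, spearman_brute
from conftest import make_genes


def toy_matrix(meth, total, contexts=None, gene="g1", n_genes_span=500):
    n_sites, n_samples = np.asarray(meth).shape
    sites = pd.DataFrame({
        "scaffold": "s1",
        "pos": np.arange(1, n_sites + 1) * (n_genes_span // max(n_sites, 1)) + 1,
        "strand": "+",
        "context": contexts if contexts is not None else ["CG"] * n_sites,
        "gene_id": gene,
    })
    samples = [f"r{i + 1}" for i in range(n_samples)]
    return MethylomeMatrix(sites, np.asarray(meth), np.asarray(total), samples,
                           {s: "sp" for s in samples})


class TestFilterSites:
    def test_strictly_greater_in_every_sample(self):
        m = toy_matrix(meth=[[1, 1, 1], [1, 1, 1], [1, 1, 1]],
                       total=[[10, 30, 30], [11, 11, 11], [30, 30, 10]])
        out = filter_sites(m, min_total_depth=10)
        assert out.n_sites == 1
        assert out.total[0].tolist() == [11, 11, 11]

    def test_empty_input(self):
        m = toy_matrix(meth=np.empty((0, 2), int), total=np.empty((0, 2), int))
        assert filter_sites(m).n_sites == 0


class TestWeightedLevel:
    def test_fully_methylated(self):
        m = toy_matrix(meth=[[10], [20]], total=[[10], [20]])
        assert weighted_methylation_level(m, "g1", "CG", "r1") == 1.0

    def test_weighted_not_site_averaged(self):
        # sites 5/10 and 0/10: weighted level 5/20, not mean(0.5, 0.0)
        m = toy_matrix(meth=[[5], [0]], total=[[10], [10]])
        assert weighted_methylation_level(m, "g1", "CG", "r1") == pytest.approx(0.25)

    def test_absence_is_not_zero(self):
        m = toy_matrix(meth=[[5]], total=[[10]], contexts=["CHH"])
        assert math.isnan(weighted_methylation_level(m, "g1", "CG", "r1"))
        levels = gene_methylation_levels(m, contexts=("CG",))
        assert levels.empty


class TestCmh:
    def test_no_association_gives_zero(self):
        strata = [[[20, 20], [20, 20]], [[5, 5], [5, 5]]]
        stat, p = cmh_test(strata)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_two_stratum_frozen_value(self):
        # computed from the M^2 formula by hand: sum(a-E)=18, sum Var=200/23
        strata = [[[30, 5], [10, 25]], [[28, 7], [12, 23]]]
        stat, p = cmh_test(strata)
        assert stat == pytest.approx(324 * 23 / 200)  # 37.26
        assert stat == pytest.approx(cmh_brute(strata))
        assert p == pytest.approx(stats.chi2.sf(37.26, 1))

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(8)
        from statsmodels.stats.contingency_tables import StratifiedTable
        for _ in range(25):
            k = int(rng.integers(1, 5))
            strata = rng.integers(1, 40, size=(k, 2, 2))
            stat, p = cmh_test(strata)
            st = StratifiedTable(np.transpose(strata, (1, 2, 0)).astype(float))
            res = st.test_null_odds(correction=False)
            assert stat == pytest.approx(res.statistic)
            assert p == pytest.approx(res.pvalue)

    def test_single_stratum_chi_square_identity(self):
        # one stratum: M^2 = (n-1)/n * Pearson chi-square
        table = np.array([[12, 8], [5, 15]])
        stat, _ = cmh_test([table])
        chi2 = stats.chi2_contingency(table, correction=False)[0]
        n = table.sum()
        assert stat == pytest.approx((n - 1) / n * chi2)

    def test_stratum_order_invariance(self):
        strata = [[[30, 5], [10, 25]], [[2, 9], [8, 3]], [[7, 7], [6, 8]]]
        assert cmh_test(strata)[0] == pytest.approx(cmh_test(strata[::-1])[0])

    def test_degenerate_strata(self, caplog):
        with caplog.at_level(logging.WARNING):
            stat, p = cmh_test([[[5, 5], [0, 0]], [[10, 5], [5, 10]]])
        assert "degenerate" in caplog.text
        assert not math.isnan(stat)
        stat, p = cmh_test([[[0, 0], [0, 0]]])
        assert math.isnan(stat) and math.isnan(p)


class TestFisher:
    def test_balanced_table(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_extreme_table_matches_enumeration(self):
        p = fisher_exact_2x2([[10, 0], [0, 10]])
        assert p == pytest.approx(fisher_brute([[10, 0], [0, 10]]))

    def test_row_swap_invariance_and_brute(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            t = rng.integers(0, 15, size=(2, 2))
            if t.sum() == 0:
                continue
            p = fisher_exact_2x2(t)
            assert p == pytest.approx(fisher_exact_2x2(t[::-1]))
            assert p == pytest.approx(fisher_brute(t.tolist()))

    def test_all_zero_table(self, caplog):
        with caplog.at_level(logging.WARNING):
            assert fisher_exact_2x2([[0, 0], [0, 0]]) == 1.0
        assert "all-zero" in caplog.text


class TestSpearmanAndBh:
    def test_profile_correlation_limits(self):
        x = [0.1, 0.4, 0.2, 0.9]
        assert profile_correlation(x, x) == pytest.approx(1.0)
        assert profile_correlation(x, [-v for v in x]) == pytest.approx(-1.0)
        assert math.isnan(profile_correlation([1, 1, 1, 1], x))
        assert math.isnan(profile_correlation([1, 2], [3, 4]))

    def test_ties_match_rank_then_pearson(self):
        x = [1.0, 2.0, 2.0, 3.0, 5.0, 5.0]
        y = [2.0, 1.0, 4.0, 4.0, 4.0, 6.0]
        assert profile_correlation(x, y) == pytest.approx(spearman_brute(x, y))

    def test_bh_matches_brute_and_is_monotone(self):
        rng = np.random.default_rng(10)
        p = rng.uniform(0, 1, 40)
        q = bh_adjust(p)
        assert np.allclose(q, bh_brute(p.tolist()))
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestCxRoundTrip:
    def test_write_read_identity(self, tmp_path):
        rng = np.random.default_rng(11)
        total = rng.integers(0, 40, size=(30, 2))
        meth = rng.binomial(total, 0.4)
        ctx = rng.choice(["CG", "CHG", "CHH"], 30).tolist()
        m = toy_matrix(meth, total, contexts=ctx)
        paths = {}
        for s in m.samples:
            paths[s] = str(tmp_path / f"{s}.cx.tsv")
            write_cx_report(m, s, paths[s])
        back = read_cx_reports(paths, m.sample_species)
        merged = back.sites.merge(m.sites, on=["scaffold", "pos", "strand", "context"])
        assert len(merged) == 30
        order = m.sites.sort_values(["scaffold", "pos", "strand", "context"]).index
        assert np.array_equal(back.meth, m.meth[order])
        assert np.array_equal(back.total, m.total[order])


class TestCallDmgs:
    @pytest.fixture(scope="class")
    @staticmethod
    def planted():
        cfg = SimulationConfig(seed=21, n_ancestral_genes=120, n_meth_replicates=3,
                               n_dmg=5, ancient_runs=0)
        genomes, truth = simulate_genomes(cfg)
        meth = simulate_methylomes(genomes, truth, cfg)
        return cfg, genomes, truth, meth

    def test_planted_dmgs_pass_all_three_criteria(self, planted):
        cfg, genomes, truth, meth = planted
        calls = call_dmgs(meth.matrices["ginseng"], meth.matrices["quinquefolius"],
                          genomes.genes["ginseng"], contexts=("CG",))
        planted_ids = {g for g, _ in truth.dmg[("ginseng", "quinquefolius")]}
        sub = calls[calls["gene_id"].isin(planted_ids)]
        assert len(sub) == len(planted_ids)
        assert sub["is_dmg"].all()
        assert (sub["delta_between"].abs() > 0.5).all()
        assert (sub["frac_sig_windows"] > 0.1).all()

    def test_between_difference_below_half_is_never_dmg(self, planted):
        cfg, genomes, truth, meth = planted
        calls = call_dmgs(meth.matrices["ginseng"], meth.matrices["quinquefolius"],
                          genomes.genes["ginseng"], contexts=("CG",))
        weak = calls[calls["delta_between"].abs() <= 0.5]
        assert len(weak) > 0
        assert not weak["is_dmg"].any()

    def test_single_replicate_downgrades_intraspecific_criterion(self, planted, caplog):
        cfg, genomes, truth, meth = planted
        m1 = meth.matrices["ginseng"].subset_samples(["ginseng_r1"])
        with caplog.at_level(logging.WARNING):
            calls = call_dmgs(m1, meth.matrices["quinquefolius"],
                              genomes.genes["ginseng"], contexts=("CG",))
        assert "replicates" in caplog.text
        assert not calls["within_tested"].any()


class TestContextAssignment:
    def test_contexts_follow_reference_sequence(self, small_sim):
        cfg, genomes, truth = small_sim
        meth = simulate_methylomes(genomes, truth, cfg)
        m = meth.matrices["ginseng"]
        gm = genomes.genes["ginseng"]
        seqs = genomes.ref_seqs["ginseng"]
        sub = m.sites.sample(200, random_state=0)
        for r in sub.itertuples():
            g = gm[r.gene_id]
            seq = seqs[r.gene_id]
            off = r.pos - g.start
            if r.strand == "+":
                assert seq[off] == "C"
                if r.context == "CG":
                    assert seq[off + 1] == "G"
                elif r.context == "CHG":
                    assert seq[off + 1] != "G" and seq[off + 2] == "G"
                else:
                    assert seq[off + 1] != "G" and seq[off + 2] != "G"
            else:
                assert seq[off] == "G"
                if r.context == "CG":
                    assert seq[off - 1] == "C"
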