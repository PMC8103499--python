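"""Per-gene cytosine methylation statistics and DMG calling.

Gene-body methylation is quantified as the weighted level (summed methylated
reads over summed total reads across a gene's retained cytosines of one
context), which is robust to uneven coverage. Differentially methylated
genes (DMGs) between two species are called with a stratified
Cochran-Mantel-Haenszel (CMH) test — strata are paired biological
replicates — followed by three filters: a small, non-significant
intraspecific replicate difference; an interspecific level difference above
50 percentage points; and a minimum fraction of significant gene-body
windows after Benjamini-Hochberg correction.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .models import GeneModel, InputError, MethylomeMatrix

logger = logging.getLogger(__name__)

CONTEXTS = ("CG", "CHG", "CHH")


# --- CX report I/O ----------------------------------------------------------

CX_COLUMNS = ["scaffold", "pos", "strand", "count_methylated", "count_unmethylated", "context"]


def write_cx_report(matrix: MethylomeMatrix, sample: str, path: str) -> None:
    """Write one sample's counts as a Bismark CX-report-style TSV."""
    i = matrix.samples.index(sample)
    df = matrix.sites[["scaffold", "pos", "strand", "context"]].copy()
    df["count_methylated"] = matrix.meth[:, i]
    df["count_unmethylated"] = matrix.total[:, i] - matrix.meth[:, i]
    df[CX_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_cx_reports(sample_paths: dict, sample_species: dict) -> MethylomeMatrix:
    """Read CX-report TSVs (one per sample) into a single MethylomeMatrix.

    Sites are outer-joined on (scaffold, pos, strand, context); a site absent
    from one report gets zero counts there.
    """
    samples = sorted(sample_paths)
    frames = []
    for s in samples:
        df = pd.read_csv(sample_paths[s], sep="\t", header=None, names=CX_COLUMNS)
        bad = ~df["context"].isin(CONTEXTS)
        if bad.any():
            raise InputError(f"sample {s}: unknown context values {sorted(df.loc[bad, 'context'].unique())}")
        df = df.set_index(["scaffold", "pos", "strand", "context"])
        frames.append(df.rename(columns={"count_methylated": f"m_{s}",
                                         "count_unmethylated": f"u_{s}"}))
    joined = pd.concat(frames, axis=1).fillna(0).astype(np.int64).sort_index()
    sites = joined.index.to_frame(index=False)
    meth = np.stack([joined[f"m_{s}"].to_numpy() for s in samples], axis=1)
    unmeth = np.stack([joined[f"u_{s}"].to_numpy() for s in samples], axis=1)
    return MethylomeMatrix(sites, meth, meth + unmeth, samples,
                           {s: sample_species[s] for s in samples})


def assign_genes(matrix: MethylomeMatrix, genes: Iterable[GeneModel]) -> MethylomeMatrix:
    """Annotate sites with the gene body they fall in (non-overlapping genes).

    Sites outside every gene body get a missing gene_id and are ignored by
    gene-level operations.
    """
    genes = list(genes)
    starts: dict = {}
    for g in genes:
        starts.setdefault(g.scaffold, []).append(g)
    sites = matrix.sites.copy()
    gene_id = np.full(len(sites), None, dtype=object)
    for scaf, glist in starts.items():
        glist.sort(key=lambda g: g.start)
        s_arr = np.array([g.start for g in glist])
        e_arr = np.array([g.end for g in glist])
        ids = np.array([g.gene_id for g in glist], dtype=object)
        mask = (sites["scaffold"] == scaf).to_numpy()
        pos = sites.loc[mask, "pos"].to_numpy()
        idx = np.searchsorted(s_arr, pos, side="right") - 1
        ok = (idx >= 0) & (pos <= e_arr[np.clip(idx, 0, None)])
        vals = np.full(len(pos), None, dtype=object)
        vals[ok] = ids[idx[ok]]
        gene_id[mask] = vals
    sites["gene_id"] = gene_id
    return MethylomeMatrix(sites, matrix.meth, matrix.total, matrix.samples, matrix.sample_species)


# --- site filtering and weighted levels -------------------------------------

def filter_sites(matrix: MethylomeMatrix, min_total_depth: int = 10,
                 samples: Optional[list] = None) -> MethylomeMatrix:
    """Retain sites whose total depth is strictly above ``min_total_depth``
    in EVERY listed sample (all samples by default)."""
    samples = matrix.samples if samples is None else samples
    idx = [matrix.samples.index(s) for s in samples]
    keep = (matrix.total[:, idx] > min_total_depth).all(axis=1)
    return matrix.subset_sites(keep)


def gene_methylation_levels(matrix: MethylomeMatrix,
                            contexts: Iterable[str] = CONTEXTS) -> pd.DataFrame:
    """Weighted methylation level per (gene, context, sample).

    level = sum(methylated) / sum(total) over the gene's sites of that
    context. Genes with no retained site of a context are simply absent from
    the result (absence of evidence, not level 0).
    """
    sites = matrix.sites
    if "gene_id" not in sites.columns:
        raise InputError("sites carry no gene assignment; call assign_genes first")
    mask = sites["gene_id"].notna() & sites["context"].isin(list(contexts))
    sub = sites.loc[mask, ["gene_id", "context"]]
    rows = []
    for j, s in enumerate(matrix.samples):
        df = sub.copy()
        df["meth"] = matrix.meth[mask.to_numpy(), j]
        df["total"] = matrix.total[mask.to_numpy(), j]
        agg = df.groupby(["gene_id", "context"], sort=True).agg(
            meth=("meth", "sum"), total=("total", "sum"), n_sites=("meth", "size"))
        agg = agg[agg["total"] > 0]
        agg["level"] = agg["meth"] / agg["total"]
        agg["sample"] = s
        rows.append(agg.reset_index())
    out = pd.concat(rows, ignore_index=True)
    out["species"] = out["sample"].map(matrix.sample_species)
    return out[["gene_id", "context", "sample", "species", "level", "n_sites", "meth", "total"]]


def weighted_methylation_level(matrix: MethylomeMatrix, gene_id: str, context: str,
                               sample: str) -> float:
    """Weighted level for a single (gene, context, sample); NaN if no sites."""
    j = matrix.samples.index(sample)
    sites = matrix.sites
    mask = ((sites["gene_id"] == gene_id) & (sites["context"] == context)).to_numpy()
    total = matrix.total[mask, j].sum()
    if mask.sum() == 0 or total == 0:
        return float("nan")
    return float(matrix.meth[mask, j].sum() / total)


# --- Cochran-Mantel-Haenszel ------------------------------------------------

def _cmh_components(tables: np.ndarray) -> tuple:
    """Per-stratum (a - E[a]) and Var[a] with degenerate strata masked.

    ``tables`` has shape (..., k, 2, 2) with rows = groups and columns =
    methylated/unmethylated. A stratum is degenerate when any margin is zero.
    """
    a = tables[..., 0, 0]
    n1 = tables[..., 0, :].sum(axis=-1)
    n2 = tables[..., 1, :].sum(axis=-1)
    m1 = tables[..., :, 0].sum(axis=-1)
    m2 = tables[..., :, 1].sum(axis=-1)
    n = n1 + n2
    ok = (n1 > 0) & (n2 > 0) & (m1 > 0) & (m2 > 0) & (n > 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(ok, n1 * m1 / np.where(n > 0, n, 1), 0.0)
        var = np.where(ok, n1 * n2 * m1 * m2 /
                       (np.square(np.where(n > 0, n, 1.0)) * np.where(n > 1, n - 1, 1)), 0.0)
    dev = np.where(ok, a - e, 0.0)
    return dev, var, ok


def cmh_test(strata: Iterable) -> tuple:
    """Cochran-Mantel-Haenszel test over 2x2 strata (no continuity correction).

    M^2 = [sum_k (a_k - E a_k)]^2 / sum_k Var(a_k) with
    E a_k = n1k m1k / nk and Var a_k = n1k n2k m1k m2k / (nk^2 (nk - 1));
    p from the chi-square distribution with 1 df. Degenerate strata (a zero
    margin) are dropped with a warning; if every stratum is degenerate the
    result is (NaN, NaN).
    """
    tables = np.asarray(list(strata), dtype=float)
    if tables.ndim != 3 or tables.shape[1:] != (2, 2):
        raise InputError("strata must be a sequence of 2x2 tables")
    dev, var, ok = _cmh_components(tables)
    if not ok.all():
        n_bad = int((~ok).sum())
        if n_bad == len(tables):
            logger.warning("all %d strata degenerate; CMH undefined", n_bad)
            return float("nan"), float("nan")
        logger.warning("dropping %d degenerate stratum/strata from CMH", n_bad)
    denom = var.sum()
    if denom == 0:
        return float("nan"), float("nan")
    stat = float(dev.sum() ** 2 / denom)
    return stat, float(stats.chi2.sf(stat, df=1))


def cmh_bulk(tables: np.ndarray) -> tuple:
    """Vectorised CMH over an array of tests, shape (n_tests, k, 2, 2)."""
    dev, var, ok = _cmh_components(np.asarray(tables, dtype=float))
    denom = var.sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(denom > 0, dev.sum(axis=-1) ** 2 / np.where(denom > 0, denom, 1), np.nan)
    p = np.where(np.isnan(stat), np.nan, stats.chi2.sf(stat, df=1))
    return stat, p


# --- small-sample helpers ---------------------------------------------------

def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table of non-negative counts.

    p is the hypergeometric-tail sum over tables (margins fixed) whose
    probability does not exceed the observed table's. An all-zero table
    yields p = 1 with a warning.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise InputError("Fisher exact needs a 2x2 table of non-negative counts")
    if t.sum() == 0:
        logger.warning("all-zero 2x2 table; Fisher p = 1")
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values; NaNs are passed through."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if mask.sum() > 0:
        from statsmodels.stats.multitest import multipletests
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def profile_correlation(x, y) -> float:
    """Spearman rank correlation of two matched per-gene level profiles.

    Pairs with a missing value are dropped; needs >= 3 shared genes; a
    constant vector gives NaN (undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InputError("profiles must be matched gene-for-gene")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        return float("nan")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


# --- DMG calling ------------------------------------------------------------

DMG_DEFAULTS = dict(delta_within_max=0.10, delta_between_min=0.50,
                    frac_windows_min=0.10, alpha=0.01)


def _window_counts(matrix: MethylomeMatrix, genes: dict, context: str,
                   n_windows: int) -> pd.DataFrame:
    """Per (gene, window, sample) summed meth/total counts for one context."""
    sites = matrix.sites
    mask = (sites["gene_id"].notna() & (sites["context"] == context)).to_numpy()
    sub = sites.loc[mask, ["gene_id", "pos"]].copy()
    start = sub["gene_id"].map(lambda g: genes[g].start)
    length = sub["gene_id"].map(lambda g: genes[g].length)
    sub["window"] = np.minimum(((sub["pos"] - start) * n_windows // length).astype(int),
                               n_windows - 1)
    for j, s in enumerate(matrix.samples):
        sub[f"m_{s}"] = matrix.meth[mask, j]
        sub[f"t_{s}"] = matrix.total[mask, j]
    return sub.groupby(["gene_id", "window"], sort=True).sum(numeric_only=True).drop(columns=["pos"])


def call_dmgs(matrix_1: MethylomeMatrix, matrix_2: MethylomeMatrix,
              genes_1: dict, genes_2: Optional[dict] = None,
              gene_map: Optional[dict] = None,
              contexts: Iterable[str] = CONTEXTS,
              n_windows: int = 20, min_total_depth: int = 10,
              delta_within_max: float = 0.10, delta_between_min: float = 0.50,
              frac_windows_min: float = 0.10, alpha: float = 0.01) -> pd.DataFrame:
    """Call differentially methylated genes between two species.

    ``matrix_1``/``matrix_2`` hold the replicate samples of the two species
    (possibly on different mapping references); ``gene_map`` maps matrix-1
    gene ids to matrix-2 ortholog ids (identity by default). Only genes
    fully mapped in both species (every replicate with >= 1 retained site of
    the context in the gene body) are tested. is_dmg requires all three
    filter criteria; the gene-level CMH statistic and its BH q-value across
    genes are reported alongside.
    """
    genes_2 = genes_1 if genes_2 is None else genes_2
    species_1 = sorted(set(matrix_1.sample_species.values()))
    species_2 = sorted(set(matrix_2.sample_species.values()))
    if len(species_1) != 1 or len(species_2) != 1:
        raise InputError("each matrix must hold samples of exactly one species")
    sp1, sp2 = species_1[0], species_2[0]

    m1 = filter_sites(matrix_1, min_total_depth)
    m2 = filter_sites(matrix_2, min_total_depth)
    reps1, reps2 = m1.samples, m2.samples
    k = min(len(reps1), len(reps2))
    within_testable = len(reps1) >= 2 and len(reps2) >= 2
    if not within_testable:
        logger.warning("a species has < 2 replicates: intraspecific criterion skipped")

    out_rows = []
    for context in contexts:
        w1 = _window_counts(m1, genes_1, context, n_windows)
        w2 = _window_counts(m2, genes_2, context, n_windows)
        g1_all = w1.index.get_level_values(0).unique()
        gmap = {g: (gene_map.get(g) if gene_map else g) for g in g1_all}
        gene_tot1 = w1.groupby(level=0).sum()
        gene_tot2 = w2.groupby(level=0).sum()
        common = [g for g in g1_all
                  if gmap[g] is not None and gmap[g] in gene_tot2.index
                  and all(gene_tot1.loc[g, f"t_{s}"] > 0 for s in reps1)
                  and all(gene_tot2.loc[gmap[g], f"t_{s}"] > 0 for s in reps2)]
        if not common:
            continue

        # --- window-level CMH over paired replicates
        recs = []  # (gene index, window, stratum tables)
        widx = []
        tables = []
        for gi, g in enumerate(common):
            g2 = gmap[g]
            sub1 = w1.loc[g]
            sub2 = w2.loc[g2]
            wins = sorted(set(sub1.index) & set(sub2.index))
            for w in wins:
                t = np.zeros((k, 2, 2))
                for s in range(k):
                    mm1, tt1 = sub1.loc[w, f"m_{reps1[s]}"], sub1.loc[w, f"t_{reps1[s]}"]
                    mm2, tt2 = sub2.loc[w, f"m_{reps2[s]}"], sub2.loc[w, f"t_{reps2[s]}"]
                    t[s] = [[mm1, tt1 - mm1], [mm2, tt2 - mm2]]
                widx.append((gi, w))
                tables.append(t)
        stat_w, p_w = cmh_bulk(np.array(tables)) if tables else (np.array([]), np.array([]))
        q_w = bh_adjust(p_w)

        n_tested = np.zeros(len(common), dtype=int)
        n_sig = np.zeros(len(common), dtype=int)
        for (gi, w), p, q in zip(widx, p_w, q_w):
            if np.isnan(p):
                continue
            n_tested[gi] += 1
            if q < alpha:
                n_sig[gi] += 1

        # --- gene-level summaries
        gene_tables = []
        for g in common:
            g2 = gmap[g]
            t = np.zeros((k, 2, 2))
            for s in range(k):
                mm1, tt1 = gene_tot1.loc[g, f"m_{reps1[s]}"], gene_tot1.loc[g, f"t_{reps1[s]}"]
                mm2, tt2 = gene_tot2.loc[g2, f"m_{reps2[s]}"], gene_tot2.loc[g2, f"t_{reps2[s]}"]
                t[s] = [[mm1, tt1 - mm1], [mm2, tt2 - mm2]]
            gene_tables.append(t)
        stat_g, p_g = cmh_bulk(np.array(gene_tables))
        q_g = bh_adjust(p_g)

        for gi, g in enumerate(common):
            g2 = gmap[g]
            lv1 = {s: gene_tot1.loc[g, f"m_{s}"] / gene_tot1.loc[g, f"t_{s}"] for s in reps1}
            lv2 = {s: gene_tot2.loc[g2, f"m_{s}"] / gene_tot2.loc[g2, f"t_{s}"] for s in reps2}
            L1 = sum(gene_tot1.loc[g, f"m_{s}"] for s in reps1) / sum(gene_tot1.loc[g, f"t_{s}"] for s in reps1)
            L2 = sum(gene_tot2.loc[g2, f"m_{s}"] for s in reps2) / sum(gene_tot2.loc[g2, f"t_{s}"] for s in reps2)

            # criterion (i): no replicate pair with a large AND significant difference
            within_ok = True
            delta_within = 0.0
            if within_testable:
                for reps, lv, tot in ((reps1, lv1, gene_tot1), (reps2, lv2, gene_tot2)):
                    gkey = g if reps is reps1 else g2
                    for a_i in range(len(reps)):
                        for b_i in range(a_i + 1, len(reps)):
                            sa, sb = reps[a_i], reps[b_i]
                            d = abs(lv[sa] - lv[sb])
                            delta_within = max(delta_within, d)
                            if d >= delta_within_max:
                                tab = [[tot.loc[gkey, f"m_{sa}"],
                                        tot.loc[gkey, f"t_{sa}"] - tot.loc[gkey, f"m_{sa}"]],
                                       [tot.loc[gkey, f"m_{sb}"],
                                        tot.loc[gkey, f"t_{sb}"] - tot.loc[gkey, f"m_{sb}"]]]
                                if fisher_exact_2x2(tab) < alpha:
                                    within_ok = False

            delta_between = L1 - L2
            between_ok = abs(delta_between) > delta_between_min
            frac_sig = n_sig[gi] / n_tested[gi] if n_tested[gi] > 0 else 0.0
            windows_ok = frac_sig > frac_windows_min

            out_rows.append({
                "gene_id": g, "gene_id_2": g2, "context": context,
                "species_1": sp1, "species_2": sp2,
                "cmh_statistic": stat_g[gi], "p": p_g[gi], "q": q_g[gi],
                "level_1": L1, "level_2": L2,
                "delta_between": delta_between, "delta_within": delta_within,
                "frac_sig_windows": frac_sig, "n_windows_tested": int(n_tested[gi]),
                "within_ok": within_ok, "between_ok": between_ok, "windows_ok": windows_ok,
                "within_tested": within_testable,
                "is_dmg": bool(within_ok and between_ok and windows_ok),
            })

    cols = ["gene_id", "gene_id_2", "context", "species_1", "species_2", "cmh_statistic",
            "p", "q", "level_1", "level_2", "delta_between", "delta_within",
            "frac_sig_windows", "n_windows_tested", "within_ok", "between_ok",
            "windows_ok", "within_tested", "is_dmg"]
    return pd.DataFrame(out_rows, columns=cols)
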