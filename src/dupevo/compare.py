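"""Class-wise comparative statistics.

Per-gene statistics (pi, dxy, dN/dS, methylation levels) are compared
between each duplicate-gene class and the full annotated gene set
("overall") with Wilcoxon two-sample rank-sum tests; subgenome asymmetry
and biased fractionation are summarised for doublet/singleton ortholog
groups; gene-set enrichment uses the upper hypergeometric tail. All
multiple-testing correction is Benjamini-Hochberg, one family per
statistic table.
"""

from __future__ import annotations

import itertools
import math
from collections import defaultdict
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .methylome import bh_adjust, profile_correlation
from .models import InputError

EXACT_WILCOXON_MAX_N = 12


# --- Wilcoxon rank-sum ------------------------------------------------------

def wilcoxon_rank_sum(x, y) -> tuple:
    """Two-sample Wilcoxon rank-sum test with average ranks for ties.

    Returns ``(W, p)`` where W is the rank sum of ``x``. For combined
    n <= 12 the two-sided p is exact (enumeration over all rank
    assignments, doubling the smaller tail); otherwise the normal
    approximation with tie-corrected variance and continuity correction is
    used. Samples must be non-empty; if every pooled value is tied, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise InputError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    nx, ny = len(x), len(y)
    n = nx + ny
    W = float(ranks[:nx].sum())
    if np.all(pooled == pooled[0]):
        return W, 1.0

    if n <= EXACT_WILCOXON_MAX_N:
        sums = [sum(c) for c in itertools.combinations(ranks, nx)]
        total = len(sums)
        lo = sum(1 for s in sums if s <= W + 1e-9)
        hi = sum(1 for s in sums if s >= W - 1e-9)
        p = min(1.0, 2.0 * min(lo, hi) / total)
        return W, p

    mean = nx * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts ** 3 - counts).sum() / (n * (n - 1))
    var = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return W, 1.0
    d = W - mean
    z = (d - 0.5 * np.sign(d)) / math.sqrt(var)
    return W, float(2.0 * stats.norm.sf(abs(z)))


# --- class-wise comparisons -------------------------------------------------

def compare_classes(stats_df: pd.DataFrame, class_map: dict, statistics: Iterable[str],
                    classes: Optional[Iterable[str]] = None) -> pd.DataFrame:
    """Compare each gene class against the overall distribution per statistic.

    ``stats_df`` has one row per gene (index or column ``gene_id``) and one
    column per statistic; ``class_map`` maps gene_id to a set of class
    labels (every gene implicitly belongs to "overall"). For each
    (class, statistic), the class genes' values are tested against all
    genes' values with the rank-sum test; NaN-flagged genes are dropped per
    cell. Direction is from the median difference (ties -> ns). BH
    correction is applied per statistic across classes.
    """
    df = stats_df.set_index("gene_id") if "gene_id" in stats_df.columns else stats_df
    if classes is None:
        classes = sorted({c for cs in class_map.values() for c in cs})
    classes = [c for c in classes if c != "overall"]
    rows = []
    for stat_name in statistics:
        if stat_name not in df.columns:
            raise InputError(f"unknown statistic column {stat_name!r}")
        overall = df[stat_name].dropna()
        for cls in classes:
            members = [g for g, cs in class_map.items() if cls in cs]
            vals = df.loc[df.index.intersection(members), stat_name].dropna()
            if len(vals) == 0 or len(overall) == 0:
                rows.append({"class": cls, "statistic": stat_name, "n_class": len(vals),
                             "n_overall": len(overall), "W": np.nan, "p": np.nan,
                             "direction": "untestable"})
                continue
            W, p = wilcoxon_rank_sum(vals.to_numpy(), overall.to_numpy())
            med_diff = float(np.median(vals) - np.median(overall))
            rows.append({"class": cls, "statistic": stat_name, "n_class": len(vals),
                         "n_overall": len(overall), "W": W, "p": p,
                         "direction": "higher" if med_diff > 0 else ("lower" if med_diff < 0 else "ns"),
                         "median_diff": med_diff})
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    for stat_name in out["statistic"].unique():
        m = out["statistic"] == stat_name
        out.loc[m, "q"] = bh_adjust(out.loc[m, "p"].to_numpy())
    # a cell is directional only when significant after correction
    ns_mask = (out["q"].isna() | (out["q"] >= 0.05)) & (out["direction"] != "untestable")
    out.loc[ns_mask, "direction"] = "ns"
    return out


# --- subgenome asymmetry ----------------------------------------------------

def subgenome_asymmetry(levels: pd.DataFrame, tetraploid_species: Iterable[str]) -> dict:
    """Cross-species consistency of subgenome (A - B) differences.

    ``levels`` has columns ``group_id, species, subgenome, level`` with one
    row per doublet-gene copy per species. Returns a dict with:

    * ``per_gene``: A-B difference per species and a cross-species
      sign-consistency flag (genes missing a species are excluded and
      counted in ``n_excluded``);
    * ``correlations``: Spearman correlation matrix over all
      (species, subgenome) per-gene level profiles;
    * ``mean_within_species_between_subgenome`` and
      ``mean_between_species_same_subgenome``: partition means of that
      matrix (the asymmetry signature: copies of the same subgenome in
      different species resemble each other more than the two subgenomes
      within one species do).
    """
    tetraploid_species = sorted(tetraploid_species)
    piv = levels.pivot_table(index="group_id", columns=["species", "subgenome"],
                             values="level", aggfunc="mean")
    needed = [(s, g) for s in tetraploid_species for g in ("A", "B")]
    for col in needed:
        if col not in piv.columns:
            piv[col] = np.nan
    piv = piv[needed]

    diffs = pd.DataFrame(index=piv.index)
    for s in tetraploid_species:
        diffs[s] = piv[(s, "A")] - piv[(s, "B")]
    complete = diffs.dropna()
    n_excluded = len(diffs) - len(complete)
    signs = np.sign(complete)
    if len(tetraploid_species) >= 2:
        consistent = (signs.nunique(axis=1) == 1) & (signs != 0).all(axis=1)
    else:
        consistent = pd.Series(np.nan, index=complete.index)
    per_gene = complete.copy()
    per_gene["consistent"] = consistent

    cols = [f"{s}_{g}" for s, g in needed]
    mat = pd.DataFrame(np.nan, index=cols, columns=cols)
    for (c1, col1), (c2, col2) in itertools.combinations(zip(cols, needed), 2):
        rho = profile_correlation(piv[col1], piv[col2])
        mat.loc[c1, c2] = mat.loc[c2, c1] = rho
    np.fill_diagonal(mat.values, 1.0)

    within, between = [], []
    for (c1, (s1, g1)), (c2, (s2, g2)) in itertools.combinations(zip(cols, needed), 2):
        rho = mat.loc[c1, c2]
        if np.isnan(rho):
            continue
        if s1 == s2 and g1 != g2:
            within.append(rho)
        elif s1 != s2 and g1 == g2:
            between.append(rho)

    frac = float(consistent.mean()) if len(complete) and len(tetraploid_species) >= 2 else float("nan")
    return {
        "per_gene": per_gene,
        "n_excluded": n_excluded,
        "sign_consistency_fraction": frac,
        "correlations": mat,
        "mean_within_species_between_subgenome": float(np.mean(within)) if within else float("nan"),
        "mean_between_species_same_subgenome": float(np.mean(between)) if between else float("nan"),
    }


# --- biased fractionation ---------------------------------------------------

def fractionation_bias_test(orthogroups: Iterable) -> dict:
    """Exact binomial test for biased post-WGD gene loss between subgenomes.

    Only singleton groups carry a loss signal: a singleton surviving in
    subgenome A records a loss from B and vice versa. Tests the loss counts
    against an unbiased 0.5 split.
    """
    lost_from_a = lost_from_b = 0
    for g in orthogroups:
        if g.category != "singleton":
            continue
        (sub,) = g.tetraploid_copies.keys()
        if sub == "A":
            lost_from_b += 1
        elif sub == "B":
            lost_from_a += 1
    n = lost_from_a + lost_from_b
    if n == 0:
        return {"lost_from_A": 0, "lost_from_B": 0, "p": float("nan"), "testable": False}
    p = stats.binomtest(lost_from_a, n, 0.5, alternative="two-sided").pvalue
    return {"lost_from_A": lost_from_a, "lost_from_B": lost_from_b,
            "p": float(p), "testable": True}


# --- enrichment -------------------------------------------------------------

def enrichment_hypergeometric(gene_set: Iterable[str], annotation: pd.DataFrame,
                              universe: Iterable[str]) -> pd.DataFrame:
    """Per-category enrichment of ``gene_set`` within ``universe``.

    ``annotation`` has columns ``gene_id, category``. For each category with
    K universe members, of which k are in the n-gene set drawn from the
    N-gene universe, p = P(X >= k) under the hypergeometric null; q by BH
    across categories.
    """
    universe = set(universe)
    gene_set = set(gene_set)
    if not gene_set <= universe:
        raise InputError("gene set must be a subset of the universe")
    if not gene_set:
        return pd.DataFrame(columns=["category", "k", "K", "n", "N", "p", "q"])
    ann = annotation[annotation["gene_id"].isin(universe)]
    N = len(universe)
    n = len(gene_set)
    rows = []
    for cat, sub in ann.groupby("category", sort=True):
        members = set(sub["gene_id"])
        K = len(members)
        k = len(members & gene_set)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"category": cat, "k": k, "K": K, "n": n, "N": N, "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
    return out
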