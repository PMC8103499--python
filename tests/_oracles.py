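"""Independent brute-force oracles for the statistics kernels.

Everything here is deliberately naive: explicit loops, explicit
enumerations, its own hard-coded genetic code. These implementations are
the reference the package kernels are checked against and must not share
code with them.
"""

import itertools
import math

import numpy as np

# hard-coded standard genetic code (independent of the package's table)
_BASES = "TCAG"
_AAS = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
GENETIC_CODE = {
    a + b + c: _AAS[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}


def pi_brute(alleles, gene_length):
    """Average pairwise differences per site by explicit pair loops."""
    n = len(alleles)
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            for a, b in zip(alleles[i], alleles[j]):
                if a != "N" and b != "N" and a != b:
                    total += 1
    n_pairs = n * (n - 1) // 2
    return total / (n_pairs * gene_length)


def dxy_brute(alleles_a, alleles_b, gene_length):
    total = 0
    for ha in alleles_a:
        for hb in alleles_b:
            for a, b in zip(ha, hb):
                if a != "N" and b != "N" and a != b:
                    total += 1
    return total / (len(alleles_a) * len(alleles_b) * gene_length)


def ng86_brute(seq1, seq2):
    """Nei-Gojobori by explicit pathway enumeration (independent code path).

    Mirrors the documented conventions: changes to stop codons are
    nonsynonymous for site counting; pathways through stop codons are
    excluded unless all are blocked.
    """
    assert len(seq1) == len(seq2) and len(seq1) % 3 == 0
    codons1 = [seq1[i:i + 3] for i in range(0, len(seq1), 3)]
    codons2 = [seq2[i:i + 3] for i in range(0, len(seq2), 3)]

    def syn_sites(codon):
        s = 0.0
        for pos in range(3):
            for b in "ACGT":
                if b == codon[pos]:
                    continue
                mut = codon[:pos] + b + codon[pos + 1:]
                if GENETIC_CODE[mut] == GENETIC_CODE[codon]:
                    s += 1 / 3
        return s

    S = (sum(map(syn_sites, codons1)) + sum(map(syn_sites, codons2))) / 2
    N = len(seq1) - S

    sd = nd = 0.0
    for c1, c2 in zip(codons1, codons2):
        positions = [p for p in range(3) if c1[p] != c2[p]]
        if not positions:
            continue
        paths = []
        for order in itertools.permutations(positions):
            cur = c1
            steps = []
            blocked = False
            for p in order:
                nxt = cur[:p] + c2[p] + cur[p + 1:]
                if GENETIC_CODE[nxt] == "*":
                    blocked = True
                steps.append((cur, nxt))
                cur = nxt
            paths.append((blocked, steps))
        usable = [steps for blocked, steps in paths if not blocked]
        if not usable:
            usable = [steps for _, steps in paths]
        ssum = nsum = 0.0
        for steps in usable:
            for a, b in steps:
                if GENETIC_CODE[a] == GENETIC_CODE[b] and GENETIC_CODE[a] != "*":
                    ssum += 1
                else:
                    nsum += 1
        sd += ssum / len(usable)
        nd += nsum / len(usable)

    def jc(p):
        if p >= 0.75:
            return float("nan")
        return -0.75 * math.log(1 - 4 * p / 3)

    ps = sd / S if S else 0.0
    pn = nd / N if N else 0.0
    ds, dn = jc(ps), jc(pn)
    ratio = dn / ds if (ds == ds and ds > 0 and dn == dn) else float("nan")
    return dn, ds, ratio


def cmh_brute(strata):
    """CMH statistic by direct per-stratum evaluation of the formula."""
    num = 0.0
    den = 0.0
    for (a, b), (c, d) in strata:
        n1, n2 = a + b, c + d
        m1, m2 = a + c, b + d
        n = n1 + n2
        if n1 == 0 or n2 == 0 or m1 == 0 or m2 == 0:
            continue
        num += a - n1 * m1 / n
        den += n1 * n2 * m1 * m2 / (n ** 2 * (n - 1))
    if den == 0:
        return float("nan")
    return num ** 2 / den


def fisher_brute(table):
    """Two-sided Fisher exact p by full enumeration over the support."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = prob(a)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs + 1e-12)


def hypergeom_tail_brute(k, N, K, n):
    """P(X >= k) for X ~ Hypergeometric(N, K, n) by direct summation."""
    return sum(math.comb(K, x) * math.comb(N - K, n - x) / math.comb(N, n)
               for x in range(k, min(K, n) + 1))


def binom_two_sided_brute(k, n, p=0.5):
    """Two-sided exact binomial p: sum of outcomes no more likely than k."""
    pk = math.comb(n, k) * p ** k * (1 - p) ** (n - k)
    total = 0.0
    for x in range(n + 1):
        px = math.comb(n, x) * p ** x * (1 - p) ** (n - x)
        if px <= pk * (1 + 1e-9):
            total += px
    return min(1.0, total)


def average_ranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1
    return ranks


def wilcoxon_exact_brute(x, y):
    """Exact two-sided rank-sum p: enumerate every assignment of the pooled
    (tied-average) ranks to the x positions."""
    pooled = list(x) + list(y)
    ranks = average_ranks(pooled)
    nx = len(x)
    W = sum(ranks[:nx])
    sums = [sum(c) for c in itertools.combinations(ranks, nx)]
    lo = sum(1 for s in sums if s <= W + 1e-9)
    hi = sum(1 for s in sums if s >= W - 1e-9)
    return W, min(1.0, 2 * min(lo, hi) / len(sums))


def spearman_brute(x, y):
    """Average-rank Spearman via explicit rank-then-Pearson computation."""
    rx = average_ranks(list(x))
    ry = average_ranks(list(y))
    mx = sum(rx) / len(rx)
    my = sum(ry) / len(ry)
    cov = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    vx = math.sqrt(sum((a - mx) ** 2 for a in rx))
    vy = math.sqrt(sum((b - my) ** 2 for b in ry))
    return cov / (vx * vy)


def bh_brute(pvalues):
    """Benjamini-Hochberg adjusted p-values, direct step-up definition."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvalues[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return adj


def best_chain_brute(points, max_gene_gap, gap_penalty):
    """Maximum monotone-chain score by depth-first enumeration.

    ``points`` are (r1, r2, score) anchors; chains must be strictly
    increasing in r1 and strictly monotone (either direction) in r2 with
    rank gaps bounded by ``max_gene_gap``; score is anchor sum minus linear
    gap penalties. Returns the best score over all chains of any length.
    """
    best = -math.inf

    def extend(chain_score, last, direction, remaining):
        nonlocal best
        best = max(best, chain_score)
        for idx, (r1, r2, s) in enumerate(remaining):
            if last is not None:
                l1, l2 = last
                if r1 <= l1 or abs(r1 - l1) > max_gene_gap:
                    continue
                if direction == +1 and (r2 <= l2 or r2 - l2 > max_gene_gap):
                    continue
                if direction == -1 and (r2 >= l2 or l2 - r2 > max_gene_gap):
                    continue
                if direction == 0 and (r2 == l2 or abs(r2 - l2) > max_gene_gap):
                    continue
                new_dir = direction if direction != 0 else (1 if r2 > l2 else -1)
                pen = gap_penalty * ((r1 - l1 - 1) + (abs(r2 - l2) - 1))
            else:
                new_dir = 0
                pen = 0.0
            extend(chain_score + s - pen, (r1, r2), new_dir,
                   remaining[:idx] + remaining[idx + 1:])

    extend(0.0, None, 0, list(points))
    return best
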