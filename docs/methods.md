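# Methods

`dupevo` re-implements, as a tested desk-scale pipeline, the comparative
genomics and epigenomics workflow used to study duplicated-gene evolution in
an allopolyploid species complex: an allotetraploid lineage (three descendant
species, here named ginseng, quinquefolius and japonicus, sharing one
tetraploidization) and a diploid relative (notoginseng), with a conserved
eudicot outgroup genome for deep-collinearity context. This note documents
the models, estimators, defaults and numerical choices, and what the
synthetic data generator does and does not emulate.

## Duplicate-gene classification

**Anchor chaining.** Homolog anchor pairs (a BLAST/MCScanX-style tabular hit
list) are chained into collinear blocks by dynamic programming in gene-rank
space: a block is a maximum-score chain with ranks strictly increasing on
side 1 and strictly monotone on side 2, adjacent rank gaps bounded by
`max_gene_gap` (default 25), score = Σ anchor scores − `gap_penalty` (default
1.0) × Σ rank gaps, and at least `min_block_anchors` (default 5) anchors.
These defaults follow common MCScanX practice. Blocks are extracted greedily
(best chain first, anchors consumed); for ≤ 12 anchors the chain score is
provably the exhaustive-search optimum (regression-tested). Ties are broken
toward the smaller total rank gap, then the lexicographically smallest
starting gene id, so output is deterministic. Within a self comparison,
anchors joining two genes on the same scaffold fewer than `max_gene_gap`
ranks apart are excluded from chaining — local tandem arrays otherwise
masquerade as short collinear blocks.

**Ortholog groups.** Groups are connected components over anchors inside
diploid↔tetraploid blocks and cross-subgenome (A↔B) blocks. Categories:
*singleton* (one subgenome copy retained, diploid ortholog present),
*doublet* (both subgenome copies, no diploid ortholog), *triplet* (both
copies plus the diploid ortholog); doublet totals in the classical sense are
doublet + triplet. Where duplicated segments contribute extra collinear
copies, the copy with the highest summed anchor score represents its
subgenome. Subgenome assignment is read from the annotation (GFF3
`subgenome` attribute), never inferred.

**Collinearity depth.** A gene's depth is the number of distinct blocks
covering it; depth strictly greater than 4 yields the *ancient collinear*
label (evidence of retention through ancient polyploidizations), and
membership in any block against a designated outgroup eudicot taxon yields
*conserved eudicot*.

**SSD modes.** Same-subgenome duplicate pairs (cross-subgenome pairs are
WGD homoeologs and are excluded, mirroring tools that remove WGD pairs
first) are classified with the priority *segmental* (pair is an anchor of an
intra-genome block) > *tandem* (rank gap exactly 1) > *proximal* (rank gap
in (1, `proximal_max_rank_gap`], default 10) > *transposed* (exactly one
copy collinear with the diploid outgroup; the non-collinear, novel-locus
copy receives the label) > *dispersed* (everything else). Transposed
detection is outgroup-collinearity-based; the alternative intra-genome rule
is not implemented.

**Families.** Reciprocal best-scoring hits per (gene, partner taxon) define
a graph whose connected components are families; families whose members all
belong to the focal taxa are *lineage specific*.

## Population-genetic statistics

Variant filtering retains sites with MQ > 30 and read depth > 3 (both
strict); the gene length is unchanged, since removed sites return to the
monomorphic denominator. Per-gene nucleotide diversity is
π = Σ pairwise mismatches / (n_pairs × L) with pairwise deletion of missing
calls and the full gene length L as denominator (VCFs omit invariant
sites). Between-population divergence dxy uses all inter-population
haplotype pairs over the same denominator; for orthologs called against two
different assemblies, positions where the two reference sequences disagree
are counted as fixed differences. Where a diploid gene maps to both
subgenome copies, cross-reference comparisons use one designated
representative (the lexicographically smallest tetraploid id, i.e. the
subgenome-A copy under the default naming).

Selection pressure is estimated with the Nei–Gojobori (1986) counting
method: synonymous site counts averaged over both sequences (mutations to
stop codons counted as nonsynonymous), multi-difference codons averaged
over all mutational pathways excluding those through stop codons (all
pathways used if every one is blocked), and Jukes–Cantor correction
d = −(3/4)·ln(1 − (4/3)p). dS = 0 flags the ratio undefined. A counting
estimator is a deliberate, self-contained choice over ML codon models; it
is adequate for the class-wise distribution comparisons this package makes,
which depend on rank structure rather than absolute rates.

Gene presence in a resequenced panel is mean read depth ≥ 0.2 × the
genome-wide median (the relative threshold is configurable; 0.2 is the
package default, chosen so that genuinely absent genes at < 10% of median
depth are unambiguous).

## Methylation statistics and DMG calling

Cytosine sites are retained when their total (methylated + unmethylated)
depth is strictly above 10 in **every** sample of the comparison. Gene-body
methylation per context is the weighted level Σ meth / Σ total over
retained sites — robust to uneven coverage, unlike averaging per-site
fractions. A gene with no retained site is excluded, not scored 0.

DMGs between two species are called per context in three steps on genes
fully mapped in both species (every replicate with ≥ 1 retained site in the
gene body):

1. **Intraspecific consistency** — no replicate pair differs by ≥ 10
   percentage points with that difference Fisher-exact significant at
   α = 0.01. (A difference must be both large *and* significant to
   disqualify; rejecting on test significance alone would discard ~α of
   true DMGs per replicate pair from count noise, defeating the filter's
   false-positive-minimizing purpose.) With fewer than two replicates the
   criterion is skipped and flagged.
2. **Effect size** — the interspecific weighted-level difference exceeds
   50 percentage points.
3. **Gene-body extent** — the gene body is tiled into 20 equal-width
   windows; per window, a Cochran–Mantel–Haenszel test over strata
   (replicate i of species 1 vs replicate i of species 2, pairing the
   first min(r₁, r₂) replicates in sorted order) with M² =
   [Σ(aₖ − E aₖ)]² / Σ Var aₖ, no continuity correction (this keeps the
   single-stratum identity M² = (n−1)/n × Pearson χ² exact); BH correction
   across all windows of all genes per context; more than 10% of the
   windows with data must reach q < 0.01. Windows with no covered site are
   excluded from the denominator.

The stratification by replicate pairs and the 20-window tiling are package
choices (both configurable); degenerate strata (a zero margin) are dropped
with a warning. Profile correlations are Spearman with average ranks.

## Class-wise comparisons

Each class is compared against the full annotated set ("overall") per
statistic with the two-sample Wilcoxon rank-sum test: exact enumeration of
all rank assignments (average ranks for ties, two-sided p as the doubled
smaller tail) when the combined n ≤ 12, otherwise the normal approximation
with tie-corrected variance and continuity correction. Direction labels
come from the median difference and are reported only when the BH-adjusted
q < 0.05; BH families are one per statistic table. Biased fractionation is
an exact two-sided binomial test of per-subgenome loss counts (singleton
groups only — retained pairs carry no loss signal). Enrichment is the upper
hypergeometric tail over a user-supplied gene→category table; no real
pathway databases are consulted.

## The synthetic data generator

The generator emulates the study design, not the organisms' full biology:

* **History.** One tetraploidization shared by three descendant species on
  the fixed tree ((ginseng, quinquefolius, japonicus), notoginseng), two
  parental subgenomes A/B, independent post-WGD copy loss (rate
  `fractionation_prob` per copy, split between subgenomes by
  `fractionation_bias`), diploid-lineage gene loss, a conserved outgroup
  genome carrying a subset of ancestral genes in order, and planted SSD
  events of all five modes (copies stay within the donor's subgenome).
  Ancient collinearity is emulated by planting extra collinear copies of a
  gene run (so run members are covered by > 4 blocks), not by simulating
  the actual paleo-triplications.
* **Sequences.** Random stop-free codon sequences evolve by Jukes–Cantor
  substitution along fixed branch lengths (scalable per branch);
  nonsynonymous proposals are accepted with a per-gene probability ω drawn
  by class (ancient-collinear low and tight, dispersed high and wide) —
  the simplest model that produces the rank and variance structure the
  comparisons consume. No indels, no codon-usage bias, no recombination.
* **Populations.** Haplotypes carry the species consensus plus biallelic
  polymorphism planted at per-site rate 2π with allele frequency 1/2 in
  expectation, which makes per-gene π unbiased for the target; per-gene
  lognormal diversity multipliers give singleton genes a higher and wider
  π distribution. A configurable fraction of sites carries failing MQ/DP
  metadata with garbage genotypes so the variant filter is load-bearing.
  Coalescent structure (linkage, site-frequency spectra) is *not* modeled:
  passing tests show estimator correctness and rank recovery, not realism
  of allele-frequency dynamics.
* **Methylomes.** Per-site counts are Binomial(coverage ~ Poisson(30),
  gene-level mean), matching the count-data assumptions of the CMH test.
  The gene-level mean is hierarchical: class mean (per context; CG > CHG >
  CHH, ancient-collinear hypomethylated, dispersed hypermethylated,
  singletons above retained doublets/triplets) + gene effect + an
  ancestral subgenome-copy effect shared identically by the three
  tetraploid species (sd `meth_copy_sd` = 0.10 — this *is* the inherited
  asymmetry signature; a planted subset of doublets gets a fixed ±0.2
  offset instead) + species effect (sd 0.06) + tetraploid-clade effect
  (sd 0.05) + small species×copy and replicate effects (sd 0.03 / 0.02).
  Because the copy effect is ancestral, the null expectation of ~25%
  three-species sign agreement only applies when it is disabled
  (`meth_copy_sd = 0`), which is how the null calibration is simulated.
  DMGs are planted per species pair as 0.85 vs 0.15 level overrides
  (difference 0.7 > the 0.5 calling threshold) on genes unused by any
  other planting. Bisulfite conversion error and intergenic cytosines are
  not modeled (only gene-body sites are emitted; no downstream operation
  consumes intergenic sites).
* **Defaults** emulate the study shape: 4 accessions per species for
  variants, 2 methylome replicates per species (the study design's two
  individuals per species; recovery tests use 3), mean coverage 30×,
  planted π of 0.0004 / 0.0022 / 0.0039 / 0.0010 for ginseng /
  quinquefolius / japonicus / notoginseng (the published rank structure;
  only the ranks are asserted anywhere).

Determinism: every operation seeds its own generator from (seed, stage
index), so `simulate_genomes`, `simulate_population_variants` and
`simulate_methylomes` are independently reproducible and the full pipeline
reproduces byte-identical outputs (SHA-256 manifest) for a fixed config.

## Problem sizes

The shipped tests and the acceptance script run at desk scale by choice:
200–1,000 ancestral genes, 300 bp genes, 2–4 scaffolds per subgenome.
These sizes are large enough for exact category-count recovery, ≥ 90%
planted-event recall and 3-SE statistical bands, while keeping every run
reproducible on a laptop.

## Known limitations

* Transposed-duplicate detection needs the donor's ancestral locus to sit
  inside a recovered diploid–tetraploid block; sparse or heavily
  fractionated regions can demote transposed copies to dispersed.
* dxy across two assemblies assumes orthologs of equal length (no
  alignment step); the generator guarantees this, real data may not.
* The CMH stratification by paired replicates discards unpaired replicates
  beyond min(r₁, r₂).
* NG86 saturates (JC correction undefined) for p ≥ 0.75; such pairs are
  flagged, not extrapolated.
* The intraspecific DMG filter reads the published criterion as
  "large AND significant difference disqualifies"; the alternative reading
  (any non-significant test disqualifies) is stricter and was rejected —
  see the DMG section above.
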