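# Methods

## Problem and model

In a chicken × quail F1 hybrid, the two alleles of each gene come from
different species whose transcripts differ by nucleotide substitutions.
Reads that overlap a diverged site map within the mismatch budget to only
one parental reference; counting such species-specific reads per gene
measures allele-specific expression. The biological question is posed as a
stage contrast: for each series — quail (Q), chicken (G), and the hybrid's
quail- and chicken-derived alleles (HQ, HG) — is a gene upregulated,
downregulated, or unaltered between blastoderm stage X and stage XIII/XIV?
A gene upregulated in both parental series whose hybrid shows upregulation
of neither allele is classified as misregulated (pattern D). Because
mapping efficiency differs between reference genomes, expression levels are
never compared across species directly; only within-series stage changes
are compared across series.

## Synthetic data generator

The generator emulates the study design, not any particular dataset.

- **References.** Genome A (chicken side) is uniform random DNA, one
  transcript per gene (default 1,000 genes × 1,000 nt); genome B (quail
  side) substitutes each site independently with probability
  `divergence_rate` (default 0.07, the mean coding divergence scale of
  chicken vs quail), choosing uniformly among the three alternative bases.
  Divergence is substitution-only: no indels, so coordinates are shared
  between genomes and ungapped verification is exact.
- **Program.** A fraction `up_both_fraction` (default 0.1) of genes is
  upregulated in both parents; of these, `misregulation_fraction` (default
  0.5) is planted as pattern D (both hybrid allele log2FCs zeroed), the
  rest as pattern A. Remaining genes draw a shared parental direction
  (10% up / 10% down / 80% unaltered) and a `parent_discordance` fraction
  (default 0.35) redraws the chicken direction independently — real
  parental species share only part of their stage response, and without
  this partial divergence the cross-series concordance ordering would be
  degenerate. A redraw never re-creates an up-in-both gene, so the
  eligible-class prevalence stays exactly as planted. Planted effects are
  ±2 on the log2 scale (safely past the FC > 2 call boundary).
- **Counts.** Negative binomial with Var = μ + αμ² (default α = 0.05,
  baseline mean 200); the expected count is
  `library_size_factor × baseline × 2^lfc` at stage XIII/XIV. Hybrid
  samples emit two allele-level columns (HQ, HG) at half the series mean —
  symmetric allele usage; within-stage allelic imbalance is out of scope.
- **Reads.** FR-oriented 100 bp pairs from fragments of N(250, 25²) nt
  clipped to [150, 350], start positions uniform, per-base error 0.001
  substituting a random different base; constant quality "I". Fragments
  are allocated multinomially with weights expression × length. A truth
  table records (read id → gene, genome, position) for every pair.
- **Design.** Default 3 replicates per (series, stage, sex) cell — the
  published per-cell sample counts appear only in a figure, so the
  replication level is a configurable package default, not a claim about
  the study.

What the generator does **not** model: GC/positional bias, PCR duplicates,
intron structure or splicing, indel divergence, allelic imbalance, and
mapping-efficiency asymmetries beyond sequence divergence itself. Passing
tests therefore demonstrate the correctness and statistical behavior of
the analysis logic under an idealized sequencing model, not performance on
real libraries.

## Dual-genome classification

An exact k-mer index (default k = 31) over the forward strands of both
genomes drives a seed-and-verify search: every location reachable by any
exact k-mer of the read or its reverse complement is verified by
full-length Hamming comparison, and all locations within the mismatch
budget (default 2; `N` always mismatches) are reported. With two
mismatches on a 100 nt read, a true location can evade a 31-mer seed only
if the mismatches split every window; the test suite therefore also proves
seeded ≡ brute-force equivalence at k = 15, where ⌈100/3⌉ ≥ 15 guarantees
an intact seed.

Pair classification per genome keeps the best-mismatch concordant pairing
(same gene, opposite strands, FR orientation, fragment span within
[150, 350]); more than one distinct best location discards the pair as
multimapped. Pairs concordant in exactly one genome are species-specific;
in both, common (removed before allelic counting); otherwise unmapped /
orphan / discordant by how many mates mapped. "Common" is presence-based:
a better mismatch total on one side does not rescue a pair that maps
concordantly to both genomes. Parental-mode samples consult only the
conspecific genome. Orphan elimination is ordered after the multimap check
and before the specific/common split; the order cannot affect concordant
pair counting, which is all the quantification consumes.

## Differential expression

A deliberately small DESeq2-style analogue, per (series, sex) matrix:

- **Size factors**: median-of-ratios against the geometric-mean
  pseudo-reference over genes with all-positive counts.
- **Dispersion**: per-gene method of moments on normalized counts,
  α̂ = max(α_min, (pooled within-group variance − pooled mean)/pooled
  mean²), α_min = 1e−8. At 3 vs 3 replicates this estimate carries only
  4 degrees of freedom, and plugging it into a normal-reference Wald test
  is anti-conservative (measured null raw-p < 0.05 fraction ≈ 0.13).
  `de_analysis` therefore moderates the per-gene values toward the
  family-wide mean with prior weight 10 df — a precision-weighted common-
  dispersion squeeze in the spirit of edgeR, deliberately *not* a
  mean-dispersion trend. After moderation the null fraction is ≈ 0.05–0.06
  and power at the planted effect size is unchanged (≈ 1.0). A t-reference
  alternative was rejected: t(4) restores calibration but its heavy tail
  halves power at planted log2FC = 2.
- **Fit and test**: the per-stage NB log-likelihood at fixed α is strictly
  concave in log(mean), so each group mean is the unique root of the score
  (bracketed root finding, xtol 1e−12). log2FC = log2(q_XIII/XIV / q_X);
  the SE comes from the observed information of the two log2-scale mean
  parameters at the fit; p is the two-sided normal tail of log2FC/SE. An
  all-zero stage group is floored at 0.5/mean(size factor). BH adjustment
  is applied within one (series, sex) family.
- **Direction call** (strict inequalities, fixed thresholds): up iff
  FDR < 0.05 and FC > 2; down iff FDR < 0.05 and FC < 0.5; else unaltered.
  FC is oriented stage XIII/XIV over stage X, so developmental
  upregulation means FC > 2.

Not implemented, by design: dispersion/LFC shrinkage toward trends,
outlier (Cook's distance) handling, independent filtering, multi-factor
designs.

## Patterns and sets

Each sex's analysis universe is the intersection of the four series'
retained-gene lists (the low-count filter runs per series × sex matrix, the
scope each stage contrast actually uses). Pairwise concordance reports the
3×3 direction table, the diagonal share (one decimal), and Pearson's r of
the paired log2FCs. Eligibility requires up in both parents; among
eligible genes the hybrid allele pair maps to A (both up), B (chicken
allele only), C (quail allele only), D (neither). Per-sex profiles
combine into eligible/pattern-D unions ("male and/or female") and the
pattern-D intersection (both sexes). The four-digit code (1 = up,
2 = down, 0 = unaltered over Q, G, HQ, HG) is cosmetic output; the digit
assignment for down/unaltered is a package convention.

## Overrepresentation

One-sided hypergeometric upper tail P(X ≥ k) per term with K ≥ 1 population
genes (terms with K = 0 are untestable and skipped), BH over tested terms,
significance at FDR < 0.05. The population defaults to the analyzed-gene
universe, mirroring the use of an organism reference set; no term-graph
propagation is applied. The synthetic annotation generator plants one term
enriched in true pattern-D genes so the enrichment stage is exercisable
end to end.

## Determinism and scale

A single global seed derives per-stage substreams by hashing the stage
name, so any stage reproduces in isolation and full reruns are
byte-identical (manifest records parameters and output checksums). The
default `run_all` read-level scale (60 genes, 2,000 pairs per library;
both configurable, with `reads_per_sample: null` matching the full NB
count depth) exercises the complete FASTQ → pattern path in about a
minute; the
full-scale statistical properties (1,000 genes, 3 replicates/cell) are
established at the count level, where read simulation adds sampling noise
but no new logic. Problem sizes in the test suite follow the same split.

## Known limitations

- The mapper is transcript-space, ungapped and substitution-only; it is
  not a general spliced aligner and has no mapping-quality model.
- Calibration and recovery results are specific to the idealized NB
  generator; real data dispersion trends and outliers would need the full
  DESeq2 machinery this package intentionally simplifies.
- With shallow read depth the hybrid allele counts (half depth, minus
  common-read loss) lose power first, inflating false pattern-D calls;
  the default study depth avoids this regime.
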