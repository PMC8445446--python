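# Methods

This note records the statistical model, parameter defaults, numerical
conventions, and the design and limits of the synthetic-data generator.

## 1. Candidate set: leads and LD proxies

Lead SNPs are taken from a GWAS-catalog-style table and kept when the
reported p-value is strictly below `gwas_p_max` (default 5e-8). Each lead is
expanded against a phased haplotype panel (0/1 alleles, sites × haplotypes).
For two sites with allele-1 frequencies `pA`, `pB` and 1/1-haplotype
frequency `p11`:

```
D   = p11 − pA·pB
D'  = |D| / Dmax,   Dmax = min(pA(1−pB), (1−pA)pB)   if D > 0
                    Dmax = min(pA·pB, (1−pA)(1−pB))  if D < 0
r²  = D² / (pA(1−pA)·pB(1−pB))
```

A panel site within `window` (default 1 Mb) of a lead joins Tier 2 when
`r² > 0.6` (strict) and `D' ≥ 1` compared with a 1e-9 tolerance, so the
exact-equality criterion D' = 1 survives floating point. Conventions:

- A monomorphic margin makes LD undefined; such sites raise an error at the
  statistics level and are skipped with a warning during expansion. Coercing
  to 0 (or D' = 1) would silently distort the candidate set.
- A site that is both a lead and someone's proxy stays Tier 1, and lead-lead
  links are not recorded in the pairs table; the pairs table therefore counts
  (lead, Tier-2 proxy) relations only.
- r² and D' are clamped to [0, 1] to absorb float dust; the worked identity
  D' = 1 ⇔ at most three haplotype classes exist is tested exhaustively.

## 2. The prioritization funnel

Annotation inputs are BED intervals (0-based, half-open). SNP positions are
1-based and convert to the single-base interval `[pos−1, pos)`.

1. **Enhancer filter.** Segmentation records whose state tag is one of the
   six active-enhancer ChromHMM states (`13_EnhA1`, `14_EnhA2`, `15_EnhAF`,
   `16_EnhW1`, `17_EnhW2`, `18_EnhAc`) are selected and merged (overlapping
   *and* book-ended runs collapse), so a SNP occupies at most one enhancer
   region and region counts are well defined.
2. **TFBS filter.** "Located within TFBS-containing enhancers" is read as a
   positional conjunction: the SNP lies inside an enhancer AND inside a TFBS
   cluster. A looser reading (SNP in an enhancer that overlaps a TFBS
   anywhere) is available via `require_tfbs_in_enhancer=False`.
3. **Regulatory rank.** Ranks are the ordinal categories
   `1a < 1b < 1c < 1d < 1e < 1f < 2a < 2b < 2c < 3a < 3b < 4 < 5 < 6 < 7`
   (smaller = stronger evidence); a SNP passes when its rank is at least as
   strong as the threshold (default `2b`). A missing rank record fails the
   filter — absence of evidence is not evidence.

Survivors are the *high-probability causal enhancer SNPs*. Funnel attrition
is asserted monotone at orchestration level. Independently, SNPs inside
lncRNA transcripts are annotated (one row per SNP-transcript pair) and a Venn
report counts overlaps between the high-probability set, eQTL SNPs, and
lncRNA SNPs.

Distance convention (tools differ, so it is fixed here): a point inside an
interval has distance 0; one base outside either edge has distance 1
(`p0 ≥ end → p0 − end + 1`; `p0 < start → start − p0`), matching the
adjacency-is-one convention of `bedtools closest -d`. Nearest-feature ties
are all reported, with the lowest (chrom, start) as primary.

## 3. eQTL circuits

Associations (variant, gene, tissue, nominal p, slope) are kept when
`p < 5e-8` (strict) and the slope is finite and nonzero. Retained rows
collapse into a bipartite SNP→gene graph with one edge per distinct
(variant, gene) pair. Edge direction follows the **unanimity rule**: `up` if
every tissue slope is positive, `down` if every one is negative, `mixed`
otherwise; mixed edges can be expanded per tissue. Tissue counts are
distinct-tissue counts. Per-gene summaries aggregate a gene's edges with the
same rule (Gene / Cluster / Direction / Tissue N).

Nearest genes use the full gene span, not the TSS. The discordance statistic
is the fraction of eQTL target genes that are not the nearest gene of *any*
of their eQTL SNPs; it is `None` (undefined, not zero) on empty input.

## 4. Expression clustering

Genes are clustered on per-tissue median-TPM profiles: euclidean metric,
complete linkage (scipy), tree cut at a fixed cophenetic height, default
7.6 — the cut that produced the 28-group partition of the case study's
candidate risk genes. Group ids are relabelled by first occurrence so the
partition is deterministic and permutation-invariant up to relabelling. An
optional `log10(x+1)` transform is available. Relative expression for heatmap
display rescales each row to [0, 1]; constant rows map to zero and are
flagged.

## 5. Enrichment

**ORA.** Exact hypergeometric upper tail: for a query of `n` universe genes,
a term of `K`, overlap `k`, `p = P(X ≥ k) = hypergeom.sf(k−1, N, K, n)`;
equivalent to the one-sided 2×2 exact test (verified against
`scipy.stats.fisher_exact` in the suite). Benjamini–Hochberg adjustment via
statsmodels; zero-overlap terms get p = 1.

**Cell-type specificity test** (a simplified SNPsea). Per cell type, a
gene's expression share (expression / row sum) is ranked descending and
divided by the number of genes, giving a specificity percentile in (0, 1];
a locus scores the minimum percentile over its genes; the per-cell-type
statistic is Σ −log(locus score) over loci. The null redraws gene-count-
matched loci uniformly from the matrix; significance uses the add-one
estimator `p = (1 + #{null ≥ observed}) / (n_perm + 1)`, so p is never zero
and ties make the test conservative. Null calibration at n_perm = 99 over
1000 replicates is part of the acceptance suite.

## 6. Synthetic data generator

Design goal: every pipeline stage must be exercisable offline with known
ground truth.

- **LD blocks.** Each lead (allele frequency exactly 1/2) gets
  `proxies_per_lead` proxies derived from its haplotype column. The default
  `one_sided` mode flips an exact count `k = round(flip_prob · #zeros)` of
  the lead's 0-allele haplotypes to 1. Only three haplotype classes then
  exist, so D' = 1 *exactly*, and r² has the closed form
  `q(1−p)/(q + (1−q)p)` with q the lead frequency and p the flip fraction —
  0.8182 at the defaults (q = 1/2, p = 0.1), safely above the 0.6 threshold.
  A `symmetric` mode XORs Bernoulli noise onto every haplotype instead
  (correlation ≈ 1 − 2p at q = 1/2) but populates all four haplotype classes
  and therefore *fails* an exact D' = 1 criterion; it exists to demonstrate
  that distinction, not to feed the pipeline.
- **Annotations.** Every planted causal SNP sits at the midpoint of an
  active-enhancer segment, inside a TFBS cluster, carries a passing rank,
  and has at least one eQTL row with p drawn log-uniform *below* the
  significance threshold. Every non-causal SNP is assigned one of five
  failure patterns (nothing / enhancer only / enhancer+TFBS with failing or
  missing rank / rank only / TFBS only) so it fails at least one funnel
  condition; noise eQTL rows get p log-uniform *above* the threshold.
  Midpoint placement keeps recovery independent of boundary conventions,
  which are tested separately at the interval level.
- **Expression** is tissue-clustered (each gene high in one home tissue),
  and one gene set is enriched for the planted target genes.
- **Scale presets.** The desk-scale default (8 leads × 4 proxies, 120
  haplotypes) runs in well under a second. `paper_scale_bundle` arranges
  block sizes, annotation runs, rank assignments, and eQTL/lncRNA plans so
  that every recomputed stage count equals the case study's headline funnel
  (129 leads, 1,817 candidates, 1,939 pairs, 484/188, 140/85, 94, 26, 15
  eQTLs / 64 genes, 745/159, 78 SNPs / 42 lncRNAs); it generates and runs in
  a few seconds.

**Realism and limits.** The generator is a test harness, not a population-
genetics simulator: haplotypes have no recombination map or coalescent
structure, LD blocks are independent and noise-free outside the planted
proxies, annotation tracks are placed deterministically around SNPs rather
than drawn from genomic state frequencies, eQTL p-values are sampled around
the threshold rather than from an effect-size model, and expression archetypes
are caricatures of tissue specificity. These choices are deliberate: they make
planted-truth recovery a sharp, binary oracle (sensitivity = specificity = 1.0
across seeds) instead of a statistical tendency.

## 7. Determinism and artifacts

All randomness flows through `numpy.random.default_rng(seed)`. Pipeline
outputs are headered TSV plus JSON with sorted keys and no timestamps, so
re-running on identical inputs is byte-identical. The manifest echoes the
config, records SHA-256 checksums of all inputs, stage counts, and the
package version.
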