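# Methods

This note documents the models, conventions and design choices behind
`nashsom`: what each procedure assumes, which parameters matter, what the
simulator does and does not emulate, and where the design was genuinely
open.

## Somatic SNV calling

The caller operates on per-read pileup observations at candidate sites in a
tumor with a matched normal. The candidate alternate allele is the most
frequent non-reference base among high-quality tumor reads (ties break to
the lexicographically smallest base). Seven filters are then evaluated —
always all seven, with every p-value recorded, so a call carries a complete
filter profile rather than stopping at the first failure.

Parameters (`snv.SnvParams`), with defaults:

| parameter | default | meaning |
|---|---|---|
| `tumor_af_min` | 0.15 | tumor alt fraction must strictly exceed this |
| `normal_af_max` | 0.02 | normal alt fraction may equal but not exceed this |
| `tn_fisher_alpha` | 0.05 | tumor-vs-normal Fisher significance level |
| `hq_base_quality` | 10 | reads with phred Q strictly above this are "high quality" |
| `hq_coverage_min` | 10 | minimum HQ depth in both samples (inclusive) |
| `error_rate_f` | 0.1 | null rate of the sequencing-error binomial screen |
| `screen_alpha` | 0.01 | shared level of the four artifact screens (strict `p > alpha` passes) |
| `end_window` | 10 | bases from a read terminus counted as "near the end" |

Conventions that had to be pinned down:

* **Allele-fraction denominators** are high-quality reads only, consistent
  with the coverage gate; bases other than ref and alt are ignored in the
  2×2 tables.
* **Boundary semantics** are literal: "> 15%" strict, "no more than 2%"
  inclusive, "≥ 10×" inclusive, "p > 0.01" strict.
* **Binomial screen orientation.** The screen is stated as a pass on
  `p > 0.01` at `f = 0.1`. We define `p = P(X ≤ k)` under
  `Binomial(n_HQ, f)`: genuine variants with abundant support score near 1
  and pass, while sites whose alt support is improbably *low* for a real
  variant fail. The orientation is an explicit, logged parameter
  (`binom_orientation`) because the pass rule is meaningful under either
  tail; the lower tail is the one under which the rule filters in the
  intended direction.
* **Sidedness.** The tumor-vs-normal Fisher test defaults to one-sided for
  alt enrichment in the tumor (`tn_fisher_alternative="greater"`); the
  three artifact screens are one-sided in the direction that indicates an
  artifact (alt base qualities lower; alt enriched among repeat-aligned
  reads; alt enriched near read ends), so `p > 0.01` reads "no significant
  artifact signal".
* **"Repeat-aligned"** is operationalized as a per-read boolean
  multi-mapping flag in the pileup format.
* **"Within 10 bp of a read end"** means `min(d5', d3') < end_window`,
  i.e. the first or last 10 positions of a 100-base read (a uniformly
  placed site lands there with probability 0.2).

Monotonicity holds by construction at stages 1–4: adding alt reads with the
same qualities and positions can only raise the tumor alt fraction,
sharpen the tumor/normal contrast, raise coverage and raise the binomial
tail probability.

## Somatic indel filtering

Candidate generation is out of scope; candidates arrive as summary rows
(total coverage, supporting-read count and averages, median end offset,
strand split). The six criteria and the known-sites exclusion use literal
boundary semantics: coverage 29 fails and 30 passes; exactly 2 mean
mismatches fails; median offset exactly 10 fails ("within 10 bp"); a
strand fraction of exactly 0.20 passes ("< 20%" fails). "Forward- or
reverse-aligned … < 20%" is read as *either* strand deficient, i.e. the
smaller of the two fractions is compared — flagged as an interpretation in
the class docstring. Known-site matching requires the exact
(chrom, pos, ref, alt) tuple.

## Statistical core

All tests live in `nashsom.stats` with fixed conventions (see its module
docstring). Exact tests (Fisher, binomial tail, hypergeometric, exact
Wilcoxon) are computed from scipy's distribution primitives; the test suite
verifies them against independent brute-force enumeration oracles
(`math.comb` sums, exhaustive rank assignments) for all inputs with totals
up to 20. The Wilcoxon test is exact (full enumeration) for combined
samples up to 12 without ties, and otherwise uses a mid-rank normal
approximation with tie-corrected variance and a 0.5 continuity correction;
under the simulator's integer-quality null its type-I error at the 0.01
screen level is ≈ 0.010. Welch's form is the default for unpaired
comparisons (the cohort groups have unequal sizes and variances); a
pooled-variance option exists. The burden summary's "±" dispersion is
treated as a standard deviation, and the significance conclusion also holds
under the standard-error reading (both are computed by the acceptance
script).

One spec-level correction: the Benjamini–Hochberg step-up map is **not**
idempotent on arbitrary adjusted outputs (re-applying it rescales by
`m/i`). Idempotence is therefore asserted on genuine fixpoints of the map
(constant vectors, zero-padded vectors), alongside the properties that do
hold generally: adjusted ≥ raw, capped at 1, monotone along the sorted raw
order, and permutation-equivariant.

## Consequence annotation

The toy gene models are CDS-only (no UTR/splice/promoter classes). A
substitution inside a CDS is classified by translating its reference and
mutated codon on the coding strand, reverse-complementing for minus-strand
genes: synonymous, missense, stopgain or stoploss; anything outside every
CDS is noncoding. Coding indels are classified by length difference
(frameshift vs in-frame) and count as non-synonymous, matching how the
original analysis folded its single indel into the non-synonymous tally.
Recurrence and burden count non-synonymous records only by default
("mutated gene numbers" are distinct genes per sample; a per-call counter
is available). Percentages round half-up to one decimal.

## Expression analysis

Values are log2-scale throughout (log2 Cy5/Cy3 ratios; FPKM-like
abundances are `log2(x+1)`-transformed first). The two-group test behind
"p < 0.05" is a Welch *t*-test, recorded in the output metadata, with raw
(unadjusted) p-values; BH FDR is applied only in the paired design, where
the selection rule is raw `p < 0.05` **and** adjusted `p ≤ 0.15`.
"≥ 2-fold" means `|Δlog2| ≥ 1`, inclusive. Hierarchical clustering uses
1 − Pearson correlation with average linkage (a common choice for
expression heat maps; both are configurable in principle through scipy),
with samples pre-sorted by id so the tree is invariant to input column
order.

## Enrichment

Hypergeometric upper-tail test per gene set, universe fixed (defaulting to
all genes of the gene-model file), sets intersected with the universe
before testing, BH across *all* sets of the collection including
zero-overlap sets. The minimum-overlap floor (4 genes for expression
queries, 3 for mutation queries) is applied as a conjunction with the
adjusted-p threshold, after adjustment. Mutation pathways aggregate over
tumors: reported when significant in ≥ 3 samples.

## The simulator

The generator emulates the statistical structure of a paired tumor/normal
exome + expression study at desk scale:

* **Genome**: uniform-random A/C/G/T chromosomes (default 2 × 100 kb) with
  non-overlapping gene models; each CDS starts with ATG, ends with a stop,
  has length divisible by 3 and no internal stop codon; about half the
  genes are split by an intron; strands are random.
* **Reads** are 100 bases; site offsets within reads are uniform; base
  qualities are ~N(35, 4) rounded and clipped to [2, 40]; 5% of reads are
  repeat-flagged at baseline; depths are Poisson (mean 80 per sample, the
  normal defaulting to the tumor mean), resampled to be nonzero at truth
  loci.
* **Somatic variants** (default 20 per tumor, VAF 0.3) draw alt counts
  Binomial(depth, VAF) in the tumor; the matched normal receives a small
  leak (`normal_contamination`, default 0.5% of the tumor VAF), a
  realistic tumor-in-normal level for dissected adjacent tissue.
  **Germline variants** sit at VAF 0.5 in both samples. Both are planted
  inside CDS so gene and consequence truth are defined.
* **Artifact classes** (default 6 per class per tumor) carry tumor-only
  alt support shaped so exactly one screen sees them: end-biased sites put
  every alt read within 10 bases of a read terminus; repeat-biased sites
  flag every alt read as multi-mapping; low-quality-alt sites draw alt
  base qualities ~N(14, 2) clipped to [11, 20] — low, but above the Q > 10
  cut, so only the rank test (not the allele-frequency gate) can catch
  them.
* **Background loci** (default 500 per sample) carry only sequencing error
  (rate 0.001 per base), making specificity measurable; the exome-wide
  scale of a real capture is deliberately not reproduced.
* **Expression**: gene-wise baselines N(0, 0.5²) plus a planted group
  effect (default log2(2.5) on 50 of 1000 genes, sign random) plus
  N(0, 0.25²) noise; the paired design adds a per-pair baseline shift and
  defaults to 17 tumor/normal pairs, mirroring the human validation arm.
* **Gene sets**: planted enriched pathways draw 60% of their members from
  the "hot" list (planted DE or mutated genes); non-planted sets are drawn
  from the universe *excluding* hot genes, so the planted sets' hot-gene
  overlap dominates by construction.
* **Indel candidates**: clean rows passing every criterion plus one row
  violating exactly one criterion each, labelled in a `planted_fail`
  column.

Identical (seed, config) reproduces every output byte for byte; each
generator draws from an independent substream of the seed.

What the simulator does **not** emulate — and hence what passing tests do
not show about real data: alignment and mapping error beyond a binary
repeat flag, context-dependent and strand-asymmetric error profiles,
mutational signatures, copy number and tumor heterogeneity/subclonality,
batch and dye effects in expression, correlated genes, and realistic
pathway topology. Recovery rates here characterize the procedures under
their own model assumptions, not expected performance on real exomes.

## Problem sizes and numerical choices

The default test and acceptance workloads use 5 tumor/normal pairs, ~1,300
sites per pair (depth 80), a 1,000-gene expression matrix with 5-vs-5
groups, 20 gene sets over a 1,000-gene universe (1,000 null queries for
the family-wise check), and a 10-gene genome for the exhaustive
consequence sweep (~7,900 codon classifications). Exact-test oracle sweeps
cover all tables/configurations with totals ≤ 20 (~21,000 checks). These
sizes were chosen so the full suite runs in well under a minute while
every rate of interest has enough trials to be meaningful.

Numerical details: two-sided Fisher p-values sum all tables with
probability ≤ the observed probability times (1 + 1e-7) to absorb
floating-point ties; zero-variance t-tests return p = 1 when means agree
and raise otherwise; correlation distance matrices are symmetrized and
clipped at 0 before linkage; VCF floats are written with 4 significant
digits.

## Known limitations

* Multi-allelic sites are not modeled (plurality allele only).
* The indel module filters precomputed candidate summaries; it does not
  detect indels from reads.
* Gene models carry CDS blocks only, so regulatory and splice consequences
  cannot be assigned.
* The burden chi-square/frequency comparisons assume independent samples;
  no multiplicity correction is applied across genes in the frequency
  comparison, matching the original single-gene usage.
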