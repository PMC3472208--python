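# Methods

## Study design being modelled

The package targets a pooled allelic-expression design: RNA from the same N
diploid individuals is pooled and sequenced before (S0) and after (S1) a
stress treatment. Because individuals — hence genotypes — are identical in
the two pools, any change in the read-count ratio of a SNP's two alleles
between pools reflects a change in allelic *expression*, pointing to
cis-regulatory variation responding to the treatment. A parallel count-based
comparison of control (C1) versus stressed (S1) libraries, with three
population replicates per treatment, supplies total gene-expression changes;
and a combined-pool SNP catalogue supplies per-gene synonymous and
nonsynonymous variation for selection-signature (Ka/Ks) estimation.

## SNP calling from pooled pileups

Input is classic 6-column samtools pileup text. Read-base strings are
decoded per the format ( `.`/`,` = reference, `^X`/`$` stripped, `±n`
indel runs skipped, `*` kept for depth bookkeeping but never counted as an
allele, since only substitutions are analysed). Base calls below phred 20
and N calls are excluded from allele counts.

A site is called a SNP when (i) filtered depth ≥ `min_coverage`, (ii) the
two most frequent alleles include a minor allele with count ≥
`min_minor_count` and frequency ≥ `min_freq`, and (iii) a one-sided binomial
test rejects the hypothesis that the minor-allele reads are sequencing error:
P(X ≥ minor | depth, error_rate) < α. The binomial-error model is this
package's explicit, transparent formulation of the coverage/frequency/
p-value gate used by pooled SNP callers, with per-base error rate 0.01 by
default. Ties between the 2nd and 3rd allele are broken alphabetically and
logged; sites with more than two alleles above noise are analysed at their
top two.

Two profiles are shipped. The allelic-expression branch uses coverage ≥ 8,
minor count ≥ 2, then requires each pool's two-allele depth ≥ 20 when
pairing; pairing keeps only *consistent* SNPs — the same unordered allele
pair called in both pools. The "in both treatments" depth wording of the
original protocol is ambiguous between "in each" and "in either"; the
stricter per-pool reading (≥ 20 in each pool) is implemented. The selection
branch combines both pools' reads and uses coverage 20–8000 with minor
count ≥ 4; the 8000 cap is applied as a site filter.

## Differential allelic expression

Each consistent SNP yields the 2×2 table [[A_S0, B_S0], [A_S1, B_S1]].
The test is Pearson's chi-squared with df = 1 and *no* Yates continuity
correction (pooled counts are large; the correction is available by flag).
A zero allele column leaves the test undefined; such sites are skipped with
a warning. P-values are adjusted by Benjamini–Hochberg step-up
(statsmodels) and significance declared at FDR < 0.05.

"Concordance" of DAE with differential expression is operationalised as
membership: a significant DAE SNP is concordant when its host gene (by
1-based inclusive gene-span containment; intronic positions count) is
DE-significant. Because "correlated with differential expression" could
also be read directionally, a secondary count reports whether the
allele-A frequency shift and the host gene's log fold-change share a sign.

## Codon annotation and weighted site lengths

CDS models come from GFF3 CDS features grouped by Parent; the 5'-most
segment's phase is honoured (first segment on +, last on −) and models whose
phase-trimmed length is not divisible by 3 are excluded with a warning
rather than aborting a run. Coordinates are 1-based inclusive externally and
converted once at the boundary. Genomic SNPs are mapped to a spliced-CDS
offset honouring strand (alleles complemented on minus-strand genes), and
classified synonymous/nonsynonymous under the standard genetic code
(translation table 1 — plant nuclear genes).

Weighted site lengths implement transversion-penalised site counting: at
each codon position the three alternative bases always comprise one
transition and two transversions; transitions get weight 1, transversions
1/penalty (default 6). The position's nonsynonymous fraction is the
weighted share of amino-acid-changing alternatives, a codon's nonsynonymous
length is the sum over its three positions, and the synonymous length is
defined as 3 − nonsynonymous length, so the two partition each codon
exactly. Only the transition:transversion weight *ratio* affects the
fractions, so this convention pins down the computation while leaving the
penalty configurable; at penalty 1 the lengths reduce to unweighted
Nei–Gojobori site fractions. Changes that create or destroy a stop codon
count as nonsynonymous; the terminal stop codon and any codon containing N
are excluded from gene totals. Codons carrying two SNPs are annotated
independently against the reference codon.

## Pseudocounted Ka/Ks and selection classes

Per gene, Ka/Ks = ((N+1)/L_N) / ((S+1)/L_S). The +1 unit is added to the
SNP *counts*, not the lengths — the disambiguation is fixed by the bundled
worked-example table, where e.g. (11+1)/258 ÷ (0+1)/120 = 5.58 ≈ 5.6
reproduces the printed value, and is unit-tested across all 90 reference
genes. Six of those 90 printed rows differ from the recomputation by
exactly 0.1 under every rounding rule; the printed integer site lengths are
evidently rounded from fractional sums, so those rows are held to a ±0.1
band while the remaining 84 must match exactly.

Classes: ratio < 0.5 purifying, > 1.5 positive, else intermediate. A
separate strong-purifying cutoff (0.20) selects the conserved gene set for
enrichment contrasts. Table output rounds to one decimal using decimal
round-half-up (matching how printed tables round), with full precision
retained internally.

## Differential expression stand-in

The DE module is intentionally minimal: per gene, a two-sided Fisher exact
test on (gene reads vs all other reads) summed within each treatment, BH
(default, FDR 0.01) or Bonferroni adjustment, and log2 fold-changes on CPM
with a 0.5-read pseudocount at the mean library size. Summing replicates
discards biological overdispersion, so on real data this test is
anticonservative — on overdispersed synthetic counts it flags many genes
beyond the planted fold-changes, and it should not be used for real DE
inference. Its role here is pipeline plumbing: providing DE labels for the
concordance and enrichment stages on synthetic data. Negative-binomial
modelling is deliberately out of scope.

## Enrichment

One-sided (over-representation) Fisher exact per category on
[[subset∩cat, subset∖cat], [rest∩cat, rest∖cat]], BH across categories.
Genes mapping to no category remain in the background and count in the
complements (conventions vary; this one is configurable by simply dropping
such genes from the background argument). The default background is the
set of genes surviving the low-count filter, the natural expressed-gene
universe when the true annotation universe is unknown.

## Synthetic data: what it emulates, and what it does not

Pools are modelled at the expressed-allele-fraction level: a segregating
site has a true alternate-allele expression fraction p = k/2N (k drawn
uniformly within configurable bounds, default 0.1–0.9, N = 10 individuals),
and each pool's reads are Binomial(depth, p) with depth ~ negative binomial
(mean 80, dispersion 0.5 by default — RNA-seq-like overdispersion; variance
= mean + disp·mean²), sequencing errors sprinkled uniformly at rate 0.005,
and 5% of calls emitted below the Q20 filter to exercise quality filtering.
DAE sites shift p by ±`dae_effect` (default 0.3) in S1, choosing a direction
that stays inside (0.02, 0.98); non-DAE sites use identical fractions in
both pools. This is the minimal sufficient statistic for pooled
allele-count tests; it does *not* simulate read-level structure — individual
identity, mapping bias, positional error profiles, linkage between sites —
so passing recovery tests demonstrate correctness of the counting and
testing machinery, not robustness to alignment artefacts.

Selection classes are planted constructively: each gene draws a target
class from the configured mix (default 77/21/2 purifying/intermediate/
positive), and the generator searches small (N, S) count pairs whose
pseudocounted ratio, given the gene's actual weighted lengths, falls with a
safety margin inside the class band; it then places exactly those SNPs in
distinct codons, choosing (position, alternate base) pairs whose effect is
verified by an independent Biopython translation. Fold-changes in the
count matrix are applied to stress libraries of truth-DE genes (default
20% of genes at 8-fold, directions alternating).

Everything is driven by one `numpy` Generator seeded from the config, and a
fixed seed reproduces every output file bit-for-bit (tested). One JSON
manifest records config, seed and file names. Known simplifications:
individuals are equally weighted in the pool (real pools weight by tissue/
RNA contribution); expression fractions equal allele frequencies (no
cis-effect baseline imbalance except at planted DAE sites); gene models
always have phase 0 (phase handling is covered by hand-built fixtures).

## Numerical and testing choices

- Chi-squared and Fisher tests are scipy's; tests verify them against the
  closed-form 2×2 statistic and hypergeometric tail sums respectively, so
  the implementation route and the oracle route stay independent.
- BH adjustment is statsmodels'; verified against a hand-applied step-up
  example.
- The genetic-code table is generated locally and cross-checked against
  Biopython's translation for all 64 codons.
- Problem sizes in the statistical acceptance tests — 10,000 null sites at
  depth ≥ 50 for type-I error (observed rejection 0.051, 0 BH hits), ~3,100
  sites with 5% planted DAE at mean depth 200 for power (sensitivity 0.91,
  observed FDR 0.047), 20 genes through the full noise-free Ka/Ks path —
  were chosen as the smallest cohorts at which the binomial error bars on
  the measured rates are comfortably inside the asserted bands.
- Recovery tests fix their seeds; the quoted measurements are what those
  seeds produce deterministically.

## Known limitations

- No genotype likelihoods, indel calling, or strand-bias filtering.
- The DE stand-in's anticonservatism (above).
- UTR sub-classification (5'/3') requires exon+CDS annotations; with
  CDS-only models non-coding SNPs inside a gene span are labelled intronic
  and outside it noncoding.
- GTF input is unsupported; gene models are standardised on GFF3 CDS
  features.
- Ka/Ks here is a within-population polymorphism ratio (pN/pS-style), not a
  divergence-based estimate; no confidence intervals are attached.
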