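# Methods

## Scope and data model

`circsig` analyses paired tumor/normal bulk RNA-seq cohorts at the level of
back-splice junctions. The unit of circRNA abundance is the back-spliced
read; everything downstream consumes a `JunctionCountMatrix` (back-spliced
and forward-spliced junction counts, circRNAs × samples, with per-sample
mapped-read totals) and gene-level FPKM / raw-count matrices. Coordinates
are 0-based half-open throughout (BED convention); GTF input is converted
on read. circBase membership is supplied as an on-disk ID map
(coordinates → `hsa_circ` accession), never queried online. Whether the
RPM denominator is all mapped or uniquely mapped reads is a property of the
metadata (`mapped_reads` travels with each sample), not something the code
guesses.

## Quantification

- **RPM** = back-spliced reads × 10⁶ / mapped reads. Linear in counts.
- **Junction ratio** = back-spliced / forward-spliced reads at the same
  splice sites. When per-site linear counts are available, the
  forward-spliced signal is the mean of the linear reads at the acceptor
  and the donor (symmetric, avoids divide-by-zero at one site). A ratio
  above 0.5 marks the circular form dominant. Degenerate cases are explicit:
  back > 0 with forward = 0 is reported dominant with an infinite,
  flagged ratio; 0/0 is undefined.
- **Support filter**: a circRNA is kept when its maximum back-spliced count
  over samples reaches `min_support_reads` (default 2).
- **Genomic origin**: the host transcript is the same-strand transcript
  whose exon boundaries contain both back-splice sites (ties → longest CDS,
  then transcript ID); labels are assigned from exon-block overlap with the
  transcript's CDS/UTR intervals. *complete CDS* is operationalised as exon
  blocks covering 100% of the transcript's CDS plus at least 1 nt of UTR —
  the configuration compatible with translation of an intact peptide. No
  overlapping transcript → intergenic; overlap without exonic overlap →
  intronic. Exactly one label per circRNA.
- **Isoform diversity**: isoforms of one host gene are ranked by mean RPM
  across samples, ties broken lexically by circRNA ID for determinism; the
  predominant share is the top isoform's fraction of the gene's summed
  circRNA RPM.
- **Flanking introns**: the introns immediately upstream of the acceptor
  and downstream of the donor. A circularised run that includes the first
  or last exon lacks that flank; the side is flagged and contributes zero
  length. Repeat / binding-peak content is counted by interval overlap.

## Tissue specificity

TSI = Σᵢ (1 − xᵢ/x_max) / (n − 1) over n tissues, with xᵢ the per-tissue
median expression across **normal** samples only (tumors never enter the
profile). TSI is 0 for a uniform profile, 1 when exactly one tissue is
expressed, scale- and permutation-invariant. Features first pass an
abundance filter: median RPM ≥ 0.1 (circRNAs) or median FPKM ≥ 10 (genes)
in at least one tissue, comparisons inclusive. Categories: ubiquitous
(TSI ≤ 0.3), tissue-specific (TSI ≥ 0.85), intermediate otherwise; both
boundaries inclusive. Medians of an even sample count use the midpoint;
argmax ties resolve to the first tissue in canonical (sorted) order;
all-zero profiles are flagged and excluded rather than silently dropped.
Whether the RBP panel passes the FPKM ≥ 10 prefilter is configurable
(`rbp_abundance_prefilter`, off by default).

## Differential expression

Implemented in-repo as a vectorised negative-binomial Wald pipeline:

1. **Size factors** by median-of-ratios over features with a positive
   geometric mean.
2. **Dispersion** per feature by method of moments on normalized counts,
   estimated within each condition (removing the condition effect from the
   moments) and averaged, floored at 10⁻⁸.
3. **GLM**: NB log-link model per feature with intercept, condition, and —
   in the default paired design — patient indicator covariates, fitted by
   iteratively reweighted least squares batched over all features
   (batched normal equations, tolerance 10⁻¹⁰, linear predictor clipped to
   ±30, a 10⁻¹⁰ ridge for rank safety). Log size factors enter as offset.
4. **Wald test** on the condition coefficient. The statistic is referred to
   a t distribution with n_samples − n_conditions degrees of freedom — the
   information actually backing the dispersion estimate (pairing covariates
   do not consume dispersion df). A null-calibration study on simulated
   cohorts (10 tumor/normal pairs, ~1,200 features) motivated this choice:
   the normal reference is anti-conservative (≈ 0.059 at nominal 0.05) and
   a residual-df t(9) over-conservative (≈ 0.030), while the dispersion-df
   t sits at ≈ 0.044.
5. **BH adjustment** across tested features; all-zero features are excluded
   from testing and reported non-significant.

Calls require both gates: adjusted p < 0.05 **and** |fold change| ≥ 2,
applied to the unshrunk estimate (no LFC shrinkage). Swapping condition
labels negates every log2 fold change exactly. Before testing, each
cancer's cohort is prevalence-filtered: RPM ≥ 0.1 in at least
⌈10% × n_samples⌉ samples (tumor + normal). Pairing is on by default and
switchable; the paired model absorbs patient-level baseline differences.

The global abundance comparison sums RPM per sample and compares tumor vs.
normal totals per cancer with the two-sided Wilcoxon rank-sum test
(the unpaired rank test is used deliberately, matching the study-style
statistics for this figure-level comparison); cohorts with fewer than three
pairs report an undefined p.

## Attribution

Pearson correlation is the primitive; r ≥ 0.7 counts as strong. Constant
profiles give a flagged undefined r. For **tissue-specificity attribution**
correlations run over per-tissue median profiles (one point per tissue);
a tissue-specific circRNA is host-driven when its host gene is itself
tissue-specific with the same argmax tissue, RBP-associated when its best
correlation against the tissue-specific members of the RBP panel reaches
0.7, `both` when both hold, otherwise unexplained. circRNAs without a host
gene are skipped with a flag. For **dysregulation attribution** a DE
circRNA is host-explained when its host gene is significantly altered in
the same cancer with the same direction (the any-direction tally is also
reported, since published "explained by" fractions are ambiguous on this
point); otherwise it is screened by per-sample correlation within that
cancer's cohort against the significantly altered RBPs. The fold-change
quadrant table (circRNA vs. host linear transcript log2FC signs) is emitted
for all DE circRNAs with a measurable host fold change; concordant +
discordant partition it exactly. The RBP panel is always an input file,
never hard-coded.

## Synthetic cohorts

The generator emulates a seven-tissue paired study: per-patient tumor and
normal libraries with log-normal mapped-read totals (median 2×10⁷,
σ = 0.2); a toy annotation of single-transcript genes (6–10 exons, CDS
leaving real UTRs) from which circRNAs are drawn as contiguous internal
exon runs (2–5 exons, geometric isoform count with P(1 isoform) = 0.2646 so
~73.5% of host genes yield ≥ 2 isoforms); and negative-binomial counts
around tissue/condition means (dispersion 0.1 for junctions, 0.05 for
genes). Baseline circRNA abundance is log-normal (median 0.3 RPM, σ = 1),
so the majority of circRNAs are lowly expressed. Forward-spliced counts
follow a per-circRNA circular:linear ratio, log-normal with median 0.2, so
a small tail of circles outnumbers its linear host.

Planted structure (one class per circRNA): 50× single-tissue elevation with
zero background (tissue-specific); flat well-expressed profiles
(ubiquitous); per-sample means proportional to the realized expression of a
tissue-specific host gene (host-coupled) or of a tissue-specific RBP
(RBP-coupled, host gene non-specific); and explicit per-cancer tumor
effects of 2² = 4-fold on background circRNAs — cancer-specific, shared
consistent and shared inconsistent patterns, with shared patterns planted
first. Tumor circRNA means are additionally downscaled globally (default
×0.7), reproducing the tumor-wide loss of circRNA output. Design choices
worth noting:

- Tumor effects are planted only on background circRNAs with baseline
  ≥ 0.5 RPM, so recovery metrics measure the test rather than the
  counting-noise floor of barely expressed features.
- Coupled circRNAs get a 1 RPM baseline floor: correlation attribution is
  identifiable only above counting noise, and attributed circRNAs in
  practice pass abundance filters anyway.
- Each tissue-specific RBP is planted **down**-regulated in one cancer (the
  splicing-factor-loss motif). An up-regulated tissue-specific RBP would
  drag its entire coupled circRNA cohort upward in one tissue and mask the
  global abundance drop there — a confound of the truth design, not a
  property of the methods under test.

What the generator does **not** emulate: read-level sequencing artifacts,
mapping ambiguity, patient-level covariates (age, stage, batch), correlated
dispersion between circRNA and host, isoform-level linear splicing, or
compositional coupling between gene panels. Passing recovery tests
therefore demonstrates correctness of the statistics under a clean NB
generative model, not robustness to every failure mode of real libraries.

## Problem sizes and determinism

Default simulated cohorts are 7 tissues × 10 patients × 2 conditions
(140 libraries, ~300 genes, ~870 circRNAs); the committed test
configurations use the same shape with fewer genes where only I/O is
exercised. Null calibration uses 8 single-tissue replicate cohorts
(~9,500 tests). All randomness flows from a single mandatory seed through
one `numpy` generator; identical seeds give bit-identical cohorts and
byte-identical fixture files.

## Known limitations

- The NB Wald engine targets qualitative agreement with DESeq2-family
  tools, not parity: no dispersion shrinkage, no outlier refitting, no
  independent filtering. A cross-check against pyDESeq2 on a small planted
  instance (same top hits, signs, and log2FC within ±0.35) is part of the
  test suite.
- Genomic-origin and flanking-intron logic assume the host transcript
  explains the back-splice sites exactly; circRNAs from unannotated
  splice sites fall back to the best-overlap transcript.
- Attribution is correlational plus binding-site overlap; it makes no
  causal claim.
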