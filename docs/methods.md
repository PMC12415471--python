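# Methods

`cernakit` implements the computational core of a two-group (two-breed)
whole-transcriptome skin study: differential expression of four RNA classes,
high-confidence miRNA-target links, competing-endogenous-RNA (ceRNA)
pair/triplet inference, back-splice circRNA junction calling, and the small
closed-form bench-assay computations. Every stage can be exercised against a
synthetic study with known planted truth. This note records the models, the
parameters that matter, the numerical choices, and the limits of what the
synthetic tests demonstrate.

## The synthetic study

The generator (`cernakit.simulate`) emulates a 2-group x 3-library design
(each library standing for a pool of two animals, as in pooled-library bulk
designs). All randomness flows from `SimConfig.seed` through independent
per-generator streams, so every artifact is a pure, byte-reproducible
function of the config.

**Counts.** Each feature draws counts from a negative binomial with
variance mu + alpha*mu^2; per-feature means are log-uniform over
`10**nb_mean_log_range` (default 10-1000). The default dispersion
alpha = 0.02 reflects the damped biological variability of pooled
libraries. A `de_fraction` of features per class (default 10%) has its
group-B mean multiplied by `2**(+/-de_log2fc)` (default |log2FC| = 2).

**Planted ceRNA structure.** `n_triplets` (default 10) sponge-mRNA pairs
are planted, alternating lncRNA and circRNA sponges, each sharing
`mirnas_per_triplet` (default 5) dedicated miRNAs; the recorded truth
expands each pair into one (sponge, miRNA, mRNA) triplet per shared miRNA.
Member means are tied to one standard-normal latent value per sample (one
independent latent vector per pair): sponge and mRNA means scale by
`exp(+a z_s)`, miRNA means by `exp(-a z_s)`. Two deliberate choices:

- *Group-centered latent factors.* The latent vector is centered within
  each group, so the co-expression structure lives entirely inside the
  groups and is orthogonal to the group contrast: the planted fold change
  of every member is exactly `de_log2fc`, and the DE stage is not asked to
  detect a shift through extra latent noise.
- *Amplitude calibration.* With amplitude a and dispersion alpha the
  latent-only log-scale Pearson between sponge and mRNA is approximately
  a^2(2/3) / (a^2(2/3) + alpha + 1/mu). The default a = 0.5 at
  alpha = 0.02 and planted base mean 300 gives ~0.88, and the coherent
  group shifts (sponge/mRNA up in B, miRNA down) push the realized
  six-sample correlations well past the screening thresholds
  (PCC > 0.8, SCC < -0.7). Planted members are always seated in the DE
  set when `de_fraction > 0` because the ceRNA screen only considers
  differentially expressed candidates.

**Predictor tables.** Both tables contain every planted miRNA-target link;
a `decoy_target_fraction` (default 0.5) of each table's rows are decoys
unique to that table and disjoint between tables, so intersection removes
them exactly.

**Toy genome and junction reads.** Two 100-kb chromosomes carry genes of
3-6 exons (150-400 bp, introns 100-300 bp). Each planted circle spans
exon boundaries of one host gene; the genome is edited so the circle
flanks read GT..AG on the gene strand (AC..CT genomically for minus-strand
genes). Junction reads are emitted pre-aligned: read = circle tail +
circle head, with the anchor alternating between the circle head
(`xS yM` at the circle start) and tail (`xM yS` ending at the circle
end); the clip/match split keeps both parts >= 15 bases. Mates map fully
inside the circle. Background reads are single-end full-match records.
No sequencing errors or quality modeling: alignment itself is out of
scope, and the caller's contract is exact-match re-alignment.

**What the synthetic data does not emulate.** Real libraries have
GC/length biases, overdispersion heterogeneity, mapping ambiguity,
incomplete and erroneous annotations, predictor tables with correlated
false positives, and junction reads with mismatches near the clip point.
Passing tests therefore demonstrate the correctness of the algorithms
under their stated assumptions, not field performance on real data.

## Differential expression

Counts are normalized with median-of-ratios size factors (features with
any zero excluded from the geometric means; factors rescaled to geometric
mean 1). The test is a two-group NB Wald test:

- log2FC = log2((meanB + c) / (meanA + c)) with pseudocount c = 0.5
  normalized counts, so all-zero groups never produce infinities or NaN.
- Per-feature dispersion is estimated by method of moments from the pooled
  within-group variance, alpha = (s^2 - mu)/mu^2, floored at 1e-8.
- With only three libraries per group a per-feature dispersion makes the
  Wald z heavy-tailed (approximately t with ~4 df), so the default
  `dispersion_mode="trend"` stabilizes it through a mean-dispersion trend
  alpha(mu) = a0 + a1/mu fitted by least squares across features, with one
  MAD-based trimming pass so a minority of genuinely high-dispersion
  features does not drag the trend for the bulk. `dispersion_mode="gene"`
  keeps the raw per-feature estimate.
- SE(log2FC) comes from the NB variance of the group means via the delta
  method; the two-sided p uses the standard normal.
- BH step-up adjustment; `significant` means padj < alpha (default 0.05).
  A raw-p mode exists because "significance threshold p < 0.05" is
  ambiguous in such workflows; adjusted p is the default since BH is
  meaningless otherwise.

Under the null generator (2,000 features, 3 vs 3) the raw false-positive
rate at p < 0.05 sits near 0.05-0.06 and the KS distance from uniform
below 0.05; planted |log2FC| = 2 at base mean >= 100 is recovered
essentially completely with no sign errors (see `scripts/acceptance.py`).
This is a deliberately simplified pipeline: no dispersion shrinkage
toward a prior, no GLM covariates, no independent filtering, no outlier
handling — the contract is calibration and recovery, not bit-compatibility
with full-featured DE packages.

FPKM is count / (length_kb x mapped_millions), with gene-level values as
the sum over the gene's transcripts. Small-RNA reads are retained at
lengths in [18, 30] nt inclusive. lncRNA candidates require length
strictly > 200 bp and exon count >= `min_exons`; the exon cutoff has no
canonical value, so it defaults to 2 and is configurable.

## miRNA-target links

High-confidence interactions are the exact set intersection of two
predictor tables (tool and score dropped). Co-expression uses Spearman
rank correlation (midranks for ties) computed on log2(x+1)-transformed
normalized expression — size-factor-scaled counts for miRNAs, FPKM for
targets; the choice of scale only matters through ties since SCC is
rank-based. Pairs are retained when SCC is strictly below -0.7, by
default only among DE miRNAs and DE mRNAs (the filter is coupled to the
differential analysis; `restrict_to_de=False` lifts it). With six
samples the SCC takes coarse values; the strict inequality at the
threshold is intentional and tested.

## ceRNA screening

For a candidate (sponge, mRNA) pair with miRNA sets T_sponge and T_mrna
inside a universe U, the screen computes k = |T_sponge ∩ T_mrna| and the
one-sided hypergeometric tail p = P(X >= k) with population |U|,
successes |T_sponge|, draws |T_mrna|. The universe defaults to all miRNAs
of the post-intersection interaction set — the least arbitrary choice; DE
miRNAs or all expressed miRNAs are reasonable alternatives and can be
passed explicitly. A pair is retained when k > 3 (literally "more than
3", i.e. k >= 4, `min_shared` to override), p < 0.05, BH FDR < 0.05
(adjusted separately within lncRNA-sponge and circRNA-sponge candidates,
matching the two separate networks), and Pearson correlation of the
sponge and mRNA on log-normalized expression strictly above 0.8. The PCC
is applied to the sponge-mRNA pair (the ceRNA hypothesis predicts their
positive coupling); which pair the threshold should govern is not
canonical, so it is configurable. Triplets are one per (pair, shared
miRNA) whose miRNA-mRNA link survived the SCC filter; a miRNA-sponge
anticorrelation filter exists but defaults off. Networks export as SIF,
GraphML and edge-list TSV with typed, de-duplicated nodes.

## Back-splice junction calling

CIGARs are classified into clip signatures: clip+match (`xS/H yM`,
left_clip), match+clip (`xM yS/H`, right_clip), clip+match+clip
(double_clip, the single-exon / long-short-long circle case); anything
else — pure matches, internal indels — is ignored. For each clipped
record with a clip of >= 10 bases (shorter clips are uninformative for
exact re-matching) the clipped query segment is exactly string-matched
against the reference within a +/-100 kb window of the anchor. Only the
chiastic configuration yields a candidate: a right-clip's clipped suffix
must match strictly upstream of the anchor (junction start = clip match
start, end = anchor end), a left-clip's clipped prefix strictly
downstream (start = anchor start, end = clip match end). Colinear
matches are ordinary splices and produce nothing. A clip matching at
several chiastic positions is discarded and tallied (never guess between
targets). Double clips are resolved by checking both terminal clips
against the opposite ends of the anchor block directly.

Paired-end candidates must have the mate's leftmost position inside
[start, end] on the same chromosome (single-end records bypass the
filter). Splice signals are read strand-aware at the flanks (donor
immediately 3' of the junction end, acceptor immediately 5' of the
start, reverse-complemented for minus); GT-AG is canonical, AT-AC weak
(kept but flagged; `require_gt_ag` restricts). With annotation, the
junction start must sit on an annotated exon start and the end on an
exon end, within a tolerance that defaults to 0 (the appropriate "known
range" is not canonical; +/-2 is a documented option), and the source
gene is the smallest containing gene interval. Calls group candidates by
(chrom, start, end, strand) and count distinct query names, so a pair
clipping at both mates supports a junction once; `min_reads` defaults to
2 junction reads, the conventional support floor. Coordinates are 0-based
half-open internally and 1-based inclusive in all reports (BED output is
0-based half-open by format definition). Output is invariant to input
record order.

## Assays

- 2^-ddCT: dCT = CT_target - CT_reference per sample (reference CTs
  averaged if replicated), ddCT subtracts the calibrator group's mean dCT
  (group A by default — the calibrator is a named, configurable choice),
  relative expression = 2^-ddCT. Invariant to any constant CT shift.
- Melanin working curve: OLS absorbance = slope*conc + intercept over the
  standard grid (>= 3 distinct concentrations required), r^2 reported.
  Inversion floors negative concentrations at zero with a warning
  (blank-level noise near zero is expected); content is conc x volume /
  fiber mass, reported as mg per g fiber (the natural unit for a 1 mL
  NaOH extract of a 15-30 mg sample; "relative melanin content" has no
  canonical unit).
- Follicle density: marked count / imaged area, default area 9.26 mm^2
  (one high-quality section image).
- Two-group comparison: Student's pooled-variance t (the workflow checks
  variance homogeneity first; `welch=True` available), two-sided p,
  means +/- SD, stars at * p<0.05 / ** p<0.01. Two identical constant
  groups return t = 0, p = 1 by contract.

## Problem sizes and determinism

Default study sizes (500 mRNA / 120 lncRNA / 90 circRNA / 150 miRNA
features, 20 circles, 2,000 background reads; 2,000 features for the
dedicated calibration/recovery runs; 50 circles with 5,000 background
reads for the detector study) keep the full pipeline around two seconds
while leaving ~200 decoy sponges and hundreds of decoy interactions in
play. All stages are deterministic given the config; the pipeline's
output tree is byte-identical across runs with the same seed.

## Known limitations

- The DE stage's normal Wald p is approximate at very low counts; the
  trend-based dispersion assumes most features share a smooth
  mean-dispersion relationship.
- The clipped-segment re-match is exact-match only; reads with errors in
  the clipped part would be missed (the caller targets the mismatch-free
  contract; fuzzy re-matching is future work).
- Hard-clipped junction reads cannot be re-matched (the clipped sequence
  is absent from SEQ) and are counted in diagnostics instead.
- The screen enumerates all DE-sponge x DE-mRNA combinations; for studies
  with tens of thousands of DE features per class a sparser candidate
  generation would be needed.
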