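# Methods

`oncomap` implements the cohort-level analyses used in comparative
mammary-tumor genomics as a reusable, tested pipeline. Every stage can be
exercised end to end on a synthetic cohort with planted ground truth; this
note records the models, the parameters that matter, the numerical choices,
and what the synthetic data do and do not establish about real cohorts.

## Somatic variant post-filtering (`variants`)

Variant calling and annotation are out of scope: the package consumes
called, annotated variant tables (minimal VCF v4.2 or TSV). Post-calling
operations:

- **Alignment-error rule.** For each candidate SNV site, alt-supporting
  reads pooled over *all* samples contribute their optimal (AS) and
  suboptimal (XS) alignment scores; the site is rejected iff
  meanXS ≥ 0.8 × meanAS (the ratio is a parameter; the inequality is
  non-strict at the boundary). Filtering is per site, never per sample.
  A read with no suboptimal hit contributes XS = 0 — the natural reading of
  "no competing placement", made explicit here because upstream aligners
  simply omit the tag.
- **Consequence mapping.** Sequence Ontology terms map deterministically to
  six functional classes (missense, nonsense, frameshift, in-frame indel,
  splice, silent); the table ships as package data
  (`data/consequence_map.tsv`) so annotation dialects can be swapped.
  Indels override ambiguous annotations: net length change divisible by 3 ⇒
  in-frame, otherwise frameshift. Unknown terms become class `other`,
  non-silent = false, with a logged warning.
- **Recurrence.** A gene is recurrently mutated when non-silently mutated
  in strictly more than `min_fraction` (default 0.05) of samples; ordering
  is by descending frequency, ties alphabetical.
- **Germline candidate cascade.** Keep a record iff depth ≥ 10 in both
  tumor and normal (or normal-only records with depth ≥ 10), pathogenicity
  ∈ {truncating, pathogenic, likely_pathogenic}, population MAF missing
  (novel) or < 0.05, and within-cohort MAF < 0.05. The filter is
  idempotent by construction.

## Burden and selection (`burden`)

TMB is the per-sample count of exonic mutations (silent included), reported
per Mb of callable target. The callable size is a parameter
(`target_mb`, default 38 Mb — a round exome-scale figure, not a measured
capture size; set it to your panel). Hypermutation is strictly
`tmb_per_mb > 10`.

Purity correction multiplies the count by 1/purity: detection of clonal
mutations is diluted proportionally to the neoplastic-cell fraction. The
factor is pluggable for users who prefer a different dilution model.

The selection statistic is a deliberately simple **surrogate** for
covariate-based dN/dS models (it is not dNdScv): with per-gene
nonsynonymous/synonymous opportunity (E_N, E_S) weighted by the cohort's
channel rates,

    dN/dS = ((n_obs + 0.5) / (s_obs + 0.5)) / (E_N / E_S),

p from a two-sided binomial test of n_obs among n_obs + s_obs against
E_N/(E_N+E_S), BH-adjusted within scope (gene or sample). The 0.5
pseudocount keeps ratios finite at zero counts. No covariates, no
negative-binomial overdispersion — rankings on real data will be noisier
than dNdScv's.

## Mutational signatures (`mutsig`)

Spectra use the standard 96 channels: six pyrimidine-strand substitution
classes (C>A, C>G, C>T, T>A, T>C, T>G) × 16 flanking contexts, contexts
alphabetical within class. Purine-reference SNVs are reverse-complemented;
catalogs are therefore interchangeable by channel *name*, never position.

- **De novo deconvolution**: multiplicative-update NMF minimizing
  generalized Kullback–Leibler divergence (the classical signature-analysis
  objective), best of `restarts` random initializations; the per-iteration
  objective trace is exposed so monotonicity is testable.
- **Exposure fitting**: non-negative least squares (Euclidean), which is
  convex and deterministic; the asymmetry with the KL de novo objective is
  intentional and documented.
- **Catalog matching**: cosine similarity on the raw (non-negative)
  profiles, ties broken by catalog order.

The bundled synthetic catalog's first signature concentrates mass on C>T
channels, mimicking the dominance of spontaneous CpG-deamination mutations
in aging tissue; the others are random sparse profiles, so mixtures stay
identifiable.

## Copy number (`scna`)

Input is binned tumor/normal read depth. The ratio t/n is normalized by
its genome-wide median, then divided by the median ratio of the bin's GC
decile (decile-median correction rather than loess: fewer knobs, directly
testable; decile count configurable), and log2 is taken last. Zero-depth
bins are masked, never imputed.

**CBS.** Per chromosome, the statistic is the maximal |z| of a mean-shift
over circular arcs; because an arc and its complement give the same |z|,
scanning contiguous windows suffices. A split is accepted iff its
within-chromosome permutation p ≤ alpha (default 0.01, `nperm` 1000, with
early stopping once significance is impossible), recursing on the pieces;
`min_width` (3 bins) bounds segment size, and segments never cross
chromosome boundaries. The "undo splits" refinement of the reference CBS
implementation is omitted — a documented deviation; profiles with gradual
waves may over-segment slightly.

**Recurrence.** Per bin, G_amp = Σ_samples max(seg_mean − 0.2, 0)
(mirrored for deletions at −0.2). The null preserves each sample's segment
structure by cyclic shift of its whole-genome profile; per-bin p-values
come from the pooled null, BH-adjusted, and peaks are maximal runs with
q ≤ 0.25. This is a simplified G score, not GISTIC2: no semi-exact
background, no arm/focal decomposition, no peel-off. The ±0.2 amplitude
thresholds are conventional log2 cutoffs, configurable.

## Cross-species projection (`crossmap`)

UCSC chain semantics throughout: 0-based half-open, tStrand '+',
negative-strand query coordinates on the reversed sequence (forward
position = qSize − 1 − chain offset). The parser enforces the block-sum
arithmetic (Σsize + Σdt = tEnd − tStart, likewise for q) and reports the
offending chain and line.

Interval projection maps base-for-base through aligned blocks only; gap
bases are reported as unmapped, and output intervals merge only when
contiguous in *both* genomes (so a source interval spanning an alignment
gap yields separate target intervals even when they abut). Where several
chains cover a source base, the highest-score chain wins (configurable in
effect by pre-filtering the chain list).

Segment-level log2 ratios project coverage-weighted onto a fixed bin grid
of the destination genome (default 1 Mb); uncovered bins carry NaN, not 0.
Re-segmentation applies a centered moving-median (window 5) then CBS.
Note: median smoothing correlates neighboring bins, which the permutation
null does not model — flat regions may fragment; the planted-boundary
recovery is unaffected, and window 1 disables smoothing. Projection is
per sample first, aggregation after. Cohort concordance is the Pearson r
between per-bin cohort sums of positive parts (amplifications) and of
negative parts (deletions), over bins covered in both cohorts.

## Expression subtyping (`subtypes`)

Input is log2(FPKM+1); the 2,000 most-variable genes are factorized
(gene filtering is this package's choice — sensible for bulk expression,
configurable). Euclidean multiplicative-update NMF, `restarts` = 30 per
rank; per restart each sample is assigned to its dominant metagene, the
consensus matrix records co-assignment frequency, and the cophenetic
correlation of average-linkage clustering of 1 − consensus measures
stability. The selected rank is the largest candidate with cophenetic ≥
0.95. Caveat observed on strong block-structured data: consensus can stay
near 1 *above* the true rank (extra metagenes carve the same sub-structure
every restart), so the rule can overshoot when given a wide range; inspect
the per-rank cophenetic curve, or narrow `k_range`, on such data.

Tumor-specific metagenes are those with higher mean activity in tumor than
in normal samples (manual override supported). A sample is assigned to its
dominant metagene only if tumor-specific; domination by a normal-tissue
metagene, or an exact tie, leaves it UNASSIGNED — this is how a cohort of
n tumors can yield fewer than n subtype calls.

Preranked GSEA is the weighted KS running sum (weight p = 1) with a
gene-label permutation null and sign-matched tail p. Signature scores
z-score genes across samples, then either correlate the sample's z-profile
with a ±1 up/down template (correlation mode, bounded in [−1, 1]) or take
mean z(up) − mean z(down) (mean-difference mode; with no down genes this is
a plain module score, covering EMT-style and metagene-average scores).
Median splits send ties to the low group. Survival comparisons are
multi-group log-rank tests (df = groups − 1) with Kaplan–Meier coordinates
emitted for plotting.

## Cohort statistics (`stats`)

Fisher's exact test uses the minimum-likelihood two-sided rule; the U test
is exact for untied samples of ≤ 20 each, otherwise normal-approximated
with tie and continuity corrections; ANOVA is the classical F test with a
p = 1 convention for all-constant equal-mean groups; BH is the standard
step-up. These delegate to scipy/lifelines/statsmodels; the test suite
carries independent enumeration oracles (every 2×2 table with N ≤ 40;
every labeling at n = m = 3..7). Pathway enrichment builds the
(in/out pathway) × (hit/not-hit) table over an explicit gene universe —
the universe is always a caller-supplied input, never assumed.

## Synthetic cohort (`synthetic`)

The generator emulates the study conditions end to end: a benign/malignant
cohort (default benign fraction ≈ 0.25, echoing 43 benign of 183 WES
cases) with histology-dependent driver Bernoulli frequencies; background
mutation counts Poisson at `tmb_rate`; trinucleotide channels drawn from a
signature mixture and placed at reference positions whose ±1 context
matches (contexts located by scanning an i.i.d.-uniform ACGT toy genome);
VAF = clonal fraction × purity / 2 with binomial sampling at depth 100,
clonal fractions Uniform(0.2, 1) in benign vs Uniform(0.5, 1) in malignant
so malignant allele fractions are stochastically larger (the planted analog
of the benign→malignant MAF shift); binned depths Poisson around a
GC-monotone mean with planted, purity-diluted copy segments; toy two-genome
chains with an exact per-base map as projection oracle; and a
block-structured expression matrix with planted metagene clusters whose
exponential survival hazards differ under independent exponential
censoring (default censor rate 0.02 per time unit).

Reproducibility: every generator derives one RNG sub-stream per sample
from (seed, stream-tag, index), so enlarging a cohort never reshuffles
earlier samples, and identical spec + seed gives byte-identical tables.

What the synthetic data do **not** emulate: read-level errors and mapping
artifacts (so the AS/XS filter is exercised on constructed score tables,
not emergent errors), linkage between mutations, subclonal tree structure,
germline haplotypes, covariate-driven regional mutation-rate variation
(so the dN/dS surrogate's calibration holds by construction), expression
compositionality and batch effects, and real chain-file complexity
(chains here are small and conflict-free except where tests plant
conflicts). Passing tests therefore establish correctness of the
algorithms under their stated models, not robustness to real-data
violations of those models.

## Problem sizes and tolerances

Default test problem sizes are chosen for sharp discrimination at desk
scale: 1,000-bin profiles at SNR 10 for breakpoint recovery (±2 bins),
10,000-mutation spectra for exposure recovery (±0.03), 100–200 simulation
seeds for power (≥ 80% at hazards 0.1/0.1/0.5, n = 150) and null
calibration (KS α = 0.01). Discrete-statistic calibrations (exact binomial
p-values) are checked against simulated nulls rather than continuous
U(0,1). Numerical guards: 1e-12 floors inside NMF updates, catalog rows
row-stochastic within 1e-6, segment means reconstruct bin means within
1e-9.
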