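# Methods

## The differential model

The case–control test is a pooled-read Fisher exact test. Within a
(lineage, time point) stratum, reads are summed over all case donors and
all control donors; for each feature the 2×2 table contrasts reads in the
feature ("observed") against reads in all other features ("expected").
The two-sided p-value follows the point-probability rule — the sum of the
probabilities of all tables with the observed margins whose
hypergeometric probability does not exceed the observed table's, with a
relative tie tolerance of 1e-7 (the convention of R's `fisher.test`).
The implementation is vectorized over features via log-space
hypergeometric mass evaluated on each table's support; tests verify it
against `scipy.stats.fisher_exact` and an exact integer-arithmetic
enumeration for margins ≤ 200.

The effect is the case/control proportion ratio (a/(a+b))/(c/(c+d)); the
direction flag (`up_in_cases` iff effect > 1), not the ratio's
orientation, is the contract consumed downstream. Features with zero
reads in both groups in a stratum are excluded from testing and from the
BH denominator. BH FDR (statsmodels) is applied within each
(modality, time point) across lineages and features; pooling across time
points is available via `bh_scope="all"`.

**Assumptions and caveats.** Pooling reads across donors treats cells as
exchangeable within a stratum and ignores donor-level variation
(pseudoreplication). The test is approximately calibrated when per-cell
counts are multinomial given the stratum mean (the generator's
overdispersion→0 regime); any donor-level variance component —
overdispersed cells, planted link latents, dosage effects — makes it
anti-conservative. This is a faithful property of the pooled design, not
a defect of the implementation; the null-calibration tests quantify it,
and a robustness test documents the inflation under per-cell
overdispersion. Mixed-model alternatives are deliberately out of scope.

## Normalization and linking

Pseudobulk signals are normalized to reads-per-million within each
(donor, time point, lineage) key. Candidate peak–gene pairs are all
same-chromosome pairs with |peak midpoint − TSS| ≤ 1 Mb (closed bound,
strand-agnostic). Discovery correlates the peak's snATAC RPM with the
gene's snRNA RPM — both from the same multiome nuclei — across all
(donor, time point, lineage) observations (Pearson, two-sided t
approximation); nominal links require P < 0.05 and |r| > 0.05.
Validation recomputes the Pearson correlation between the *unpaired*
layers (snATAC vs scRNA) and accepts a link only with the same sign as
discovery and |r| > 0.65 (strictly greater). Pairs with a zero-variance
vector are skipped and logged; ≥ 5 paired observations are required.

The correlation unit is the pseudobulk observation rather than single
nuclei: per-nucleus signals are too sparse for stable per-pair
correlation, and the sample-level validation contrast requires
sample-level signals anyway. A known consequence of pooling observations
of unequal size (lineages hold different cell numbers) is that the noise
scale of an observation is shared between the two modalities — small
lineages are noisy in both — which fattens the null tails of r: on null
cohorts with the default unequal lineage proportions, ~6% of independent
pairs pass P < 0.05 instead of the nominal 5%. With equal per-lineage
cell allocations the rate is 5.0% (a property test covers the
exchangeable case). We keep the unequal proportions because they are the
realistic condition, and document the mild anti-conservatism rather than
reweighting the estimator.

Link density (links per kb per distance bin) divides the link count by
bin width in kb × number of genes with ≥ 1 candidate peak in the bin; it
is descriptive only, since the normalization of such densities is not
standardized.

## Replication

A discovery (feature, lineage, time point, modality, q < 0.10) is
checked in orthogonal layers: the other RNA modality at the same
stratum, the same modality at the other two time points, and —
crossing modalities — linked peaks (for a gene) or the linked gene in
either RNA layer (for a peak). A layer replicates when its test reaches
q < 0.10 with the same direction; for linked features, direction
concordance means the accessibility and expression changes share sign.
Same-modality/different-timepoint and different-modality/same-timepoint
layers are weighted equally. A discovery is "replicated" when present in
≥ `min_layers` layers including itself (default 2). A missing layer
table marks a layer untested, never failed.

## QTL scan

Dosage is the alt-allele count 0/1/2 (genotypes 0/0, 0/1, 1/1; `./.`
missing). For each index SNV, features within 1 Mb are tested per
(lineage, time point): Spearman rank correlation (midrank ties) between
donor-level RPM and dosage, two-sided p from the t approximation —
adequate at the cohort's donor counts, exact permutation p-values are
not computed. The Bonferroni multiplier is the number of tests performed
within each (lineage, modality), spanning SNVs, features and time
points. Monomorphic SNVs are skipped and logged. Per-timepoint testing
is the default (signals are normalized "per individual and time point");
a pooled run can be emulated by averaging RPM over time points upstream.

## Adjacency excess

"Adjacent" means consecutive ranks in the full sorted peak set on the
same chromosome; no base-pair gap rule is applied by default (a
`max_gap` option exists). With k significant among N peaks on a
chromosome, the chance expectation of adjacent significant pairs is
(N−1)·P(both ends significant) = k(k−1)/N by linearity of expectation;
the permutation estimate shuffles labels within chromosomes and matches
the closed form (tested). Strata (lineage × time point) are counted
separately and summed.

## Motif representation

Motif occurrence is binary per peak (≥ 1 hit; a hit-count mode exists
behind a flag). Per motif, occurrence among case-up peaks versus
case-down peaks forms a 2×2 table tested with the same Fisher
implementation as the differential module; the fold change is the
occurrence-rate ratio, flagged at nominal P < 0.01. Peaks significant in
both directions across strata are removed from the down set before
testing.

## Endotype analysis

Endotypes derive from the first autoantibody-positive sample: {IAA} →
IAA-first strict; multiple antibodies including IAA but not GADA →
IAA-first loose; GADA symmetric; sets containing both IAA and GADA, or
neither, → other. The labels are mutually exclusive internally; group
*selection* uses the cumulative convention (a loose group includes its
strict members), matching how cohort tables count. Subgroup differential
runs use the subgroup's cases and their matched pair controls with the
identical pooled-Fisher machinery, and subgroup-specific replication
(not the all-case runs). Overlap with the overall signal is
|overall ∩ subgroup, same direction| / |overall| per
(lineage, time point, direction).

## The synthetic cohort generator

The generator emulates the study design: n matched case–control pairs,
three time points, three layers, five lineages with fixed per-sample
cell allocations (defaults 0.25/0.15/0.30/0.18/0.12 for
Monocyte/B/CD4T/CD8T/NK — realistic PBMC fractions), Poisson library
sizes (800 reads/cell RNA, 1500 ATAC), and multinomial read allocation
over features, optionally gamma-perturbed per cell (`overdispersion`;
at 0 the model is exactly multinomial). snRNA and snATAC share nuclei;
scRNA is an independent draw from the same donor-level means. Endotype
labels are assigned to cases by largest-remainder allocation of
fractions mirroring a 49-case series (21 IAA-strict, 17 IAA-loose,
8 GADA-strict, 3 GADA-loose).

Planted structure:

* **Differential effects**: multiplicative fold on case donors' rates in
  one (lineage, time point), optionally restricted to an endotype
  family. Planted features receive fixed baseline weights w = 1/|fold−1|
  so each effect moves exactly one unit of rate mass; with equal numbers
  of up and down effects the case rate vector renormalizes without
  displacing non-planted features — otherwise, at pseudobulk read
  depths, the compositional displacement of abundant null features
  becomes statistically visible and contaminates null sets in the whole
  cohort and subgroups alike.
* **Links**: a shared standard-normal latent per (donor, time point,
  lineage) scales both the peak and gene rate by exp(c·z − c²/2)
  (mean-one), inducing positive cross-modality correlation in all
  layers; the default c = 1 makes the latent dominate sampling noise.
* **QTLs**: rate × fold^dosage with dosages Binomial(2, 0.3) per donor.
* **Motif hits**: background occurrence 0.10 per peak×motif; the planted
  motif occurs at 0.60 in case-up differential peaks.

Baseline abundances are log-normal (σ = 1.2), shared across lineages and
time points: lineage identity enters only through cell proportions, so
non-planted features are exchangeable between strata — the property the
null-calibration tests rely on. What the generator does **not** emulate:
lineage-specific marker expression, batch or age structure, library-size
gradients between donors, HLA/LD genetic structure, or the real cohort's
absolute cell counts. Passing tests therefore demonstrate the
correctness and calibration of the machinery under the stated model, not
robustness to those real-data features.

## Problem sizes and numerics

Default desk-scale conditions: 10 pairs, 200 genes, 300 peaks, 100 cells
per donor/time point/layer (recovery and endotype conditions use 20
pairs); the full pipeline runs in well under a minute and replicate
studies (20 cohorts) in a few minutes. Normalization tolerance is
relative 1e-9 on the per-million sum; Fisher tie tolerance 1e-7 in log
space; p-values are clipped into (0, 1]. Effect ratios with zero control
reads are ±inf/NaN and carry no direction guarantee; downstream sets key
on the direction flag only. Zero-total pseudobulk keys are excluded and
logged; empty strata are skipped with a warning.
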