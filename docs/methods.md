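# Methods

## Scope and data model

`pollentx` analyzes bulk RNA-seq count data and seed-marker transmission
counts from the maize male gametophyte. All genomic coordinates are
1-based inclusive (the GFF3 convention); distances between intervals are
the number of bases strictly between them, with overlap or abutment
counting as distance 0. Feature-level containers are plain dataclasses
around numpy arrays and pandas frames; file interfaces are GFF3 (via
gffutils), BED6, and headered TSV throughout.

## TE quantification and classification

**Fractional counting.** A read with k equally best-scoring alignments
contributes weight 1/k at each locus. Each locus's weight goes to the
overlapping feature with the largest base overlap; exact ties split the
weight equally (the upstream aligner convention leaves ties unspecified,
so an explicit symmetric rule was chosen). Loci overlapping no feature
contribute nothing, so total assigned weight never exceeds the number of
reads, with equality when every locus lands in a feature.

**Proximity partition.** TEs with a gap of less than 2,000 bp to any
gene body are `near_genes` and excluded from element-level analysis:
their signal cannot be separated from genic read-through. A gap of
exactly 2,000 bp is distal, because the distal analysis set is defined
as "more than 2 kb away". Proximity is measured edge to edge (gene body
to TE body, no promoter extension) and strand-agnostic; both the
threshold and the measurement are configurable.

**Normalization and differential expression.** Counts are rounded to
integers, normalized with median-of-ratios size factors (rescaled to
geometric mean 1), and each target tissue is compared to the seedling
reference. The test is a deliberately minimal negative-binomial Wald
test — *not* a reimplementation of DESeq2 or Cuffdiff, which remain the
field-standard tools for real data:

* per-feature dispersion α by method of moments,
  α = (s² − μ̄)/μ̄², pooled over the two groups;
* moderation toward a mean-expression trend: features are split into
  ~20 expression bins, the trend is the within-bin median α, and the
  working dispersion is max(individual, trend), floored at 1e-8 — the
  maximum keeps genuinely high-variance features conservative while
  rescuing the many features whose 4-replicate moment estimate
  collapses to zero;
* Wald statistic z = ln(μ̂_t/μ̂_r) / SE with the delta-method standard
  error SE² = (μ_t + αμ_t²)/(n_t μ_t²) + (μ_r + αμ_r²)/(n_r μ_r²),
  referred to a standard normal;
* BH adjustment over tested features. Features whose mean normalized
  count falls below 1 receive a missing p (the independent-filtering
  route into the `not_covered` category). The reported log2 fold change
  adds a 0.5 pseudocount to each group mean so all-zero groups stay
  finite; the test itself uses the raw means.

Under the simulated null (shared NB, 4 vs 4 replicates) this test's raw
p < 0.05 fraction sits at 0.043–0.05, and it recovers ≥ 95% of planted
4-fold activations at mean 50 — both checked in the suite.

**Categories.** Every annotated TE receives exactly one label, with
precedence: `near_genes` (proximity), then `not_covered` (total raw
counts below 10 across samples, or adjusted p missing in every tissue
comparison), then `dynamic` (adjusted p < 0.05 in at least one tissue
versus seedling), else `static`. Family enrichment is the per-family
log2 of observed over expected proportion against a background set,
reported as missing when either count is zero. Cross-stage analyses use
persistence fractions (|up(A) ∩ expressed(B)| / |up(A)|) and a
hypergeometric upper-tail test for two-dataset overlaps.

One aberrant replicate per tissue can be masked from TE analyses via
`drop_samples` (mirroring the removal of a contaminated sperm-cell
replicate in the motivating study) without touching gene-level analyses.

## Gene expression classes

FPKM = fragments / (kb of transcript × millions of mapped fragments).
Class assignment works on per-tissue replicate-mean FPKM: the top 20%
of expressed features (nonzero mean; configurable to all features)
defines "highly expressed" per tissue. Vegetative-cell genes are top-20%
in mature pollen with FPKM(MP) > FPKM(SC); sperm-cell genes the
converse; seedling genes are top-20% in seedling and top-20% in neither
MP nor SC. An exact MP = SC tie leaves the gene unclassified with a
warning. Rank ties at quantile boundaries break by feature id, making
every assignment deterministic and scale-invariant. A `very_high` flag
marks log2(FPKM) > 8 within a class (about the top 5%).

## Binned coexpression statistic

For one tissue the top-N expressed features (default 20,000, isoform or
gene level as supplied) are ranked descending — ties again broken by
id — and cut into bins (default 200). Per bin, two series accumulate
from the DE calls of TEs within 2 kb: the summed number of up- (down-)
regulated neighbors, where a TE near k binned genes counts k times, and
the number of member genes with ≥ 1 such neighbor, which each gene
increments at most once and which controls for a few TE-dense genes.
Kendall τ-b (tie-corrected, asymptotic p) is computed between the
per-bin **median expression** and each count series: the per-bin median
is monotone in bin index, so τ is identical to the bin-index version
while staying robust to bin-width edits, and τ-b handles the heavy ties
in small count series. A cross-tissue control restricts the ranked
universe to features expressed strictly higher in the focal tissue than
in a potential contaminant tissue before binning.

## Quasi-binomial transmission framework

Each ear contributes one (marked, total) seed count. The intercept-only
binomial logit MLE is the pooled proportion — the IRLS fixed point has
this closed form, which is what is implemented — so an allele's
transmission rate is Σ marked / Σ total over its QC-passing ears.
Overdispersion is the Pearson statistic over its residual degrees of
freedom:

φ̂ = Σᵢ (yᵢ − nᵢμ̂)² / (nᵢμ̂(1−μ̂)) / df.

By default φ̂ pools across the alleles of one expression class
(df = ears − alleles in the class), matching the reported class-level
dispersion of ≈ 1.8; per-allele and global pooling are options. The
quasi-likelihood test refers F = (D_null − D_fit)/φ̂ to F(1, df(φ̂));
when φ is supplied without a df (e.g. a single large ear with φ = 1)
the reference degenerates to χ²(1), recovering the binomial
likelihood-ratio test. Boundary fits (rate 0 or 1) clip the fitted rate
at 1e-8 and are flagged. BH correction runs within expression class ×
cross direction, consistent with the per-class adjusted-p patterns in
the motivating tables; a global family is available.

**QC.** An ear is excluded as a putative second unlinked insertion when
its marked fraction exceeds 0.70 *and* a one-sided exact binomial test
rejects 0.5 upward at 0.01 — the "~75% transmission" rule alone is not
operational, and the added test prevents discarding small Mendelian
ears on noise. An allele is dropped when the male direction retains
fewer than three ears or fewer than two distinct plants. Every
exclusion is reported with its reason.

**Class comparisons and regressions.** A gene is defect-positive if any
of its alleles is BH-significant. Fisher exact tests compare defect
proportions between classes and between the high-expression
(log2 FPKM > 8) and low-expression halves of the vegetative-cell class;
the `alternative` is exposed because the published one-sided and
two-sided conventions differ between analyses. Within a class, OLS
regressions of transmission rate and of −log10(raw p) on log2(FPKM)
give slopes, slope p-values, and adjusted R².

## Seed phenotype statistics

Per-ear small-seed fractions (or seedless-area percentages) are compared
treatment-vs-control with Welch t-tests (Satterthwaite df — chosen over
pooled-variance t as the safer default when ear counts differ).
Fertilization outcomes at 4 days after pollination classify an ovule as
a normal double fertilization only when exactly one synergid was
penetrated and both embryo and endosperm are developing; all other
outcomes are abnormal, and the resulting 2×2 table per pollen-parent
pair is tested with the two-sided Fisher exact test. Genotyped small
seeds are tested against the Mendelian 0.5 with an exact binomial test;
0.5 is used conditional on sampling small seeds, ignoring the overall
transmission deficit (which would only strengthen an observed
enrichment).

Fisher's two-sided p sums the probabilities of all margin-fixed tables
no more likely than the observed one (the minimum-likelihood
convention); this reproduces both published two-sided values (0.000241
and 0.00572) and, with one-sided alternatives, the published
class-comparison trio (0.500, 0.125, 0.374).

## Synthetic data generators

All generators are pure functions of (config, seed) built on numpy's
`default_rng`; identical inputs give byte-identical TSV/GFF3 outputs.
Truth tables (planted gene classes, activated/deactivated TE ids,
planted transmission rates) accompany every dataset so recovery tests
never re-derive the planted signal.

* **Annotation**: genes and TEs laid out on a fixed grid per chromosome
  so features never overlap; a configured fraction of TEs is placed
  with a uniform 0–1,999 bp gap downstream of a distinct host gene, the
  rest mid-gap and ≥ 2 kb from every gene. Centromeres sit at
  chromosome midpoints. TE families are drawn from a configurable mix
  dominated by LTR retrotransposons, as in the maize genome.
* **Counts**: per-feature baseline log-means ~ Normal(3.0, 1.2) (natural
  log), counts ~ NB via gamma–Poisson with dispersion 0.1, for a
  4-tissue × 4-replicate design (seedling reference, microspore, mature
  pollen, sperm cells). Male tissues activate a fraction of TEs
  (default 8–10%) with a +2 log2 effect and down-regulate a small
  fraction with the mirrored effect. With coupling κ > 0, a near-gene
  TE's activation probability in the coupled tissues scales with its
  neighbor's expression quantile q as f₀(1 + κ(2q − 1)), clipped to
  [0, 1]; κ = 0 recovers uniform activation exactly. This rank-coupling
  is one modeling device for planting the observed gene–TE association,
  not a claim about mechanism.
* **Ear counts**: 56 alleles split 10 seedling / 11 sperm-cell / 35
  vegetative-cell, four male and four female ears per allele from two
  plants, totals uniform on 380–1,305 seeds per ear so per-allele male
  totals span ≈ 1,520–5,220. Marked counts are beta-binomial with
  intra-ear correlation ρ = 0.00095, set a priori from
  φ ≈ 1 + (n̄ − 1)ρ at the mean ear size (n̄ ≈ 842) to land the pooled
  Pearson dispersion near the reported 1.8; the empirical variance is
  checked against n·p(1−p)(1 + (n−1)ρ) in the suite. Female ears are
  always Mendelian, serving as the control mirror.
* **Phenotypes**: multinomial ovule outcomes per pollen parent (wild
  type all normal; mutant half abnormal by default) and binomial
  per-ear small-seed counts.

What the generators do **not** emulate: sequence content and alignment
ambiguity (read placements are sampled directly), library-preparation
biases, isoform switching, genomic clustering of TE families, selection
against insertion alleles, or maternal/environmental structure beyond
the exchangeable beta-binomial ear effect. Passing recovery tests
therefore demonstrate correctness of the estimators under the stated
stochastic model, not performance on real sequencing data.

## Numerical choices and problem sizes

Logit links are clipped at 1e-8 from the boundary; dispersions floor at
1e-8; −log10(p) caps p at 1e-300. All rank tie-breaks use feature id.
Test and acceptance runs use deliberately small instances — 150–2,000
features, 50–100 bins, 20 seeds for calibration loops — chosen so the
full suite completes in a few minutes while keeping every Monte-Carlo
bound at least four standard errors from its threshold.

## Known limitations

The NB Wald stand-in is less powerful than DESeq2's shrinkage estimators
at very low counts and does not model outlier replicates (no Cook's
cutoff). The quasi-binomial model is intercept-only; ear-level
covariates (plant, season) would need a fuller GLM. The coexpression
statistic treats bins as independent observations for the τ p-value, as
in the original design; spatial autocorrelation along the genome is not
modeled. Isoform-level class assignment uses the gene-level maximum
across isoforms.
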