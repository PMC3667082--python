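# Methods

## Signature model

A *signature* is a named pair of disjoint up/down gene sets together with
the universe (the full set of genes measured in its source dataset) and the
log2 threshold τ it was derived at.  All derivation rules work on the log2
scale and define "fold change" as a difference of log2 means — equivalently
the log2 ratio of geometric means.  The boundary is inclusive
(|log2 FC| ≥ τ), matching the reading of "at least two-fold" for τ = 1.
Three rules are provided:

* **group vs. reference** — mean(group) − mean(reference) per gene;
* **subtype vs. rest** — mean(subtype) − mean(all other subtypes pooled);
* **paired** — per pair, the single-sample difference positive − negative;
  the consensus keeps genes recurring in ≥ `min_support` pairs.  A gene
  reaching support in both directions is contradictory evidence; it is
  removed from both sets and logged.  This case is essentially absent at
  τ = 1 and appears at the relaxed τ = 0.5, where single-sample differences
  are noisy.

No moderated statistics (t-tests, shrinkage) are applied: the pipeline's
contract is pure fold-change thresholding, and its statistical machinery
operates downstream, on set overlaps.  Inputs are assumed already
summarized to log2 gene-level (or probe-level plus a probe map); probe
rows are collapsed to genes by unweighted arithmetic mean on the log2
scale.  Missing values are rejected at load time rather than imputed — on
level-3-style matrices absence of a gene is represented by dropping the
row, which the universe/harmonization machinery handles explicitly.

## Two-sided Fisher exact test with background harmonization

Gene lists from different platforms must be compared inside the universe of
genes measured in *all* of them; otherwise platform coverage masquerades as
biology.  `harmonize_universe` intersects universes, lists are restricted
to the intersection (G′ = G ∩ background), and the 2×2 membership table is
tested with the minimum-likelihood two-sided convention:

    p = Σ { P(k) : P(k) ≤ P(a) },  k ∈ [max(0, n_A+n_B−N), min(n_A, n_B)]

with P hypergeometric.  The expected overlap E = n_A·n_B/N is reported at
full precision (display rounding is configurable), and the direction is
*enriched* when a > E, *depleted* when a < E.  Numerical choices:
probabilities are computed through `scipy.stats.hypergeom.logpmf`
(log-gamma), so backgrounds of ~10⁴–10⁵ genes cause no overflow; the
comparison P(k) ≤ P(a) carries a relative tolerance of 10⁻⁷ to absorb
floating-point ties (the convention of standard implementations — without
it, exact probability ties on the far side of the distribution are dropped
unpredictably).  Degenerate tables (empty list after restriction, or a
single possible outcome) return p = 1 and direction *none* when a = E = 0.
The test suite verifies exact agreement (rel. error < 10⁻¹⁰) with
brute-force integer-arithmetic enumeration for every table with N ≤ 60,
and cross-checks random larger tables against an independent library
implementation.

Significance defaults to α = 0.05; raw p-values are reported without
multiple-testing correction because each table cell answers a distinct,
individually interpreted question.

## Consensus k-means and the quality factor

Preprocessing follows the standard recipe: drop genes with median absolute
deviation (unscaled, MAD = median |x − median x|) below 0.5 across tumor
samples, then standardize each gene row to zero mean and unit *population*
variance (ddof = 0; switchable).  Consensus clustering draws
⌈fraction·n⌉ samples without replacement per resample, partitions them
with Euclidean k-means (best inertia of `kmeans_restarts` k-means++
initializations), and records for each sample pair the fraction of
co-drawn resamples in which it was co-clustered.  The denominator counts
*co-drawn* resamples, not all resamples, so subsampling does not bias
entries toward zero; a pair never co-drawn is an error rather than a
silent NaN.  Final labels come from average-linkage hierarchical
clustering of 1 − consensus cut at k — a deliberate choice of the standard
extraction method, since the consensus matrix itself is the object being
summarized.  One integer seed drives the resample draws and the per-resample
k-means seeds in a single documented stream order.

The cleanness of a consensus matrix is summarized by the quality factor

    QF = mean over off-diagonal entries of 2·|m_ij − 0.5| ∈ [0, 1],

which is 1 exactly when every entry is 0 or 1 (perfectly stable
partitions) and 0 when every entry is ½ (coin-flip co-clustering).  The
number of clusters is selected as the k preceding the largest drop
QF(k) − QF(k+1) over the scanned range — a formalization of the visual
"sharp drop after the true k" argument; ties break toward smaller k.

Library defaults are 500 resamples, 80% subsampling, 10 restarts, no gene
subsampling — common consensus-clustering practice, all config-exposed.
The test suite and acceptance script use 50–100 resamples with 10
restarts: at the synthetic study's separation this keeps the consensus
matrix at the true k essentially exact while staying fast, and the number
of restarts matters more than the number of resamples — with too few
restarts, occasional k-means local minima at the true k blur QF(k_true)
and dilute the drop that the selection rule keys on.

## Correlation profiling and fold-change summaries

A sample's "expression signature" for correlation purposes is its
per-sample log2 fold-change vector against the reference-group mean; an
inducer's profile is its induced-vs-control mean log2 fold change.
Pearson correlations are computed over the harmonized gene universe (all
shared genes, not signature genes only; switchable), requiring ≥ 3 shared
genes and rejecting zero-variance profiles by name.  Group averages are
plain arithmetic means of grid cells.  Mean |log2 FC| summaries over a
gene set report the absolute value of the signed mean per sample group —
the display convention under which down-regulated sets are compared by
magnitude.

## Three-way reconciliation

Given a subtype signature B and two mutually opposed programs A and C, the
discordant sets A↓∩B↑ and A↑∩B↓ (and their C/B counterparts) are tested
against the matching side of the third signature on the triple-harmonized
background.  Because discordant sets are intersections of already-small
sets, signatures for this analysis are re-derived at the relaxed τ = 0.5;
an empty discordant set skips its test with a logged notice rather than
fabricating a degenerate result.

## Synthetic studies

The generator emulates the statistical structure the pipeline is designed
to detect, not microarray technology.  Expression is Gaussian on the log2
scale: gene baselines ~ N(8, 1), additive ±δ shifts for planted
differential expression, i.i.d. N(0, σ) measurement noise.  Defaults — 5000
genes, 4 subtypes × 30 samples vs. 10 normals, δ = 2 (four-fold), σ = 0.3,
210 markers per subtype, a 200-gene core program shared by 5 inducers
(3 induced samples each vs. 3 controls, plus 50 private response genes per
inducer so that intersecting per-inducer signatures isolates exactly the
core), and 4 positive/negative sorted pairs — are the reference conditions
of the whole test suite.  At these settings the standard error of a
subtype-vs-rest mean difference is ≈ 0.06 log2 units against a threshold
of 1.0, so marker recovery is expected to be essentially perfect; the
tests confirm the machinery, and the interesting regimes are reached by
lowering δ or raising σ.

Three overlaps are planted explicitly:

* `overlap_fraction` (ρ = 0.5) of the core appears concordantly among the
  first ("mesenchymal-like") subtype's markers;
* `anti_fraction` (0.8) of the core is opposed by the paired signature
  (positive fractions shift those genes with the sign opposite to the
  core), plus 120 paired-signature genes outside the core;
* `paired_overlap_fraction` (0.4) of the anti-core appears among the
  mesenchymal-like markers with the *paired* signature's sign — i.e.
  discordantly with the core.  This third overlap is what populates the
  discordant sets of the reconciliation analysis; with only the first two
  overlaps the subtype would agree with both programs nowhere they
  disagree with each other, and all four reconciliation tests would be
  vacuous.

Each auxiliary dataset drops 2% of non-planted genes so that universe
harmonization is exercised with genuinely different backgrounds.  One seed
drives fixed per-component substreams (allocation, baselines, three noise
matrices, missingness), so adding a component never perturbs earlier draws.

What passing on synthetic data does *not* show: robustness to batch
effects, probe saturation, heavy-tailed noise, correlated genes, unequal
subtype prevalence, or cluster structure that is not well separated —
real-data behavior on those axes is out of scope here.

## Problem sizes used in validation

The exhaustive Fisher-oracle sweep covers all ~3.3×10⁵ tables with
N ≤ 60.  Clustering validation runs 10 independently seeded default
studies over k = 2..7 with 100 resamples × 10 restarts; marker-recovery
validation runs 10 seeded studies; the concordance-structure checks use a
single default study with derived (not planted) signatures at τ = 1 and
τ = 0.5.  The acceptance script repeats the same computations at the
user-supplied seed.

## Known limitations

* The largest-drop selection is stochastic near its margin: on the default
  study the QF drop at the true k exceeds the next drops by only ~0.005,
  so an occasional seed selects k = 5; the validation criterion is
  therefore stated over ten seeds rather than per seed.
* Greedy confusion-table matching is not globally optimal for pathological
  overlap patterns; for the diagonal-dominant tables it is meant for it
  coincides with the optimal assignment.
* Expected overlap, not a variance-adjusted effect size, is the reported
  baseline — the convention of the analysis this package systematizes.
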