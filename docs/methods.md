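# Methods

This note records the models, estimators, and numerical choices behind
subtypeforge, and what the synthetic cohorts do and do not establish about
behavior on real data.

## Synthetic cohorts

The generator produces the three data layers the analysis consumes, each a
pure function of a `SimConfig` and its seed. One shared seed expands into
fixed per-component child seeds (spawn keys 11/13/17 for expression, copy
number, clinical), so adding a generator call never perturbs earlier draws.

**Expression.** Genes are independent Gaussians on the log2 scale with
noise SD `noise_sd` (default 1.0); each informative gene carries a
`+effect_size` mean shift (default 2.0) in exactly one subtype, with 50
informative genes per subtype by default. Cohort scale defaults to 138
samples × 15597 genes with K=4 balanced subtypes, matching the scale of a
typical discovery cohort. This is deliberately the minimal structure that
consensus clustering and nearest-centroid classification assume. It omits
gene–gene correlation, batch effects, heavy-tailed noise, and
probe-level artifacts of real arrays — so passing tests demonstrate
correctness of the machinery and its calibration under the stated model,
not robustness to those real-data features.

**Copy number.** Markers are equally spaced within each chromosome of a
configurable genome (default 8 chromosomes × 250 markers, 150 Mb each, arm
boundary at 60 Mb). Each sample's profile is the sum of the amplitudes of
the events it carries over the markers those events cover, plus
N(0, `cn_noise_sd`²) marker noise (default 0.2, a realistic per-marker
scale for SNP-array log2 ratios). Carriers are drawn per event with
probability `carrier_fraction` within the affected subtypes. There is no
serial correlation in the noise; the cyclic-shift null is therefore exactly
correct here, slightly optimistic for real arrays with wavy backgrounds.

**Clinical.** Categorical covariates are drawn from subtype-conditional
probability tables (defaults loosely shaped like a head-and-neck cohort:
site, nodal status, treatment, HPV status). Survival is exponential with a
per-subtype hazard in events/month; censoring is independent with
probability `censoring_rate`, in which case the observed time is uniform
on (0, event time). Exponential hazards are the simplest model supporting
log-rank power checks; no covariate-dependent censoring is modeled.

## Preprocessing

Gene median centering subtracts each gene's median across samples (exactly
idempotent). Variability is the unscaled MAD — `median |x − median x|` —
without the 1.4826 consistency factor, since only the ranking matters for
gene selection and scaling is rank-invariant. Ties at the top-n boundary
break by gene-id lexicographic order for cross-platform determinism.
Missing values are rejected at load time unless per-gene median imputation
is explicitly requested.

## Consensus clustering and model selection

Per resample, ⌈0.8·n⌉ samples are drawn without replacement and clustered
hierarchically with average linkage on `1 − Pearson` distance between
samples (computed over genes); only samples are resampled. The consensus
entry for a sample pair is its co-cluster count over its co-draw count; a
pair never co-drawn is an error instructing more resamples rather than a
silent NaN. Final labels cut the average-linkage tree of `1 − consensus`.

The area under the empirical CDF of the upper-triangle consensus values on
[0, 1] equals `1 − mean(consensus)`, which is how it is computed. The
delta-area at k is the gain over k−1 (at the smallest k, the area itself).
`select_k` recommends the largest k with delta-area ≥ 0.05 — a codified
default for what is a visual judgement in practice — and flags the run
unstable when no k clears the threshold, when the recommendation sits at
the top of the examined range (the signature of a structureless blob,
where stability keeps "improving" with k), or when the proportion of
ambiguous consensus entries (PAC on (0.1, 0.9)) exceeds 0.5. Label
tracking between consecutive k counts changed samples after optimal
class matching (Hungarian assignment), so pure renamings count as zero.

## Cluster significance

The statistic for a 2-group split is the cluster index CI = within-group
SS / total SS over all genes, defined as 0 when the total SS vanishes. The
null is a single d-dimensional Gaussian fitted to the tested submatrix:
background noise variance σ² = (1.4826 × MAD of all entries)², and a
covariance spectrum derived from the sample eigenvalues (via SVD of the
centered samples-by-genes matrix).

Two spectrum estimators are provided. The *hard* rule floors each sample
eigenvalue at σ². The *soft* rule (default) subtracts a common offset τ
from every eigenvalue before flooring at σ², with τ chosen by bisection so
the total variance is preserved. The soft rule is the default because the
hard rule is severely conservative in simulation: leading sample
eigenvalues are upward-biased, and resampling from them produces null data
that look more clusterable than the data themselves. In 200-replicate
experiments across sample/gene regimes (40/20, 25/100, 100/10, 40/100,
60/500) the hard rule rejected a true single Gaussian at a rate of 0.00 at
α = .05 (mean null p ≈ 0.8–1.0), while the soft rule attained 0.01–0.04.
The trace-preserving shrinkage is the standard remedy for this bias.

Each null dataset (same n and d, independent coordinates with the null
variances) is scored by its minimal CI over 10 seeded 2-means restarts, so
the null accounts for the cluster-seeking optimization. The 2-means inner
loop is a vectorized Lloyd iteration with k-means++-style 2-point
initialization, batched across restarts; it reaches the same minima as a
general k-means library implementation at a small fraction of the per-call
overhead, which matters in a Monte-Carlo loop with hundreds of thousands
of fits. The p-value is the add-one estimator `(1 + #{null CI ≤ observed
CI}) / (1 + n_sim)`, bounded below by `1/(1 + n_sim)`; pairwise batteries
Bonferroni-adjust over the K(K−1)/2 comparisons.

## Classifier

Core samples have silhouette width > 0 under `1 − Pearson` distance on the
variable-gene matrix (the same matrix used for clustering). Gene scores
are `t_gc = (mean_c − mean_overall) / (pooled within-class SD + s0)` with
`s0` the median pooled SD; assigning each gene to its |t|-maximizing class
makes the per-class lists disjoint by construction, and the top
`genes_per_class` per class are kept (ties by gene id). The grid of
genes-per-class values (default {50, 100, 150, 210, 300}) is searched by
stratified 5-fold cross-validation with gene selection redone inside each
fold; ties prefer the smaller model. Centroids are per-class per-gene
medians over core samples. Prediction assigns the `1 − Pearson`-nearest
centroid, ties broken by class order, computed pairwise-complete with a
50% classifier-gene coverage floor.

Two transfer routes: (i) harmonization rescales external per-gene values
to the stored training means/SDs (appropriate for a comparable array
platform; zero-variance external genes are dropped with a warning); (ii)
standardized transfer median-centers and unit-scales both the centroids
(across classes) and the external data (across samples) per gene before
nearest-centroid assignment (appropriate for sequencing-based expression,
where only relative patterns transfer).

## Copy number

Imputation copies the genomically nearest non-missing marker on the same
chromosome; equidistant ties take the upstream (lower-position) marker.
Smoothing shrinks markers whose deviation from the within-chromosome
running median (window 5) exceeds 3 × the sample's MAD-based residual
scale; profiles are then median-centered per sample. Window and z are
codified defaults for an otherwise unspecified "smoothing and outlier
removal" step. Segmentation is recursive binary splitting on the pooled
two-sample t statistic, accepting splits at p < .01 with at least 3
markers per side — a deliberately plain segmenter standing in for
circular binary segmentation, adequate for the step-like profiles the
generator produces.

The recurrent-aberration statistic is the cross-sample column sum, max
over markers for gains (min for losses, ties to the first marker in genome
order). Null replicates rotate each sample's genome-wide vector by an
independent uniform offset (250 by default); the p-value is add-one with
an inclusive comparison, so an all-zero cohort gives p = 1. The bootstrap
CI (level .95, 500 resamples of samples with replacement) relocates the
peak within the observed peak's chromosome — restricting to the chromosome
avoids cross-chromosome quantile artifacts — and is expanded if necessary
to include the observed peak. Peeling resets, for every carrier sample
(peak-marker value beyond its chromosome median in the event direction),
the contiguous beyond-median run around the peak to that median, then
retests, up to five peaks per direction or the first p ≥ .05.

Gene-level copy number is the mean of segmented values at markers within
the gene plus one nearest flanking marker per side ("immediately
adjacent"; configurable to 0 flanks), with an error beyond 1 Mb. Calls
use a strict ±0.35 threshold — boundary values are neutral — applied to
segments of median-centered profiles, matching the pipeline order. The
chromosomal instability index is the median over chromosome arms of the
arm-wise median |value|; empty arms are excluded with a warning.
Region-by-subtype association averages the smoothed centered values over a
marker interval per sample and applies Kruskal–Wallis, with optional
Bonferroni adjustment over the number of regions examined.

## Association statistics

The exact r×c Fisher test enumerates all margin-fixed tables (largest row
placed last, since it is implied by the margins) and sums the probability
of tables whose hypergeometric probability is at most the observed one, at
a 1e-7 relative tolerance — the convention of the standard statistical
environments, verified to reproduce their values on 2×4 and 3×4 tables. A
10^7-state budget guards the enumeration; beyond it the Monte-Carlo
variant (permuting category assignments, add-one estimate with reported
standard error) is instructed. Kruskal–Wallis uses the tie-corrected
chi-squared approximation. Survival uses product-limit estimates and the
multi-group log-rank test via lifelines; recurrence-free survival is the
time in months to death, recurrence, or loss to follow-up, with event
flag 1 for death/recurrence.

The two-class differential-expression test uses
`d = (mean₁ − mean₂)/(pooled SE + s0)` with `s0` the median pooled SE, a
permutation null of label reassignments, and symmetric |d| cutoffs. The
estimated FDR at a cutoff is the median over permutations of the null
exceedance count, divided by the number of called genes — with the
estimated null count floored at 0.5, since a finite permutation set cannot
certify fewer than about half a false call; without this floor the single
most extreme gene is spuriously called on roughly half of null datasets
(its estimated FDR is exactly 0 whenever the observed max beats most
permutation maxima). The selected cutoff is the smallest one whose
estimated FDR meets the threshold, maximizing calls; the called set is
monotone in the threshold.

## Problem sizes in the test and acceptance suites

The statistical property checks run at reduced but structurally faithful
sizes chosen as study conditions: consensus recovery at 120 samples × 1000
genes (250 resamples), significance calibration at 40 samples × 20 genes
with 200 replicates × 200 null simulations, the cyclic-shift checks at
500–1000 markers with 40–60 samples and 250 shifts, and the
differential-expression power check at 5000 genes with 100 planted
2-sigma shifts (30 + 30 samples). The acceptance script uses a 2000-gene
cohort for the 210-genes-per-class structural check and a 500-gene cohort
at 1000 simulations per pair for the significance battery.

## Known limitations

- The expression model is gene-independent; consensus stability on
  correlated real data is typically lower than on these cohorts.
- The segmenter is a plain binary-splitting stand-in, not a drop-in
  replacement for circular binary segmentation on noisy real arrays.
- The hard-threshold significance null remains available but is
  conservative; results produced with it should be read as lower bounds on
  significance.
- Exact Fisher enumeration is practical for the 2×4/3×4 tables of typical
  clinical summaries; larger tables fall back to Monte Carlo.
- Survival simulation is exponential with independent censoring; no
  competing risks or covariate-dependent censoring.
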