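# Methods

This note documents the models, estimators and design choices behind
`mirdiag`, in the order the pipeline applies them.

## Data model and the synthetic cohort generator

The generator emulates probe-level data from a biochip miRNA array study
of pancreatic disease: `n_mirnas` transcripts (default 863, the number of
miRNAs consistently annotated across the array's annotation releases),
`n_replicates` identical features per miRNA (default 7), and diagnostic
classes with the study's cohort sizes available as presets (blood
45 PDAC / 38 CP / 33 healthy; tissue 94 / 19 / 16).

Each sample `s` carries a latent glog-scale abundance per miRNA `m`

    x[s,m] = mu[m] + delta[m, class(s)] + eps,   eps ~ N(0, sigma_bio^2)

and each replicate feature measures

    y = o_a + b_a * sinh(x) * exp(eta) + N(0, sigma_add^2),  floored at 0

with per-array offset `o_a` and scale `b_a`, multiplicative noise
`eta ~ N(0, sigma_mult^2)`, and additive background noise.  This is the
additive–multiplicative error model that variance-stabilizing
normalization (VSN) is derived for, so preprocessing is exercised on data
it is designed to handle.  Class effects are additive on the glog scale
with a random sign per miRNA — the rank-shift alternative the
Wilcoxon–Mann–Whitney test detects.

Defaults (chosen once as plausible study conditions; no generative
parameters are published for the deposited cohort, so these are not
estimates of it):

| parameter | default | meaning |
|---|---|---|
| `mu[m]` | U(0, 10) per miRNA | baseline glog abundance; 0 = detection limit (background only), 10 ≈ 1.1e4 raw units, ~4 decades of dynamic range |
| `sigma_bio` | 0.5 | biological between-sample SD, glog units |
| `sigma_mult` | 0.1 | multiplicative replicate noise SD (log scale); yields technical-replicate correlations ≈ 0.97+ |
| `sigma_add` | 1.0 | additive background noise SD, raw units |
| `o_a` | U(0, 10) | per-array additive offset |
| `b_a` | U(0.7, 1.3) | per-array calibration factor |
| `effect_size` | 1.0 | planted class shift, glog units (study-condition scenarios use multiples of `sigma_bio`) |
| `marker_overlap` | 0.3 | fraction of each disease class's marker set shared (identical shifts) across disease classes |

Letting `mu` extend down to 0 matters: the per-array background estimate
is the 5th intensity percentile, which only estimates the additive offset
if the weakest probes are background-dominated.  Real arrays have probes
at or below the detection limit; a simulator whose weakest probe still
carries substantial signal would make any quantile-based background
correction subtract signal instead of background.

Shared markers across disease classes receive *identical* shifts, so
they cancel in the disease-vs-disease comparison — giving the three
pairwise comparisons a reproducible Venn-region structure by
construction.  The ground-truth differential set for a comparison is
defined exactly as the miRNAs whose planted shifts differ between the
two classes.

What the generator does **not** emulate: spatial array artifacts, probe
cross-hybridization, sequence-dependent probe affinities, batch effects
between clinical centers, and correlated miRNA co-regulation (planted
effects are independent across miRNAs).  Passing tests therefore show
the pipeline's statistical machinery is correct under its stated model,
not that the published cohort's numbers are reproduced.

## Preprocessing

1. **Background correction**: subtract each array's 5th-percentile
   intensity, floor at 1e-6.  The array layout's blank features are not
   available, so a low quantile stands in for them; any residual additive
   error is absorbed by the calibration fit below.
2. **Replicate summary**: median of the replicate features per
   (sample, miRNA); robust to up to three outlying features of seven;
   midpoint convention for even counts.
3. **Calibration + glog**: each array is calibrated onto a reference
   array (the one whose total intensity is the cohort median — a
   deterministic, outlier-resistant choice) and transformed with
   `h_s(x) = asinh((x − a_s)/b_s)`.

The affine parameters are fitted by robust regression of the array's
intensity quantiles onto the reference's quantiles, in two steps:

* slope `b_s = exp(median(log q_s − log q_ref))` over the quantile range
  0.25–0.95, where the distribution is scale-dominated.  A median
  log-ratio cannot be destabilized by the heavy-tailed top intensities
  (a raw-scale Theil–Sen fit on the same quantiles can be, because the
  largest order statistics of a sinh-scale distribution fluctuate by
  factors of ~e^sigma_bio between arrays).
* offset `a_s` = median residual `q_s − b_s·q_ref` over the low quantiles
  (≤ 0.25), where background dominates.

This replaces the full maximum-likelihood VSN fit with a transparent,
dependency-light estimator that keeps the method's contract: per-array
affine calibration followed by the variance-stabilizing glog.
Equivalence is asserted through the variance-stabilization *property* —
after normalization the median per-miRNA SD varies by at most 1.5× across
intensity quintiles, versus ≥ 3× (in practice ≫ 100×) before — not
through coefficient identity with any particular implementation.

The transform is strictly monotone within each array, so all downstream
rank statistics are invariant to each array's calibration.  Stage tags
(`raw-summarized` / `normalized`) make it an error to normalize twice.

## Differential abundance

Per miRNA, an unpaired two-tailed Wilcoxon–Mann–Whitney test compares
the two classes: exact enumeration when the smaller group has ≤ 8
observations and the pooled values are tie-free, otherwise the normal
approximation with tie and continuity corrections.  P-values are adjusted
across the full miRNA universe by Benjamini–Hochberg step-up;
significance is called at adjusted p < 0.05 (a flag switches to raw p,
since published marker counts do not always state the scale).
Shapiro–Wilk normality statistics are recorded per group for reference
but never gate the rank test — inference is always nonparametric.
Effect direction is reported as the difference of group medians on the
glog scale.

## Single-marker metrics

Mutual information between the class label and the dichotomized marker
is computed in bits with the plug-in estimator on the 2×2 table, scanning
every midpoint between adjacent observed values and reporting the
maximizing threshold (a median split is available as an option).  The
optimal-threshold choice is deterministic and pairs naturally with a
single sensitivity/specificity operating point.  The marker's AUC equals
the Mann–Whitney probability of correct ranking (ties ½); in the
`marker_info` summary the orientation (disease-high vs disease-low) is
chosen to maximize sensitivity + specificity and the AUC is reported in
that orientation.

## Classification

RBF-kernel SVM (C = 1, gamma = 1/(n_features·variance) by default; both
exposed, as are the other kernels, none of which are tuned) under
`n_repetitions` independent repetitions of stratified k-fold
cross-validation (default 100×10-fold; stratification is used because
the cohorts are heavily imbalanced — unstratified folds of a 94 vs 16
comparison would often lack a class entirely).

Feature selection is fully nested:

* within each **training fold**, miRNAs are ranked by their univariate
  WMW p-value computed on that fold only (ties broken by miRNA id);
* the panel size is chosen from the configured grid
  (default {5, 10, 20, 36, 50, 100}, bracketing the handful-to-dozens
  panel sizes a pancreatic miRNA signature needs) by an **inner**
  stratified 5-fold CV of the training fold, with ranking redone inside
  every inner split;
* the SVM is refit on the whole training fold with the chosen panel and
  only then predicts the held-out fold.

Choosing the panel size by held-out accuracy instead (a tempting
shortcut) is itself a selection-on-test leak: measured on null data it
inflates the mean AUC by ≈ +0.03 with excursions well past 0.55.  The
nested procedure keeps null data at chance.

Per repetition, metrics come from the pooled held-out predictions
(accuracy, sensitivity and specificity with "positive" = the disease
class, stated in the output) and the pooled decision values (AUC).  The
reported panel size per repetition is the modal fold choice.  Aggregates
are means with percentile (2.5/97.5) 95% CIs across repetitions; the
stored ROC pools decision values over all repetitions.  A final
refit on all data can be used to report a single panel; the per-fold
panels are retained in the evaluation object so the distinction stays
visible.

The ranking inside CV uses a vectorized normal-approximation WMW z-score
without tie correction: on continuous expression values ties are
measure-zero and the p-ordering equals the |z| ordering, while the exact
user-facing `wmw_test` remains available for inference.

**Permutation control**: the identical pipeline is rerun
`n_permutation_reps` times, each after an independent random permutation
of the class labels.  With nested selection the permuted-label AUC and
accuracy sit at chance; strong real-label results with chance-level
controls rule out over-fitting as the explanation.

## Overlap significance

Marker sets from different comparisons live in the same miRNA universe
of size N.  Under the null of uniform independent draws without
replacement, the expected pairwise overlap is `a·b/N` (the
hypergeometric mean) and the expected mutual triple overlap is
`a·b·c/N²`.  The permutation test draws the sets (the first set can be
fixed by symmetry), counts the mutual intersection, and reports the
one-sided (enrichment; that is the direction of scientific interest)
empirical p with the +1 correction `(#{null ≥ obs}+1)/(n_perm+1)`, which
can never be exactly zero — a raw-count estimator can, which is the only
difference from quoting `k/n_perm`.  Draws are vectorized in blocks of
4096 permutations to bound memory at the default 100,000 permutations.

## Clustering check

Agglomerative complete-linkage clustering on Euclidean distances between
normalized sample profiles ("top-down complete linkage" is a
contradiction in terms — complete linkage is agglomerative — and the
agglomerative reading is implemented).  Dendrograms are cut at given
heights or cluster counts; a 2-cluster cut yields one two-tailed Fisher
exact p from the cluster × class table, larger cuts are scored
one-cluster-vs-rest (p-values unadjusted; a Bonferroni factor of the
cluster count applies if used inferentially).  Cuts leaving a single
cluster are skipped with a warning.  The two-tailed Fisher p follows the
point-probability convention (sum over tables with fixed margins whose
probability does not exceed the observed table's).  Dendrograms export
to Newick with merge heights as branch lengths.

## Numerical and degenerate-input conventions

* All randomness flows from one integer seed; stages derive child seeds
  via a counter-based scheme (CRC32 of the stage name as spawn key), so
  adding a stage never shifts another stage's stream, and identical
  configs give bit-identical outputs including the pipeline summary.
* Constant vectors: Shapiro–Wilk and Pearson correlation raise;
  mutual information of a constant marker is 0 (independence).
* WMW with an empty group, single-class labels anywhere, sets exceeding
  the universe, non-positive CV sizes: ValueError.
* Leave-one-out (k = n) bypasses stratification (singleton folds);
  otherwise every class must have at least k members.
* TSV writers use `%.17g` so doubles round-trip exactly; readers parse
  with round-trip float precision.

## Problem sizes used in the shipped checks

The automated checks run the study's array geometry (863 miRNAs) at
desk-scale sample and repetition counts chosen by us: 40 + 40 samples
with 20 CV (or permutation) repetitions for the chance-level and
perfect-discrimination checks, 25 + 25 samples for parameter recovery,
10,000 replicates for the type-I-error check, and 20,000–40,000
permutations for the overlap-null checks.  Increasing the repetition
counts to the study's 100×10-fold and 100,000 permutations changes only
the width of the confidence intervals, not the conclusions.

## Known limitations

* The VSN calibration is quantile-based, not maximum-likelihood; arrays
  whose quantile-quantile relation to the reference is strongly
  nonlinear (e.g. saturation) are calibrated only approximately.
* Mutual information uses the plug-in estimator without bias correction;
  with few samples the optimal-split MI is optimistically biased (both
  facts are inherent to the estimator the metric specifies).
* Classification is strictly binary, mirroring the pairwise study
  design; multiclass is out of scope.
* The overlap null assumes uniform, independent marker sets; it does not
  condition on expression level or inter-comparison correlation.
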