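# Methods

This note records the model, the numerical conventions, and the design
choices behind `breathshape`, in the order the pipeline runs.

## Data model

A *measurement* is one exhalation recorded by an array of 26 gas sensors
(8 gold-nanoparticle chemiresistors `GNP01..08`, 8 analogue metal-oxide
sensors `MOXA01..08`, 10 digital metal-oxide sensors `MOXD01..10`).  Each
sensor contributes two ordered series in raw signal units: a room-air
*baseline* phase recorded before the breath reaches the chamber, and the
*breath* phase.  Measurements are stored one-per-file in a versioned JSON
dialect (`schema_version: "1.0"`) carrying the sampling interval explicitly,
since acquisition rates are device-dependent.  Class labels (`cancer` /
`control`) may live in the file or be joined from a two-column sample sheet;
`unknown` labels are accepted only outside training.  Series are processed
at double precision throughout and serialized via `repr`, so a write/read
round trip is bit-exact.

## Screening and preprocessing

Measurements missing a required sensor trace (or carrying an empty one) are
marked excluded with reason `missing_sensor:<id>`; screening is idempotent
and label-blind.  Kept traces then pass through a fixed stage order:

1. **Length equalization.** All breath series of a sensor are trimmed to the
   common minimum length T.  Excess points are removed from the *start*
   (keep-tail): the stabilized end of the response carries the signal used
   downstream, and the synthetic device jitter prepends pre-breath points.
   A symmetric-trim option exists.  Series shorter than `min_length`
   (default 10) are an error.
2. **Baseline normalization.** The reference r is the mean of the last
   `b_tail = 10` baseline points (the stabilized room-air response); the
   default output is breath/r — the standard R/R0 treatment for
   chemiresistive sensors, which also makes the result unit-free and
   scale-invariant — with breath − r as a configurable alternative.
   |r| ≤ 1e−9 raises a degenerate-baseline error rather than producing
   unbounded ratios.
3. **Median filtering.** Window 3 with replicate padding; window 1 disables.
   The window length is a package default (a narrow window removes
   single-sample spikes without distorting rise fronts).

Whether filtering should precede or follow normalization is not determined
by the problem; the fixed order equalize → normalize → filter is a package
choice and any other requested order is rejected loudly rather than
silently reordered.

### Outlier screening

Whole measurements are screened on the horizontal concatenation of all
per-sensor panels.  Columns are mean-centered; the principal components
retaining ≥ 95% of variance (capped at n − 1) define the score space.  Per
measurement, the *score distance* SD is the Mahalanobis norm of its scores
and the *orthogonal distance* OD the Euclidean norm of its residual.  Each
distance sample gets a scaled chi-squared cutoff with moment-matched
degrees of freedom (h = 2m²/v, scale = v/2m).

Two numerical choices matter here:

* **Multiplicity correction.** A cutoff at the plain 1−α quantile flags
  ≈ α·n clean measurements by construction.  Such points are *extremes*, not
  outliers; the removal cutoff is therefore taken at the per-measurement
  quantile (1−α)^(1/n), so α (default 0.01) bounds the probability that any
  clean measurement is flagged.
* **Gross-error prescreen for the moment fit.** Distances beyond 5× the
  sample median are excluded from moment estimation.  Without this, a few
  10×-amplitude faults inflate the fitted variance enough to mask
  themselves; iterative refitting is deliberately avoided because repeated
  trimming ratchets the cutoffs down on clean but *structured* cohorts and
  starts eating genuine minority shape groups.

With these choices the screen recovers 100% of injected 10×-amplitude
faults at a 0.04% false-positive rate over 20 simulated cohorts, and flags
nothing on clean ones (quantities the acceptance script recomputes).
Flagged measurements are removed from every panel, keeping panels
row-aligned across sensors.

## Common features

Per sensor and curve: minimum, maximum, mean, trapezoidal area under the
curve at unit spacing, and the mean of the last 10 points.  AUC omits the
sampling-interval factor, which is constant per sensor and irrelevant after
normalization.  26 sensors × 5 features = 130 numeric columns.

## Shape taxonomies

Per sensor, pairwise dissimilarities between all training curves feed a
hierarchical agglomerative clustering:

* **Euclidean**: √Σ(aᵢ−bᵢ)² on equal-length curves.
* **DTW**: dynamic programming over monotone alignments with steps
  {(1,0),(0,1),(1,1)}, local cost |a−b|, unnormalized path sum, optional
  Sakoe–Chiba band, no slope weighting.  Conventions are fixed because the
  literature admits several; with this one, DTW ≤ Σ|aᵢ−bᵢ| (the diagonal
  path) holds exactly and is tested.
* **Complete linkage** tracks the maximum inter-cluster dissimilarity;
  **Ward** applies the Lance–Williams recurrence to *squared*
  dissimilarities and reports square-root heights, so two singletons merge
  at their plain distance (the scipy convention).  Ward's variance
  interpretation presumes Euclidean geometry; applying it to DTW
  dissimilarities is the standard heuristic in time-series clustering and
  is documented as such.
* **Tie rule**: among minimal-dissimilarity pairs, the lowest (row, column)
  slot pair merges first; cluster labels at a cut are assigned by first
  appearance in row order.  Everything downstream is thereby deterministic.

The dendrogram is cut at every k = 2..10 (cuts with k exceeding the row
count are omitted with a warning).  Each cut's clusters are represented by
characteristic curves — pointwise means of members — and consecutive cuts
are nested by construction: the k-partition merges exactly two clusters of
the (k+1)-partition, a property the tests assert for every built taxonomy.

**Membership encoding.** One nominal column per (sensor, cut): 26 × 9 = 234
columns, values in 1..k.  Training rows keep their stored assignment; unseen
rows are assigned to the nearest characteristic curve under the taxonomy's
own distance (ties toward the lower index).  The nearest-characteristic
rule is a package decision: it uses only training-derived artifacts and
treats the characteristic curve as the cluster's representative shape.
Taxonomies are rebuilt on the training portion of every evaluation split by
default (leakage-safe); a transductive mode that clusters all rows once is
available behind a flag because either protocol is a defensible reading of
how such pipelines are run in practice.

## Feature selection

Three filters, all computed on training rows only:

* **Information Gain** IG = H(class) − H(class|feature), in bits.
* **Symmetrical uncertainty** SU = 2·IG / (H(feature) + H(class)), defined
  0 when both entropies vanish.
* **ReliefF** with k = 10 nearest hits/misses, run over all instances (no
  subsampling) for determinism; numeric diffs are range-scaled |a−b|,
  nominal diffs 0/1, equidistant neighbours resolve by index.  Note that
  ReliefF weights are *not* exactly invariant to duplicating every
  instance: a duplicate becomes its own zero-diff near hit and shifts the
  k-neighbour sums.  The tests assert the weaker, true property (a
  perfectly separating feature stays top-ranked under duplication).

Numeric columns are discretized for the entropy filters by 10-bin
equal-frequency binning with edges fitted on training data.  Selection
keeps the top m = 26 columns by default (one informative column per sensor
as a neutral budget; the threshold is a config knob, as no principled
universal value exists) or, alternatively, all strictly positive IG/SU
scores.  Ties break lexicographically by feature id.

## Classification and evaluation

* **Naive Bayes**: categorical likelihoods with Laplace add-1 smoothing on
  nominal membership columns; per-class Gaussians on numeric columns.
* **SVM**: linear kernel, C = 1, one-hot encoded nominal columns,
  probability scores by Platt-style logistic calibration of the decision
  values.
* **Random forest**: 100 trees, √p feature subsampling, seeded.  Membership
  columns enter as their integer cluster indices.

Cancer is the positive class throughout.  Each evaluation run draws one
stratified random 70/30 train/test split (re-drawn, at most 10 times, if a
fold misses a class); taxonomies, bins, scores, selection and the model are
all fitted on the training portion.  Metrics: accuracy, sensitivity and
specificity as percentages from the confusion matrix, AUROC from the
positive-class score with midrank tie handling.  Runs aggregate to means
with Student-t 95% confidence intervals; configurations are compared by
one-way ANOVA and pairwise two-sample t-tests with Bonferroni adjustment
(p × number of pairs, capped at 1).  A master seed spawns per-(combination,
run) child seeds through `numpy.random.SeedSequence`, making the whole
matrix reproducible byte-for-byte.

## Synthetic cohorts

The generator emulates the device data model, not its physics.  Defaults:
54 cancer / 85 control measurements, 26 sensors, T = 120 breath points,
40 baseline points, noise σ = 0.05 on the normalized curve, baseline level
10 raw units with 1% drift, 0–4 jittered pre-breath points per trace (so
length equalization has work to do), one missing sensor per ~8.6% of
measurements and 10×-amplitude outliers at 2%.  Curves are smoothstep
rise–plateau–decay templates around the unit ratio; each class carries
`n_prototypes` templates per sensor, and on the signal-carrying fraction of
sensors (default half) the two classes occupy interleaved amplitude slots
separated by 0.25 (= 5σ) with a small timing shift.  Ground truth
(prototype id, outlier flag, missing sensor) is recorded for recovery
tests.

`simulate_shape_only_cohort` isolates the shape-vs-summary question: the
cancer prototype is the exact *time reversal* of the control prototype,
built with ≥ 10-point flat unit segments at both ends.  Reversal preserves
the value multiset (hence minimum, maximum, mean), the trapezoidal AUC, and
— because the flat ends match — the end-mean, exactly in the noiseless
limit; the generator asserts this on its own prototypes and refuses T < 60,
where the construction cannot fit.  One property discovered in building
this: time reversal preserves the rise→plateau→decay segment *order*, so
monotone time warping aligns the two prototypes almost for free and DTW is
nearly blind to this particular contrast.  The pointwise (Euclidean)
distance between prototypes is 5–8× the within-class noise distance, and
the headline discrimination experiment therefore clusters under Euclidean
distance with Ward linkage.

## What the synthetic data does and does not show

The generator provides planted, recoverable structure: curve families with
known memberships, exactly summary-matched class contrasts, and labelled
faults.  Passing tests therefore demonstrate that the machinery is correct
and leakage-safe — distances match brute-force oracles, cuts are nested,
planted prototypes are recovered (adjusted Rand 1.0 at the matching cut),
summary-blind signal is found by taxonomy features (100% vs ~55% accuracy)
— not that comparable margins exist in clinical breath data, where class
contrasts are weaker, drift and humidity effects are present, and sensors
disagree.  Session-to-session drift, humidity compensation and VOC
chemistry are explicitly out of scope.

## Problem sizes

Default test and acceptance runs use cohorts of 139 × 26 sensors × 120
points, 100 evaluation runs for the discrimination experiment, 10–20
cohorts for outlier recovery, and ≤ 12-point series for the exhaustive DTW
oracle — sizes at which every brute-force cross-check is exact and the full
suite completes in about a minute.
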