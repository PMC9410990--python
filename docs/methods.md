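# Methods

This note records the models, the numerical choices, and what the
synthetic data can and cannot demonstrate.

## Data model

A survey is an n × p table of continuous measurements with unique
sample ids, unique feature names and a class label per sample (the
producing area, treated as an opaque identifier).  Non-detected
measurements are NaN; a column that is NaN in every row (an element
below the detection limit throughout, such as Se and Cd in the
motivating survey) is removed by `drop_nondetected` before analysis.
CSV readers accept empty cells and `ND` (case-insensitive) as
non-detected; writers emit empty cells.  The isotope ratios are stored
exactly as printed in the source summaries, without unit conversion.

## Auto-scaling

Every feature is centred to zero mean and scaled to unit standard
deviation (n−1 denominator), the standard auto-scaling of chemometrics;
"unit length" in this package always means unit sd.  Scaling parameters
are estimated on training data only and re-applied to test data.
Zero-variance features are an error naming the feature.

## Stahel–Donoho outlyingness

For each of 500 directions a drawn uniformly on the unit sphere
(normalised Gaussian draws, seeded), each sample's projected value is
standardized as |aᵀxᵢ − med| / (1.4826 · MAD); the score is the maximum
over directions, and scores above 3 are flagged (a 3σ-style rule — the
1.4826 factor makes MAD estimate σ at the Gaussian).  Directions with
zero projected MAD are degenerate and skipped; all-degenerate input is
an error.  Diagnosis runs within each class separately, on auto-scaled
features (the choice to scale first is a package decision and is
configurable by scoring any matrix directly with `sde_outlyingness`).

A caution that shapes how the scores should be read: with n = 30
samples in p = 16 independent dimensions, the maximum of 500 robust
z-scores concentrates near 3 even for perfectly clean Gaussian data
(the max of ~500 weakly correlated |N(0, 1)| values is ≈ 3.2, further
inflated by MAD noise at n = 30).  Absolute calibration of the cutoff
therefore depends strongly on the effective dimension of the data:
real elemental fingerprints are strongly correlated and behave like
low-dimensional data, while the synthetic generator's independent
features are the worst case.  What is robust in either regime — and
what the tests assert — is the *contrast*: a gross outlier displaced by
≥ 10 within-class sd scores far above every clean sample and is always
the within-class argmax, so ranking-based removal (drop the worst
sample of a flagged class) is reliable even where the absolute
false-flag rate of the 3-cutoff is not.

## DUPLEX splitting

Per class, on Euclidean distances of the class's rows: the two mutually
farthest points seed the training set; the farthest remaining pair
seeds the test set; thereafter the remaining point with maximal
minimum distance to the growing set is added to train and test
alternately.  Once the test set reaches its quota all remaining points
join the training set, which realises unequal quotas such as 20/10
exactly while both sets keep spanning the occupied space.  Ties break
toward the lowest row index, so the split is deterministic.  Per-class
splits are concatenated; the result is invariant to row interleaving
across classes.

## PLSDA

Deflation-based PLS1 (single ±1 response): w ∝ Xᵀy, t = Xw,
p = Xᵀt/tᵀt, q = yᵀt/tᵀt, rank-one deflation, repeated for A latent
variables; the regression vector is W(PᵀW)⁻¹q folded back to the
original feature scale.  Features are auto-scaled inside the fit; the
response is centred by its mean.  A is capped at min(n−1, p) and the
fit errors if deflation exhausts the effective rank first.

"Balanced centering" (on by default for one-vs-rest submodels, off for
pairwise ones): the decision threshold is placed midway between the two
class-mean fitted responses instead of at the response origin, so a
36-fold majority class cannot drag the boundary toward the minority.
This is implemented as a threshold shift after an ordinary fit; the
equivalent formulation via response recentring was rejected because
with ±1 codes the unweighted mean of the class-label means is
identically zero, which would leave imbalance uncorrected.

A selection: 100 Monte-Carlo splits, 80% calibration / 20% validation,
candidate A = 1..10, minimising the pooled rate Σmᵢ/Σvᵢ (ratio of
sums, not mean of per-split rates — splits with more validation
objects weigh more); ties go to the smaller A.  Splits whose
calibration part lacks a class are redrawn (at most 50 attempts).  A
candidate exceeding a calibration draw's rank counts all its validation
objects as errors rather than aborting the search.

## LS-SVM

RBF kernel K(x, z) = exp(−‖x−z‖²/σ²) — note σ² without a factor 2; the
grid search absorbs the convention, but it is fixed here for
reproducibility.  Training solves the dense (n+1) system
[[0, 1ᵀ], [1, K + I/γ]]·[b; α] = [0; y] by LU; the relative residual is
stored and asserted ≤ 1e−8 in the tests.  Prediction is
Σᵢ αᵢK(xᵢ, x) + b, thresholded at 0.

(σ, γ) selection: stratified seeded 10-fold CV over log₂ grids,
default σ ∈ 2⁻³..2⁷ · √p (auto-scaled features put typical pair
distances near √(2p)) and γ ∈ 2⁻⁵..2¹⁰, minimising RMSECV between the
±1 codes and the continuous held-out responses.  Ties go to the
smaller σ, then the smaller γ, by value — the argmin does not depend
on grid ordering.

## Multiclass strategies

Class order is first appearance in the training table; all internal
tie-breaks ("lowest class id") use this order, which for the integer
labels of the synthetic surveys coincides with numeric order.

* **OVR**: one balanced-centred binary model per class, trained on the
  stated class subset only; winner = argmax of threshold-centred
  responses.
* **OVO**: one model per unordered pair, trained on that pair's
  samples; each model votes, and credits its signed margin to the class
  it favours.  Winner = max votes.
* **ES**: the pairwise pool is trained once up front; 3-class (and
  tie-break) OVR submodels are trained on demand and cached by class
  subset, since the subsets are object-dependent.  Stage subsets are
  ranked by the *first* OVO's votes throughout, with ties in the vote
  ranking broken by the summed signed margins, then class order.  The
  stage schedule halves the class count with round-half-up
  (α(1) = k, α(i+1) = round(α(i)/2)), stopping before any stage falls
  below `min_classes` = 10.  For k = 37 this gives 37 → 19 → 10 and six
  subclassifiers.  The direct-formula variant round(k/2^(i−1)) is
  available (`mode="formula"`); it differs at k = 37 (third stage 9,
  which the stopping rule removes) and the recursive form is the
  default because it reproduces the intended 37 → 19 → 10 staging.
  Each subclassifier casts exactly one vote (its winner); max-wins
  combines them, and an exact tie is resolved by an OVR model trained
  on the tied classes only, consistent with every other OVR submodel.

Hyperparameters are selected independently for every binary submodel,
on that submodel's training samples only; submodel seeds are derived
deterministically from the spec seed and the submodel's class indices,
so a fitted system is reproducible bit-for-bit from (data, spec).

## Synthetic surveys

The generator emulates the survey design the package was built around:
k = 37 classes × 30 samples; per feature, the published lowest/highest
range and sd of the 37 class averages; Se and Cd all-non-detected; one
gross outlier planted in each of classes 20, 27, 37.  Class means are
drawn uniformly on [lowest, highest] per feature, independently across
features — the only between-class statistics published are range and
spread, and no covariance is invented.  Within-class noise is i.i.d.
Gaussian with sd = 0.25 × (sd of class averages); the fraction 0.25 is
a free generator parameter (no within-class dispersion was published)
chosen to give visible but not hopeless class overlap, and it is the
difficulty knob exposed to callers.  Planted outliers displace one
sample by a stated multiple (default 12) of the within-class sd along
a random direction.  Identical seeds give identical tables.

What passing tests on these surveys do **not** show: real fingerprints
have strongly correlated features (soil chemistry drives many elements
jointly), detection-limit censoring, and geography-driven isotope
gradients, none of which are simulated.  Absolute accuracies on
synthetic surveys are therefore not comparable to accuracies on real
ones — the tests assert structure (counts, schedules, invariances),
limiting behaviour (perfect separation at 5% within-class sd,
chance-level accuracy under permuted labels) and agreement with
independent solvers, not survey-specific accuracy values.

## Problem sizes

The test suite and examples run reduced designs (typically 4–12
classes, 6–20 samples per class, 3–8 features, MCCV splits 6–20, grid
folds 4–5), chosen so the whole suite completes in seconds while still
covering multi-stage schedules and all six strategy × classifier
systems; the survey-scale accounting checks (1110 → 740/367) run at
full size because they are cheap.  The acceptance script fits the full
37-class ensemble (666 pairwise models) on a 37 × 6 survey with
2-component PLSDA submodels — the subclassifier count and schedule it
reports are invariant to these sizes.

## Known limitations

* The SDE 3-cutoff is uncalibrated in high effective dimension (see
  above); use the within-class ranking, or recalibrate the cutoff, when
  features are nearly independent.
* PLS1 deflation is the classical algorithm without orthogonalised
  score re-projection; for the shallow models used here (≤ 10 LVs) the
  numerical difference is negligible.
* LS-SVM training is dense O(n³); fine for surveys of a few thousand
  samples, unsuitable far beyond that.
* The ensemble's staged subsets all derive from the first OVO's vote
  ranking; if C1 is badly wrong the later stages cannot recover classes
  it ranked below α(i).
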