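# Methods

## Problem and scope

`histomil` models recurrence risk in non-metastatic, ER-positive,
HER2-negative breast cancer from whole-slide images (WSIs) that have
already been reduced to *bags of patch embeddings*: each slide is an
N x d matrix of feature vectors produced by a pretrained patch encoder,
with the pixel coordinate of every patch retained.  The target is the
PAM50-based ROR-P score, either as a three-way risk group (low
< 11.76471, medium in [11.76471, 52.94118), high >= 52.94118; the binary
task pools low/medium against high) or as the continuous score.  The
package does not read slide pixels, run encoders, segment tissue, or
compute transcriptomic scores; those are upstream of its interface.

## Patch geometry

Scanners differ in microns per pixel (MPP), so patching is specified in
physical units: a patch covers `patch_um` x `patch_um` microns (default
128 x 128 um^2) and its pixel side is `round(patch_um / mpp)` with
ties-to-even (deterministic across platforms).  The grid is anchored at
(0, 0) with no overlap; partial edge patches are discarded.  Coordinates
are 0-based, top-left origin, half-open extents.  Slides with missing or
non-positive MPP cannot be patched at constant physical size and raise
`MissingMPPError`, signalling exclusion.  A patch intersects a polygonal
region mask when their overlap has strictly positive area; touching
boundaries do not count.

## The gated attention-MIL head

Each patch embedding is mapped through a fully connected layer with ReLU
and dropout (`h_i`, width L = 512 by default, dropout p = 0.25).  Gated
attention scores each patch with
`a_i = w^T (tanh(V h_i) * sigmoid(U h_i))` (branch width D = 384), the
scores are softmax-normalised, and the bag representation is the
attention-weighted sum `z = sum_i alpha_i h_i`.  A final linear layer
emits two logits (classification) or one continuous score (regression).
The head is permutation-invariant by construction and its attention
weights always sum to 1.

The head, its analytic gradients and the AdamW training loop are
implemented directly in NumPy.  A central-finite-difference gradient
check in the test suite is the independent oracle for the backward pass.
Training uses one bag per optimisation step, cross-entropy or squared
error, learning rate 1e-4, weight decay 1e-4, at most 40 epochs, and
early stopping on validation loss with patience 5; the parameters of the
best-validation epoch are returned.  These optimisation details are
standard ABMIL practice; correctness is judged by recovery properties on
planted cohorts, not by any particular training trajectory.  Regression
targets are standardised internally using the training-split mean and
standard deviation and predictions are de-standardised, because raw
ROR-P-scale targets (~40 +- 30) are poorly matched to the step size.
One master seed fans out to parameter initialisation, data order and
dropout, so training is bit-reproducible on one platform.

## Cross-validation and ensembling

Folds are assigned to *participants* (never slides), stratified by risk
group, so a participant with several slides can never straddle train and
test.  In each of the k = 10 iterations one fold is the test set, the
next fold is the validation set, and the remaining eight train the
model.  The choice of one whole fold as validation (rather than a random
fraction of the nine) keeps the fold machinery self-contained.  Pooled
test predictions cover every slide exactly once; pooled validation
predictions are reused for Youden threshold selection.  External cohorts
are scored by the ensemble of the 10 fold models: per-model softmax
probabilities are averaged for classification (read as "averaging the
softmax-transformed logits"), raw outputs for regression.

Training uses the full cohort; all reported metrics are restricted to
the ER-positive/HER2-negative eligible subset, mirroring the clinical
target population of the assay.

## Metrics and comparison tests

* **ROC AUC** in the Mann-Whitney form (ties get half credit), with
  **DeLong's test** on structural components for comparing two
  correlated AUCs on the same subjects.
* **Pearson r** with the **Meng-Rosenthal-Rubin z** test for two
  dependent correlations; the predictor-predictor correlation is
  computed on the same rows as the two criterion correlations.
* **Benjamini-Hochberg** adjustment within each (task, metric) family of
  pairwise comparisons against the baseline encoder.  BH output
  dominates the raw p-values and preserves order; it is a fixed point of
  itself only for flat (all-tied) outputs, which is what the worked
  examples exercise.
* **Youden's J** threshold: candidates are the unique observed scores, a
  score >= t is called positive, and J is maximised in exact integer
  arithmetic (`tp*N + tn*P`), so ties are broken deterministically toward
  the smallest threshold (which favours sensitivity).

## Survival evaluation

Follow-up is administratively censored at 10 years; events exactly at
the horizon count as events ("within 10 years").  Concordance uses
Harrell's C with an explicit pair rule: a pair is comparable iff the
strictly earlier time carries an event; all equal-time pairs are
excluded (for equal-time double events this is required; mixed
equal-time pairs are excluded for symmetry); predictor ties earn half
credit.  Two predictors of the same outcomes are compared with a
leave-one-subject-out jackknife of the C difference (each replicate is
an O(1) update of the pair sums), referred to the standard normal.  The
estimator family has published variants; the validation surface here is
agreement with a paired-bootstrap oracle and correct type-I error on
null cohorts, not digit-level equality with any one package.

The univariable Cox model maximises the Breslow partial likelihood by
Newton-Raphson (start 0, tolerance 1e-8 on the score, max 50
iterations); Efron tie handling would be a straightforward extension.
Monotone likelihood (perfect separation) is reported as a flagged
non-converged fit, detected by a scale-normalised coefficient or
standard error blowing up.  Log-rank and Kaplan-Meier (reported as
cumulative recurrence, 1 - KM) are delegated to lifelines; the Cox
fit is cross-checked against lifelines in the tests but never delegated,
and C-index is computed in-package because the pair rule above differs
from lifelines' tie conventions.

## Perturbation interpretability

Necessity: remove all patches intersecting the region mask and compare
predictions on slides the model originally called positive with softmax
probability strictly greater than 0.5.  Sufficiency: keep only the
masked region (slides with empty masks are excluded and counted).
Effects are summarised by the per-slide prediction differences with a
two-sided paired t-test and paired Cohen's d (mean/sd with n-1
denominator; zero-variance deltas are flagged undefined rather than
given a d).

The greedy sufficiency search inserts donor patches into a recipient
bag one at a time, always keeping the patch that maximises the
prediction (ties to the lowest donor index), stopping when the
prediction reaches the high-risk cutoff, when a quarter of the donor's
patches are used (floor, at least one), or — by default — when the best
candidate no longer increases the prediction.  The third rule guards
against pathological loops when every insertion hurts; disabling it
(`stop_on_no_improvement=False`) restores the two-rule behaviour.
Because the head is permutation-invariant, insertion is implemented by
appending the feature vector; export coordinates are assigned on a
synthetic grid appended below the recipient slide.

## Synthetic cohorts

Real cohorts of this kind are access-controlled, so the generator
produces cohorts with the statistical structure the pipeline assumes,
and the tests quantify recovery of known ground truth:

* Latent score r ~ Normal(40, 30) truncated to [-20, 90].  These values
  were chosen once so the three risk bins receive ~18/49/33% of
  participants, matching the development population the pipeline
  emulates.
* One cohort-level unit direction u (the "encoder geometry"); tumor-mask
  patches have mean `beta * r * u` (mu0 = 0), all patches carry
  isotropic Normal(0, sigma^2) noise.  Defaults beta = 0.05, sigma = 1;
  the strong-signal preset beta = 0.2 is the planted condition used by
  the recovery checks.  A single global direction keeps brute-force
  recovery oracles trivial.
* Recurrence: T ~ Exponential(rate = lambda0 * exp(gamma * r)) with
  lambda0 = 0.0025/yr and gamma = 0.03 per score unit, censored at 10
  years — about 13% of participants recur within the horizon, and
  proportional hazards holds by construction so the Cox stage has a
  recoverable truth.  ~65% of participants are flagged ER+/HER2-
  eligible.
* One slide per participant by default; `multi_slide_fraction` gives a
  fraction of participants two slides for leakage tests.  The null
  generator permutes the score block against the bags and the survival
  block against the scores, destroying every association while
  preserving marginals — the calibration fixture for type-I error.

What the generator does **not** emulate: encoder-specific embedding
geometry (signals live on one linear direction, real encoders are
nonlinear and anisotropic), spatial correlation between neighbouring
patches, staining/batch effects, treatment heterogeneity, and
competing risks.  Passing recovery tests therefore demonstrates that the
pipeline is correct and well-calibrated, not that any particular
encoder performs well on real slides.

## Problem sizes and numerical choices

Test and acceptance runs use deliberately scaled problem sizes chosen as
the package's own defaults for synthetic validation: cohorts of n = 200
participants with d = 32 embeddings and 32-64 patches per slide for
recovery checks, a quarter-scale head (L = 128, D = 64), n = 500 for
Cox parameter recovery, and 500 Monte-Carlo replicates for calibration
(assessed against exact binomial bounds on a 5% rejection rate).
Attention normalisation is checked to 1e-6; softmax and sigmoid use
max-shifted / branch-stable forms; the Youden and greedy tie rules are
exact integer / index comparisons.  Degenerate inputs (single-class
labels, constant predictors, no comparable pairs, empty masks, zero
score variance) raise or flag rather than silently returning numbers.

## Known limitations

* No GPU path; the NumPy head is sized for desk-scale cohorts, not
  thousands-of-patch gigapixel bags with 1536-d embeddings.
* Breslow ties only in Cox; no multivariable/adjusted models, competing
  risks, or proportionality diagnostics.
* The correlated-C variance estimator is jackknife-based; other
  published variants may differ in later digits.
* Attention GeoJSON export annotates patch rectangles only; it does not
  attempt pixel-space visualisation.
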