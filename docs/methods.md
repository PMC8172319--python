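# Methods

## The model

`vbmnet` estimates three phenotypes — age (regression), gender and
diagnostic status (binary classification) — from a pair of co-registered 3-D
tissue-density volumes per subject: gray matter (GM) and white matter (WM)
as produced by a voxel-based-morphometry (VBM) pipeline (segmentation,
template alignment, Jacobian modulation, smoothing).  The two tissues enter
as channels of a single input tensor `(X, Y, Z, 2)`; in-brain voxels carry
tissue probability in [0, 1] and background voxels are set to exactly −1, a
deliberate offset that separates background from low-but-real tissue
probability.

The estimator is one shared 3-D convolutional body with three task heads
(multitask learning).  Each body block is batch-norm → 3×3×3 convolution
(ReLU) → 3×3×3 max-pool with stride 2, so every block halves each spatial
dimension; after the last block: flatten → dropout → dense (ReLU).  Each
head is dense(1) → batch-norm → output, with a sigmoid on the
classification heads and a linear age output.  Batch norm is placed *before*
the layer it feeds, including a batch-norm on the raw input.  All conv and
dense kernels carry an L2 penalty (coefficient 1×10⁻³ by default).

Training minimizes the joint objective

    L = w1·MSE(age) + w2·BCE(gender) + w3·BCE(diagnosis),

each term a batch mean, with untuned unit weights `w1 = w2 = w3 = 1`.
Because the age MSE is on the scale of squared years while the BCE terms are
order one, optimization is biased toward the age task; the classification
heads catch up once the shared features stabilize.  This asymmetry is a
property of the untuned objective and is visible in the training histories.
Probabilities are clamped at ε = 1×10⁻⁷ before the logarithm.

The optimizer is Adam (learning rate 1×10⁻³, moment decays 0.9/0.999 by
default) with minibatches shuffled per epoch from an epoch-derived seed and
no class balancing.  After every epoch the three per-task validation losses
(MSE, BCE, BCE) are computed; whenever a task's loss sets a new minimum that
task's full model state is checkpointed, so one training session yields
*three* model versions.  Training stops when no task has improved for
`patience` consecutive epochs (global counter; a per-task variant is
available behind a flag) or at `max_epochs`.  "Improvement" is a strict
decrease with min-delta 0.

### Implementation

No deep-learning framework is used: the network, its backward pass, Adam,
batch-norm, max-pool and dropout are implemented in NumPy, with the
convolution and pooling inner loops numba-compiled (`vbmnet.nn._kernels`).
Direct-loop kernels keep the working set in cache and outperform im2col/BLAS
formulations several-fold at these channel widths on one CPU core.  The
backward pass is verified against central finite differences (parameter and
input gradients), and the input-gradient path doubles as the attribution
engine.  Everything is float32; batch-norm in inference mode is a fixed
affine map, which keeps single-example forward/backward passes (needed for
attribution) well defined.

Gradient-w.r.t.-input of the convolution reuses the forward kernel on the
padded output gradient with spatially flipped, channel-transposed weights
(the full-correlation identity).  Max-pool ties resolve to the first offset
in the flat window order, matching a flat argmax.

## Cross-validation protocol

Subjects are stratified by diagnostic status, shuffled once with the run
seed, and dealt into k partitions (per-class partition sizes differ by at
most one).  In round r, partition r is the test set; walking the remaining
partitions cyclically from r+1, the first k−2 are training and the last —
partition (r−1) mod k — is validation.  Each subject is tested exactly once.
Test sets are never touched until training finishes (asserted in tests via
an access-guarded sample mapping).

Classification operating points are chosen on *validation* scores: among the
midpoints between consecutive distinct scores (plus one candidate below the
minimum and one above the maximum — a finite set exhaustive over achievable
confusion tables), the threshold maximizing the harmonic mean of sensitivity
and specificity is selected (ties → lowest threshold) and applied unchanged
to test scores with the rule "positive if score ≥ threshold".  Reported
metrics: MAE, Pearson r with its exact-t two-sided p-value (n−2 df), and
prediction R² (1 − SS_res/SS_tot against the evaluation-set mean, possibly
negative) for age; precision, recall, F1 and AUC-ROC for the classification
tasks, with per-fold rows and mean ± SD aggregates.  Cross-fold model
selection takes, per task, the fold checkpoint with the lowest task
validation loss (ties → lowest fold index).

A confound check reports how much of gender/age is carried by total brain
volume alone: per subject, either the count of voxels with positive density
(default) or their density sum (`mode="sum"`), scored by AUC against gender
and Pearson r against age.  The synthetic benchmark uses the density-sum
mode because its cohorts live on a fixed template mask (emulating modulated
VBM output), making the voxel count constant by construction.

## SmoothGrad attribution and ROI ranking

For one example and one task: over `n_samples` (default 5) Gaussian
perturbations of the input with standard deviation `noise_level` (default
0.20) × (max − min of the example's *in-brain* values), compute the gradient
of that task's (post-activation) output w.r.t. the input with the other two
heads excluded from the gradient target, take absolute values, collapse the
two tissue channels by voxelwise mean (max behind a flag), and average.
Background voxels are zeroed after, not before, the gradient computation.
Noise is applied to all voxels; the reference range deliberately excludes
the −1 background so the marker does not inflate the noise scale.

Aggregation across the cross-validation: per fold, average the maps of that
fold's test examples; min–max normalize each fold map over in-brain voxels;
average the normalized maps across folds.  ROI ranking intersects the
aggregate map with an integer atlas and scores each ROI by its *mean*
attention (sum behind a flag, which would favour large ROIs), sorted
descending with ties toward the lower ROI id.  A nearest-neighbour atlas
resampler is provided as a stand-in for proper affine-aware resampling and
assumes matching fields of view.

## The synthetic cohort generator

The generator emulates the *outputs* of a VBM pipeline, not the pipeline
itself.  An ellipsoidal "brain" (semi-axes 40% of each grid extent) is
partitioned into contiguous ROIs as Voronoi cells of random in-brain seeds.
Per subject: GM/WM baselines of 0.6/0.5 inside the brain; injected effects
add density inside chosen ROIs (age: `magnitude × (age − mid-range age)`;
gender/diagnosis: `magnitude` for the positive class); the volume is
Gaussian-smoothed (σ = 1.5 voxels), perturbed with i.i.d. noise
(σ = 0.05), clipped to [0, 1], and background is set to −1.  Ages are
uniform on 6–20 years; gender is Bernoulli(0.5) and diagnosis
Bernoulli(0.4), approximating the demographic envelope of the paediatric
cohorts this workflow targets.  Baselines and effect scales were chosen so
that effects of 0.01–0.05 density units neither clip nor vanish under the
noise.  Each subject draws from an RNG stream derived from
(seed, subject index), so cohorts are bit-reproducible under partial
regeneration.

What the generator does *not* emulate: scanner/site effects, cortical
folding geometry, spatially correlated segmentation error, per-subject mask
variation, or any empirical age distribution.  Passing the recovery studies
therefore shows that the workflow's machinery (training, checkpointing,
selection, thresholding, attribution) detects and localises known signal at
realistic amplitudes — not that the architecture reaches any particular
accuracy on real scans.

## The benchmark (recovery and null studies)

`vbmnet.benchmark` fixes the package's reference experiment, scaled to run
on one CPU core:

- grid 32³, n = 400 subjects, 8-ROI atlas (atlas seed fixed: the ROI
  geometry is study design, not a random variable);
- injected ground truth: age slope −0.02 density/yr (GM, ROI 2) and gender
  offset +0.04 (GM, ROI 5);
- model: 2 blocks with filters (4, 8), dense 32, dropout 0.1;
- training: k = 3 folds, Adam at 5×10⁻³, batch 16, ≤ 26 epochs,
  patience 8;
- attribution: 16 test examples per fold, SmoothGrad defaults.

The small-problem schedule differs from the full-scale defaults
(lr 1×10⁻³, batch 32, ≤ 1000 epochs, patience 75, dropout 0.5) because a
133-subject training split gives only ~9 optimizer steps per epoch: the
learning rate is raised accordingly, and heavy dropout on the shrunken dense
bottleneck merely prolongs the initial plateau without a generalization
benefit at these sizes.  Two further small-scale aids are exposed as
configuration: the age head's batch-norm shift is initialized to the
training-set mean age (the model starts at the mean predictor instead of
spending steps learning the intercept), and an optional global
gradient-norm clip is available for aggressive learning rates (off by
default).

The recovery study reports the best-age checkpoint's test MAE against the
predict-the-mean baseline, the best-gender checkpoint's test AUC, and the
SmoothGrad rank of each injected ROI.  The null study runs the same
pipeline on an effect-free cohort, where test metrics must sit at chance
and the confound check must find nothing.

## Numerical choices and degenerate inputs

- Pad/trim to a cube is centred with the extra voxel on the high side for
  odd remainders; trimming refuses to remove any non-background voxel.
- Zero target variance makes Pearson r and R² undefined: reported as NaN
  with an explicit flag, never silently zeroed.  Constant predictions leave
  R² defined (exactly 0 for the evaluation-set mean).
- Degenerate (all-equal) validation scores: threshold selection warns and
  returns that value.
- Empty ROIs are skipped with a warning during ranking; flat attention maps
  normalize to zero with a warning.
- Sample records are a versioned length-prefixed binary framing (magic
  `VBMREC`, u16 version, then per record: u32 header length, JSON header
  with phenotype/shape/byte count, raw float32 payload); truncation raises
  an error naming the offending record index.
- Serialized label encoding everywhere: gender 1 = female, diagnosis
  1 = disorder (the positive classes), stated in every report header.

## Known limitations

- Batch-norm in training mode couples examples; exact reproducibility is
  guaranteed for a fixed batch size and seed on CPU, not across batch-size
  changes.
- The head biases that feed a batch-norm are redundant parameters (the norm
  cancels them); they are kept for architectural fidelity.
- The atlas resampler ignores affines; supplying a real parcellation on a
  different grid requires resampling upstream for exact geometry.
- With three noisy validation curves, the global patience counter rarely
  triggers before `max_epochs` at benchmark scale; early stopping is
  exercised primarily through the scripted-loop tests and the full-scale
  defaults.
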