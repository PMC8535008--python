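# Methods

## Problem setting

A hyperspectral camera images resected gastrointestinal tissue at 100
reflectance bands between 500 and 1000 nm. Each pixel carries a spectrum
shaped by hemoglobin absorption (~540/575 nm), fat (~740 nm) and water
(~980 nm) content, which differ between cancer and healthy mucosa. The
task is binary per-pixel classification — cancer (positive) versus any
healthy mucosa class (negative) — with generalization measured across
patients: one hypercube per patient, leave-one-patient-out
cross-validation (LOPOCV), and no pixel of the held-out patient ever in
that fold's training or balancing pool.

## Preprocessing

Every pixel spectrum is standard-normal-variate (SNV) normalized:
`x ↦ (x − mean(x)) / sd(x)` with the population standard deviation
(divide by L). Either sd convention satisfies the properties that matter
(affine invariance, idempotence); the population convention is fixed and
tagged in the cube header so a model never scores a cube whose
normalization differs from its training. Constant-spectrum pixels have no
SNV transform; they are flagged, excluded from training, and marked
invalid at inference.

Patch extraction takes the 5×5×L sub-volume centered on each annotated
pixel, zero-filling positions outside the raster (border handling is not
dictated by the protocol; zero padding after SNV is the simplest choice
that keeps the patch count equal to the annotated-pixel count).

Class imbalance is handled by random downsampling per training fold: all
classes are reduced to S, the least-represented class's count, uniformly
without replacement. Balancing once globally would leak the held-out
patient's class proportions into training, so it is done per fold.

## Models

Classical models classify the SNV spectrum of a single pixel:
RBF-SVM and linear SVM (C = 1, γ = 1/(L·var)), a two-hidden-layer
(100, 50) tanh MLP fitted with L-BFGS on log-loss, a 100-tree random
forest, and logistic regression. Undocumented hyperparameters are fixed at
these defaults and recorded in the run metadata; reproducibility is
preferred over per-dataset tuning. SVM scores are mapped to [0, 1] by a
logistic squashing of the decision function — deterministic and
rank-preserving, so ROC-AUC and threshold sweeps are unaffected (Platt
scaling would add a stochastic internal cross-validation for no benefit
here).

The 3-D CNN classifies the 5×5×100 patch around each pixel. The layer
plan (spectral axis = convolution depth axis) is

| layer | kernel | stride | dilation | padding | output |
|---|---|---|---|---|---|
| conv 1→20 | 3×3×3 | 1 | 1 | (1,0,0) | 20×100×3×3 |
| conv 20→20 | 3×1×1 | (2,1,1) | (3,1,1) | (1,0,0) | 20×48×3×3 |
| conv 20→35 | 3×3×3 | 1 | 1 | (1,0,0) | 35×48×1×1 |
| conv 35→35 | 3×1×1 | (2,1,1) | 1 | 0 | 35×23×1×1 |
| conv 35→35 | 3×1×1 | 1 | 1 | (1,0,0) | 35×23×1×1 |
| conv 35→35 | 2×1×1 | 1 | (2,1,1) | (1,0,0) | 35×23×1×1 |
| fc 805→2 | | | | | 2 logits |

with ReLU after every convolution: 30,620 convolutional plus 1,612 fully
connected parameters, 32,232 in total. The architecture family
under-determines the exact padding/stride conventions; this plan is
pinned, and conformance is defined by the weight-count checksum together
with the 5×5×100 → 2 input/output contract (`build_3dcnn` refuses a
default configuration whose count deviates). Notably, the second pooling
convolution must be unpadded to reach the checksum; padding it gives
32,302.

Training: Kaiming-initialized weights, zero biases, SGD with learning
rate 0.01 and weight decay 5·10⁻⁴, class-weighted softmax cross-entropy
with inverse-frequency weights (all ones after balancing, so the weighted
loss then equals the unweighted one). Each epoch draws **one** batch of
3000 patches uniformly without replacement from the training pool — the
literal reading of the training recipe — with a smaller single batch when
the pool is smaller. 10% of training pixels form a validation set; the
weights of the epoch with the lowest validation loss are kept. The split
is over pixels, not patients, reproducing the recipe as specified; the
resulting optimism affects only epoch selection, never the held-out-patient
metrics.

The network is implemented directly in numpy: each 3-D convolution is an
im2col gather (a strided view materialized once) followed by a single
BLAS matmul, with the exactly corresponding backward pass; gradients are
verified against central finite differences in float64 in the test suite.
Layers compute in float32 by default. Training is bit-reproducible for a
fixed seed on one machine.

## Evaluation

ROC-AUC is computed by the tie-aware rank statistic (Mann–Whitney form),
which the tests verify against a brute-force pair-counting oracle and an
independent library implementation. MCC uses the convention 0 when any
factor under the root is zero; DICE uses 1 for the 0/0 case (no positives
anywhere, none predicted). Patients without cancer pixels have no ROC-AUC
(rendered "/"), are excluded from mean-AUC rows and paired t-tests, and
enter MCC/DICE as all-negative images.

Decision thresholds come from a fixed grid of 201 evenly spaced values
{0, 0.005, …, 1}; ties break toward the smallest threshold for
determinism. The patient-generic policy picks the single grid value
maximizing the unweighted mean metric across all test images — an oracle
policy, as printed results in this literature use it; the
patient-specific policy maximizes per image and therefore dominates it
patient by patient (a property the suite asserts on every synthetic
cohort it evaluates).

Paired two-tailed t-tests use the sample standard deviation of
per-patient differences and Student's t with n−1 degrees of freedom;
aggregate rows are arithmetic mean ± sample sd. Recomputing p-values from
values rounded to two decimals reproduces published comparisons to about
±0.001; tests assert ±0.005.

## Synthetic cohorts

The generator emulates the features of the clinical data the pipeline
actually depends on:

- **Cohort layout** — 12 colon patients with the 2nd and 6th cancer-free,
  10 esophagogastric patients whose healthy area splits between stomach
  and esophagus; one cube per patient.
- **Class spectra** — smooth baseline + slope + Gaussian features
  (hemoglobin dips at 540/575 nm; the cancer difference profile adds fat
  (740 nm), water (980 nm) and a perfusion shift at 560 nm), scaled by a
  separation parameter Δ. Δ = 0 makes cancer and healthy curves
  identical (null cohort); Δ = 1 is the study-condition default.
- **Nuisance structure** — per-patient additive offset (sd 0.05),
  log-normal gain (sd 0.15) and optional spectral tilt (sd 0.02); smooth
  within-class spectral jitter (pointwise sd 0.04, correlation length
  ~10 bands); independent pixel noise (sd 0.02). With tilt, jitter and
  noise at zero, SNV removes the patient effects exactly — the formal
  version of the scatter-removal rationale, asserted to <10⁻⁶ post-SNV
  spread.
- **Geometry** — one elliptical ROI-style annotated region covering ~35%
  of the image (clinical masks annotate regions of interest, not every
  pixel), with 1–3 contiguous elliptical tumor blobs totalling ~9% of
  annotated pixels (the clinical cohorts print 8.3% and 9.4% cancer).
  Tumor shape beyond contiguity is immaterial to 5×5-patch
  classification, so ellipses suffice.

Defaults use 64×64 images rather than 640×480 so a full 22-fold LOPOCV
runs in minutes on one CPU; the spatial and spectral statistics are
unchanged by the crop, and full size is available through the
configuration. The `separable_config` variant (Δ = 2, noise 0.01, jitter
0.02, no tilt) defines the recovery benchmark: any sound pipeline should
reach mean AUC ≥ 0.95 there, and chance level (0.4–0.6) on Δ = 0.
End-to-end test runs train the CNN with 5–20 epochs at batch 512 — the
separable benchmark converges within a handful of epochs, and the
best-validation-epoch rule keeps extra epochs harmless.

What passing these tests shows: the pipeline is leak-free, the metrics
and threshold policies are correct, SNV does what it claims, and the
classifiers can exploit exactly the kind of structure the real task
presents. What it does not show: performance on real tissue, whose
intra-class variability is only known graphically and whose specular
highlights, camera noise spectra and depth effects the generator
deliberately omits. No synthetic number claims to reproduce a clinical
result.

## Numerical and design notes

- Mask palette codes are fixed (0 unannotated, 1 healthy colon, 2
  stomach, 3 esophagus, 4 cancer); colors follow the usual annotation
  scheme (purple/blue/green/red).
- Cohort composition means are unweighted per-patient means, which is how
  the published cohort tables aggregate.
- Coordinates are row-major, 0-based, (row, col) everywhere.
- Unannotated pixels (code 0) are excluded from everything: training,
  balancing, scoring validity and metrics.
- `read_cube`/`write_cube` speak plain ENVI (BSQ, float32, little-endian)
  with the wavelength list and the normalization tag in the header;
  proprietary camera dialects are out of scope, and white/dark reference
  calibration is assumed already applied upstream.
- The multi-class (4-way tissue) problem is out of scope; labels are
  binarized (healthy classes → negative, cancer → positive) as the
  evaluated task requires.

## Known limitations

- One batch per epoch means an "epoch" sees at most 3000 samples; an
  option for full-pool epochs exists in spirit via larger batch sizes but
  the literal recipe is the default.
- The numpy CNN targets desk-scale cohorts; it has no GPU path, no
  augmentation, and no deeper variants.
- MLP convergence with L-BFGS on small balanced pools can hit its
  iteration cap (capped at 300 iterations by default); the cap is a
  recorded hyperparameter.
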