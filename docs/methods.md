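# Methods

This note describes the models and procedures `v1enc` implements, the
choices made where the design was genuinely open, and what the bundled
simulator does and does not emulate.

## Problem setting

The package predicts single-neuron responses in mouse primary visual cortex
(V1) to natural grayscale images. Responses are ΔF/F calcium signals
accumulated into one nonnegative value per neuron per trial. A dataset
(one subject) provides per-trial 144×256 stimuli, response vectors, per-
neuron anatomical coordinates, dataset statistics (image mean Ī and
standard deviation s_I over the train+validation pool, per-neuron response
scale s_r), split labels (train / validation / live_test / final_test), and
stimulus identities that group the ~10 repeats of each test image.

## Model inputs

Each trial becomes a 6-channel tensor:

1. `I_norm = (I − Ī)/s_I` — the dataset-normalized image;
2. `I_center = I_norm − mean(I_norm)` — additionally centered by its own
   per-image mean;
3–6. constant planes broadcasting the merged object bounding box in
   normalized center-size form (x, y, w, h).

Object detections are an external input (a CSV of per-image boxes from any
detector). All boxes of an image are merged into one covering box by
corner-wise min/max; `pad_frac` defaults to 0 because the covering-box rule
itself contains no padding term, and is configurable where a margin is
wanted. Images with no detections use the whole-image fallback box
(0.5, 0.5, 1, 1) so the object channels stay defined; these cases are
logged. Corner coordinates use a bottom-left origin; the center-size form
is insensitive to that convention for w/h and symmetric for centers.

Targets are standardized per neuron, `r/s_r`. Anatomical coordinates are
normalized per subject: each axis is centered by its mean and divided by
its post-centering absolute maximum, landing in [−1, 1]. The per-image
(not dataset-level) mean is used in `I_center`; the per-subject (not
global) normalization is used for coordinates because readouts are
per-subject.

## Encoder

A shared convolutional core feeds per-subject Gaussian readouts.

**Core.** Five convolutional layers with widths 32, 128, 256, 256, 256;
each followed by batch normalization and ELU. Layer 1 uses a 4×4 kernel at
stride 4 (144×256 → 36×64). Layers 2–5 preserve the spatial shape; layers
3–5 are depth-separable (depthwise k×k then pointwise 1×1, with BN+ELU
after the pair). The hidden kernel size is not pinned down by the
architecture's published description; we use 3×3 with symmetric padding,
the smallest shape-preserving choice and the standard one in this model
family. The core is size-agnostic: feeding 36×64 images yields 9×16
feature maps, which is how the reduced-resolution test configurations work
without touching the architecture.

**Gaussian readout.** Neuron i reads the 256-channel feature vector at a
single spatial position. Its receptive-field center μ_i ∈ (−1,1)² is
produced from the neuron's normalized 3-D coordinates by a position
network (3 → 30 → 2; ELU hidden activation, Tanh output). During training
the sampling position is μ_i + Σ_i ε with ε ~ N(0, I₂) and Σ_i a per-neuron
2×2 matrix, clamped to [−1,1]²; at evaluation the position is μ_i exactly.
Σ is a full unconstrained matrix (it acts linearly on ε, so signs are
irrelevant) learned by gradient descent like every other parameter — the
empirical shrinking of the sampling spread over training is emergent, not
scheduled. The feature vector is bilinearly interpolated under the
align-corners convention ((−1,−1) maps to the outermost feature-cell
centers) — this convention must be fixed for checkpoints to be
reproducible, and the clamp at the frame boundary blocks the position
gradient there. The per-neuron prediction is `ELU(w·f + b) + 1 > 0`, the
positivity the Poisson loss requires.

The numerical kernels (strided/padded convolution via im2col + BLAS,
depthwise convolution, batch normalization with running statistics, Adam,
and the backward passes including the bilinear-sampling position gradient)
are implemented in NumPy in `v1enc._nn`, following the layer semantics and
default hyperparameters (ELU α=1, BN ε=1e−5/momentum 0.1, Xavier-normal
fan-in+fan-out initialization) of mainstream deep-learning frameworks so
published hyperparameters transfer unchanged.

## Training

Adam minimizes the Poisson loss `(1/m) Σ_i (o_i − r_i log o_i)` at batch
size 128. Initialization: Xavier-normal weights, zero biases, readout
feature weights 1/256, Σ ~ U(−0.1, 0.1). Batches are homogeneous in
subject (per-subject readouts fix the neuron dimension within a batch) and
interleaved round-robin across subjects within an epoch. One fresh
position sample is drawn per neuron per training step, shared across the
batch.

After each epoch, eval-mode predictions on the validation trials give a
per-neuron Pearson correlation with the standardized responses; the
scheduling metric is the mean over neurons pooled across subjects. A
plateau scheduler starts at 0.009 and multiplies the rate by 0.3 (floored
at 1e−4) when the improvement over the best value stays below 1e−6 for
more than five consecutive epochs (absolute threshold, matching the
ReduceLROnPlateau convention). Training stops at the fourth decay event or
at 200 epochs, whichever comes first, so a never-improving run visits
0.009 → 0.0027 → 0.00081 → 0.000243 and stops. The parameters with the
best validation correlation are kept, batch-norm running statistics
included (eval mode always uses the statistics frozen at that checkpoint).
No gradient clipping or weight decay is applied. The recorded best
checkpoint tracks the strict maximum of the validation metric, which can
differ from the scheduler's thresholded bookkeeping by less than the
threshold.

**Ensembling.** The non-test pool is resplit k times: each split draws a
fresh validation set of the original validation size (split k and its
member's training randomness derive from `seed + k`). Members are trained
independently and their eval-mode predictions averaged elementwise;
"ensemble N" means the mean of the first N members.

## Evaluation

For repeated test stimuli with responses r_ij (image i, repeat j) and one
prediction o_i per image:

* **Correlation to Average** R̄: per-neuron Pearson correlation between
  {o_i} and the repeat means {r̄_i}, averaged over neurons.
* **FEV** = (Var[r] − σ_ε²)/Var[r], with Var[r] the variance over all
  trials and σ_ε² the mean within-image variance — the stimulus-driven
  (explainable) share of response variance.
* **FEVE** = 1 − (MSE − σ_ε²)/(Var[r] − σ_ε²) — the share of explainable
  variance the model captures.

Population (divide-by-N) variances are used throughout so the noiseless
case is exact (FEV = FEVE = 1); a `ddof` switch enables the sample
convention for comparison with other codebases. Undefined per-neuron
values (zero variance, non-positive explainable variance) are reported as
missing, never coerced to zero, because low-FEV neurons can take large
negative FEVE values that would dominate a population mean; aggregates
report inclusion counts, and the aggregate FEVE is restricted to neurons
with FEV > 0.15. A transposed call provides the per-image correlation
across neurons.

## Analyses

**Image properties.** Brightness = mean intensity; contrast = population
standard deviation; complexity = mean spatial information, the pixelwise
magnitude √(s_v² + s_h²) of the standard 3×3 Sobel pair. Border handling is
reflect padding (the operator, not the border mode, is what defines the
measure).

**Cortical grids.** Per-neuron value vectors (typically predictions on K
probe images) are interpolated onto a regular (25, 25, 10) grid — 6250
cells — over normalized coordinates: X and Y are 25 points in [−1, 1]; Z
spans the observed depth range (pass the joint range when several subjects
are gridded together). Interpolation is piecewise-linear on the Delaunay
simplices; cells outside the convex hull are missing.

**Distance–similarity curves.** Non-missing cells (shared between both
grids in the across-brain case) are sorted by Euclidean distance to the
bottom-left-most remaining cell, a cell×cell correlation matrix of the
K-vectors is formed (within one grid, or between matched cells of two
grids), and the k-th off-diagonal is averaged with missing-aware means.
The offset k is a rank distance — the literal order after sorting — not a
Euclidean bin. The rank-distance reading is meaningful when the response
field drifts along a spatial gradient; for sensitivity checks,
`binned_distance_similarity` provides the alternative that groups all cell
pairs by true Euclidean distance and is direction-agnostic. Sorting uses squared
distances so exact geometric ties stay exact, with a stable sort fixing
tie order. Reference-cell heatmaps correlate every cell against one
reference cell and project by a missing-aware mean along the orthogonal
axis (per brain first, then across brains or brain pairs).

**Retinotopy.** Per-neuron μ from each ensemble member's position network,
averaged over members, tabulated against anatomical coordinates.

**Artificial receptive fields.** Standard-normal white-noise images (in
normalized-intensity units; the object channels take the fallback box,
since noise contains no objects) are pushed through the model and
prediction-weighted averaged: aRF = Σ_t p_t x_t / Σ_t p_t, normalized by
the sum of weights. This is the model analogue of a spike-triggered
average and is unbiased up to scale for LN neurons. A rotated 2-D Gaussian
(amplitude, center, widths, orientation, offset) is fit by least squares
with moment-based initialization on the dominant-polarity side; the center
is constrained to the image and non-convergence is flagged in the result
rather than raised.

## Synthetic V1 simulator

The simulator makes every component testable with known ground truth. Each
neuron is a linear-nonlinear unit: a 2-D Gaussian receptive field
(unit mass) applied to the normalized image, a drive gain of 2, ELU+1
rectification — the same output nonlinearity as the readout, so a
correctly specified model can approach FEVE ≈ 1 on noiseless data — and a
positive per-neuron gain (log-normal, σ=0.3). Receptive-field centers are
uniform in (−0.8, 0.8)², widths uniform in 0.10–0.18 of the half-frame
(roughly 15–25% of frame height, the scale of mouse V1 receptive fields
relative to typical stimulus coverage). Cortical (x, y) coordinates follow
the RF centers at 400 units per normalized unit with 15-unit scatter
(retinotopy with rank correlation ≥ 0.95 by construction); z takes ten
discrete imaging depths. Stimuli are Gaussian-blurred white noise (blur
σ = height/24) rescaled to intensity range, giving the spatial correlation
natural images have. Defaults emulate one recording session: 4000 train +
500 validation images, 100 test stimuli × 10 repeats, Gaussian trial noise
σ = 0.4 in response units (median explainable variance fraction ~0.7–0.8,
on the optimistic side of real recordings). Gaussian noise is rectified at
zero to keep responses in nonnegative ΔF/F-like units; this clips ~7% of
trials at the default noise level and biases repeat-based FEV estimates
upward by ~0.03 relative to the unrectified closed form — the tolerance
used when validating the estimator against the closed form. Poisson noise
(5 events per response unit) is available as an alternative.

What the simulator does **not** emulate: natural-image statistics beyond
second order (no objects, so object channels are exercised only through
the fallback box), behavioral state (pupil, running — the package is
stimulus-only by design), non-Poisson noise correlations across neurons,
and surround/orientation structure in receptive fields. Passing the
recovery tests therefore shows the estimator and optimizer are correct and
that retinotopic structure is recoverable — not that real-data accuracy
levels are reproduced.

## Problem sizes used by the tests and the acceptance script

Desk-scale configurations keep the full architecture (channel widths,
readout, loss, schedule) and shrink data: recovery runs use 200 neurons,
2000 training images at 36×64 resolution and up to 20 epochs; ensemble
property checks use 5 members on 64 neurons × 512 images for a few epochs
each (the convexity and ordering properties they verify are
scale-free); aRF recovery uses 100,000 noise frames at 36×64 — at that
frame size the Monte-Carlo error leaves a ground-truth correlation well
above 0.9, whereas the full 144×256 frame would need several-fold more
frames for the same fidelity. The acceptance script trains a 3-member
ensemble (12/5/5 epochs) on 150 neurons × 1500 images and reports
validation and test correlation, FEVE, RF-center recovery, ensemble gain,
grid statistics and aRF recovery.

## Known limitations

* CPU-only NumPy training: practical at desk scale; full-resolution,
  seven-subject, 200-epoch training is out of reach without a GPU stack.
* The depth (z) axis is gridded over the observed range; with few discrete
  imaging depths, linear interpolation between depths is a coarse model of
  laminar structure.
* ΔF/F extraction and boxcar accumulation from raw calcium traces are out
  of scope — responses enter pre-accumulated.
* The object detector is not part of the package; detection quality enters
  only through the provided boxes.
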