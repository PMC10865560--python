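# Methods

`perisinus` segments the peri-sinus space — parasagittal dural space
(PSD), intravenous arachnoid granulations (AG), and the superior
sagittal sinus lumen — from 3D T2-weighted-like volumes, and models the
resulting volumetry across the lifespan. This note documents the model,
the numerical choices, and what the synthetic experiments do and do not
demonstrate.

## Segmentation model

The pipeline is a cascade:

1. **Preprocessing.** Intensities are corrected for a smooth
   multiplicative bias field; the volume is aligned to a template grid.
2. **FCNN_mask.** A 3D U-Net (single input channel, two output
   classes) delineates the peri-sinus complex (lumen + PSD + AG,
   trained against the binarized delineation MD > 0) from parenchyma
   and subarachnoid CSF, using cross entropy.
3. **EM pre-labeling.** Inside the predicted mask, a two-component
   Gaussian mixture is fit to the intensities by EM; the maximum a
   posteriori label splits the hypointense lumen (lower-mean component)
   from the intermediate-intensity PSD (AGs share the PSD label at this
   stage). The "optimal threshold" is the MAP decision boundary itself.
4. **FCNN_labels.** A second U-Net with two input channels (z-scored
   image + pre-label map) and four output classes (background, lumen,
   PSD, AG) produces the final per-voxel argmax labeling, trained with
   generalized Dice loss.
5. **Post-processing.** Morphological closing of the labeled complex
   with non-contiguous fragments removed, a 30 mm midline crop, a
   frontal/parietal/occipital subdivision by two template-space
   anterior–posterior planes, and nearest-neighbour back-resampling to
   native space.

Both networks share the architecture: per level two blocks of
(batch norm → 3×3×3 conv → ReLU), 2×2×2 max pooling between levels,
transposed-convolution upsampling (kernel/stride 2×2×2) with skip
concatenation, and a 1×1×1 conv + softmax head. Depth (3 levels) and
width (16 base channels) are configurable; the defaults train on a
single CPU at phantom scale.

Patches are 96×64×64 voxels — in this package's grid convention
(right–left, anterior–posterior, foot–head) that is shape (64, 96, 64):
96 voxels anterior–posterior along the sinus, 64 along each other axis.
Training patches are sampled with probability proportional to the
peri-sinus probabilistic atlas (the voxel-wise mean of aligned binary
delineations); at test time a sliding grid with 50% overlap covers the
atlas bounding box dilated by 8 voxels, and overlapping softmax outputs
are averaged with uniform weights (voxels no patch covers get
background probability 1).

### Losses

Cross entropy is averaged over voxels (a constant factor relative to
the summed form; batch-size changes then do not rescale the loss).
Probabilities are clipped at 1e-7 before the log.

The generalized Dice loss is

    L = 1 − 2 (Σ_l w_l Σ_n r_ln p_ln + ε) / (Σ_l w_l Σ_n (r_ln + p_ln) + ε)

with ε = 1e-6 and inverse-volume class weights
`w_l = 1/(Σ_n r_ln)^q`. Both weight exponents in circulation are
implemented: `q = 2` (the canonical generalized-Dice definition, the
library default for `loss_gdl`) and `q = 1`. Classes absent from a
target patch are dropped (their 0/0 weight term is removed). The
pipeline default (`CascadeConfig.weight_power = 1`) uses `q = 1`: with
`q = 2` a single small AG outweighs the lumen and PSD classes by two to
three orders of magnitude, which destabilizes short training runs
(observed as rising loss and collapse of the AG class); `q = 1` keeps
all three foreground classes in the gradient. The choice is recorded in
the run config.

### Training

Adam, default learning rate 1e-4, batch size 2, up to 100 epochs with
optional early stopping (patience 10) when a validation set is given.
Augmentation: random sagittal flips (the right–left axis is the first
grid axis; flips conserve per-class volumes), additive Gaussian noise
with sd drawn uniformly from [0, sd_max] (applied after the per-patch
z-score, sd_max default 0.1), and optional slice-wise CLAHE (8×8 tiles,
clip limit 0.01, off by default). The head bias is initialized at the
log class prior of the training set, so the model starts from the
base-rate prediction instead of spending early steps learning how rare
the foreground is.

The phantom-scale cascade runs (`CascadeConfig`) use a deliberately
compressed schedule, sized so a full train-and-evaluate study completes
in well under half an hour on one CPU: batch size 1, 2 atlas-sampled
patches per scan, one scan held out as a validation split (mirroring a
train/validation protocol; 4 patches), with step caps of 20 + 6 (mask
net) and 30 + 25 + 5 (labels net, see below). Both networks decay the
learning rate from 3e-3 to 1e-3 for a tail phase: at the base rate the
per-class accuracy oscillates between single-sample steps, while the
decayed tail rises smoothly; the labels tail additionally checkpoints
every 5 steps on validation mean per-class Dice and keeps the best
state. The labels warm-up uses median-frequency class weighting
(w_c = median(f)/f_c, the classic balancing recipe): it hands the rare
AG class a first-step gradient instead of the slow, seed-dependent
emergence that unweighted cross entropy shows for a 0.04% class. The
`TrainConfig` default stays at the conservative 1e-4 for users running
longer schedules.

**Why the labels network gets a cross-entropy warm-up.** The softmax
gradient of a Dice-family loss for class c scales with that class's
predicted probability p_c. A class occupying ~0.04% of patch voxels
(a few arachnoid granulations in a 96×64×64 patch) therefore sits in a
stable zero-gradient trap when training starts cold: background
pressure pushes p_AG to zero, after which neither direction receives
gradient. Cross entropy has no such trap — its per-voxel gradient at a
true-AG voxel is p − 1 regardless of p. A related failure affects a
*short* Dice phase started from a half-trained state: while the AG
prediction is still diffuse (low precision), the generalized Dice
objective is genuinely lowered by deleting the class, because the
false-positive mass in its denominator outweighs the true overlap in
its numerator. The labels network therefore trains in phases: a
median-frequency-weighted cross-entropy warm-up (30 steps at 3e-3,
then 25 at 1e-3) that carries every class to a sharp prediction, then
a short generalized-Dice phase (5 steps, learning rate 1e-3) guarded
by step-level validation on *mean per-class Dice*
(the study's evaluation metric, and the standard model-selection
criterion for segmentation networks) — the best-validation state,
including the warm-started one, is restored, so the Dice phase is kept
only where it actually improves segmentation. At this problem scale
the guard frequently selects the warm-started state: the
generalized-Dice optimum with so few optimization steps is degenerate
for the AG class, which is an honest property of the loss at this
scale, not of the implementation.

Everything (network, losses, Adam, backprop) is implemented in NumPy,
float32, channels-last, with convolutions evaluated as one BLAS GEMM
per kernel offset. This keeps the package dependency-light and makes
training bit-reproducible under a fixed seed on a given platform.

### EM mixture

1-D EM with deterministic initialization (component means at the
25th/75th intensity percentiles, equal weights, pooled sd), relative
log-likelihood tolerance 1e-6, max 200 iterations, and component sds
floored at 1e-3 of the intensity range (floored fits are flagged). The
log-likelihood trace is monotone non-decreasing; component semantics
are fixed by mean ordering (lower mean = lumen), never by component
index. Voxels exactly on the decision boundary go to PSD. The mixture
is fit per subject.

## Preprocessing contracts

* **Bias correction** alternates a 1-D k-means tissue model (4 classes)
  with a least-squares polynomial fit (default degree 3, 3 iterations,
  30k-voxel subsample) to the log-residual; the estimated log-field is
  centred so the field has unit geometric mean over the mask. This is a
  smooth-field correction contract, not a reimplementation of N4's
  histogram-sharpening numerics.
* **Registration** ships identity and moment-matching affine
  (translation from intensity centroids, axis-aligned scaling from
  second moments, optional Powell polish on subsampled SSD), plus a
  coarse B-spline free-form refinement (2 mm control spacing, a few
  demons-style gradient steps on SSD). A plug-in hook accepts
  externally computed transforms (e.g. precomputed non-linear warps);
  transforms serialize to JSON so prediction can reuse a training-time
  alignment. Images resample linearly, labels nearest-neighbour.
* **Z-scoring** is per patch over non-padding voxels; a constant patch
  maps to all zeros (sd guard 1e-8) with a warning.

## Post-processing

Closing uses a ball structuring element (default radius 1 voxel) on the
union of non-background classes, computed on a padded domain so the
operation is extensive and idempotent; voxels gained take the nearest
original label, and fragments disconnected from the largest component
drop to background. A second refinement enforces the anatomical
definition of the intravenous AG: a genuine granulation protrudes into
the venous lumen, so an AG component whose labeled (lumen + PSD)
boundary is less than 60% lumen is relabeled as PSD. On phantoms the
two populations are well separated: genuine instances — including
large granulations that touch the vessel wall — stay above ~0.7,
while voxel-scale misclassifications on the PSD–lumen interface sit
near 0.5. Without this rule, one- and two-voxel interface specks
inflate the instance count. AG instances are connected components of the AG
class at 26-connectivity by default (6/18 available) with no minimum
volume floor by default, since granulations of only a few voxels are
real findings. Region subdivision is an exact three-way partition by
world-y planes; a voxel exactly on a plane joins the anterior region.
Boundary planes are fixed template-space coordinates supplied in
configuration (automatic sulcus localization is out of scope); the
phantom generator writes matching planes into its truth table.

## Evaluation harness

DSC, recall and precision are reported as percentages. Conventions:
both-empty comparisons score 100 (a correctly empty prediction is not
penalized); regions with no truth and no predicted voxels anywhere in
the cohort are dropped from tables rather than scored. Volume agreement
is RMS difference plus Pearson r (PSD in cm^3, AG in mm^3; AG count in
occurrences). Cross-validation plans are 60/10/10 over 80 ids, eight
folds; the eight test sets are a random partition of one permutation,
which guarantees every scan is tested exactly once (independent
redraws of the test sets could not cover all 80 ids in practice).

## Lifespan model

Responses (PSD volumes in cm^3; AG total/average/max/min in mm^3 and AG
count) are modeled as

    y ~ spline(age) + sex + spline(age):sex + (1 | source)

where spline(age) is a restricted quadratic basis: intercept, linear
age, and b_j(a) = (a−k_j)₊² − (a−k_K)₊² for j = 1..K−1 — continuous,
C^1, and exactly linear beyond the last knot. Knots default to the
5th/35th/65th/95th age percentiles. Sex is an indicator with female as
reference (the reference choice does not affect predictions). The
source random effect is intercept-only, fit by ML (REML available)
through statsmodels MixedLM; with fewer than two sources, or on a
singular mixed fit, the model degrades to OLS with a warning. AIC is
−2·llf + 2·(p + 2) for the mixed fit; adjusted R² is computed on the
marginal (fixed-effects) predictions. Population curves set the random
effect to zero and carry a delta-method confidence band; predictions
outside the fitted age range warn, because normative curves
extrapolate poorly at the extremes. ICV normalization expresses
volumes as percent of intracranial volume; both raw and normalized
responses are supported.

## Synthetic phantoms and cohorts

The phantom emulates the T2 contrast ordering of the peri-sinus region:
hyperintense CSF (mean 100), intermediate PSD and AG (70), parenchyma
(45), and hypointense lumen (25) and dura (20), on a 96³ grid at 0.8 mm
isotropic spacing. Geometry: a venous tube along the
anterior–posterior axis near the superior margin (radius ~3.2 mm with a
mild sinusoidal profile), lateral PSD wings (thickness ~2.8 mm), a
1.6 mm dura band labeled background (the four-class scheme has no dura
label), a 4 mm CSF sheath, and ellipsoidal AGs centred inside the lumen
(validated: a centre outside the lumen is a spec error). The image is
class means × exp(low-order polynomial bias, peak log-magnitude
log(1+amplitude), default amplitude 0.1) + Gaussian noise (default sd
5, i.e. one-ninth of the lumen–PSD contrast gap). Per-subject geometry
jitter (`PhantomSpec.randomized`) varies radius, wing thickness,
tube height and AG count (2–4).

Cohorts draw age uniformly on [5, 100], sex with male fraction 0.46,
and subjects uniformly across three sources whose random intercepts are
N(0, 0.3²) cm³. Default growth models give PSD ≈ 6–7.5 cm³ by age 70
with a faster male increase, AG totals rising ~0.64 mm³/yr, and AG
counts Poisson with an age-increasing rate — magnitudes chosen to be
realistic for peri-sinus volumetry. All generator parameters are
explicit fields, so recovery experiments configure the truth they test
against.

**What the phantoms do not show.** They contain no gyri, skull,
partial-volume effects, Rician noise, registration error, or
inter-rater ambiguity; intensity classes are exactly piecewise
constant before bias/noise. Passing the synthetic studies demonstrates
that the pipeline's machinery is correct and self-consistent — not that
it reaches any particular accuracy on clinical MRI.

## Problem sizes used in the shipped studies

The phantom study trains on 20 phantoms and evaluates on 5 held-out
noiseless phantoms (noiseless so that the AG instance count has a
unique right answer); the EM experiment uses 10^4 samples; the lifespan
recovery uses cohorts of n = 2000; fold planning uses the full 80-id
layout. These sizes keep a complete from-scratch run of
`scripts/acceptance.py` in the tens of minutes on one CPU.

## Known limitations

* The registration is a contract with a simplified default, not a
  diffeomorphic registrar; real studies should inject external warps
  through the plug-in hook.
* The NumPy networks are CPU-scale; there is no GPU path, mixed
  precision, or data-loader parallelism.
* The bias-correction tissue model assumes a small number of intensity
  classes; strongly textured anatomy would need a finer model.
* Mixed-model adjusted R² is marginal (fixed-effects) by construction;
  conditional R² is not reported.
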