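# Methods

## Problem and approach

Stereotactic neurosurgery planning is anchored on two midline landmarks,
the anterior and posterior commissures (AC, PC). `acpcnet` localizes both
landmarks in T1-weighted MRI volumes that have been rigidly pre-aligned to
a template, by *heatmap regression*: instead of regressing coordinates
directly, a fully convolutional network predicts a volume whose two peaks
mark the landmark positions, and a deterministic post-processing step turns
those peaks into labeled sub-voxel coordinates in RAS millimeters.

The regression target for a volume is a single-channel heatmap containing
one isotropic Gaussian sphere per landmark (shared sigma = 3 voxels,
identical to mm at 1 mm isotropic resolution), peak-normalized to 1.
Overlapping spheres combine by voxelwise maximum so normalization survives
landmark proximity; the target is label-free and AC/PC disambiguation is
deferred to post-processing, where anatomy (AC anterior of PC, i.e.
greater RAS y) resolves it. Gaussians are evaluated at every voxel without
a truncation radius — at sigma 3 the tails are numerically negligible
beyond ~15 voxels.

## Network

The regressor is a high-resolution compact 3D residual architecture: a
3x3x3 input convolution, three stages of three pre-activation residual
blocks (two 3x3x3 convolutions each) with dilation factors 1, 2, 4, and a
linear 1x1x1 head — 20 convolutional layers in the default configuration,
with a theoretical in-plane receptive field of 87 voxels by the recurrence
rf += (k-1)·dilation per layer. All convolutions are zero-padded so the
output heatmap has the input window's shape. The head is linear (no output
nonlinearity): targets live in [0, 1] but the task is a regression, and a
linear head keeps the loss landscape simple.

The implementation is self-contained NumPy (float32): convolutions are
computed by tap-wise `tensordot` accumulation with an optimization that
skips kernel taps which can only read zero padding — for the quasi-2D
training windows used here that cuts the 27-tap loop to 9. Backward passes
are hand-derived; gradients were verified against central finite
differences. Instead of normalization layers, the second convolution of
every residual branch is zero-initialized so each block starts as the
identity; together with He initialization of the remaining weights this
keeps 20-layer training stable at the configured learning rates. Inputs
are standardized per volume (z-scoring) before the network sees them, at
training and inference alike; the choice is recorded in the model handle
so checkpoints stay self-describing.

Two presets share one topology: `NetConfig()` (16 channels, full scale)
and `NetConfig.desk()` (8 channels) — shrinking channels rather than
structure keeps topology-dependent properties (layer count, receptive
field) identical, so desk-scale tests exercise the same architecture.

## Training

Training is patch-based. Window centers are drawn from a *sampling prior*:
the same Gaussian-sphere construction centered on the template AC/PC,
renormalized to sum 1 — so nearly all windows contain landmark signal.
The prior doubles as the framework's static error map; iterative error-map
updating is not implemented because a static prior suffices for two
well-localized midline landmarks.

Windows are quasi-2D, default (72, 72, 1); the desk preset uses
(48, 48, 1). The singleton axis is assigned uniformly at random among the
three axes at sampling time, yielding the three orthogonal 2D views — the
assignment must live in the sampler because an axial slab cannot be turned
into a sagittal one after cutting. Augmentation then applies in-plane
transposes, per-axis flips (identical geometry for input and target), and
a uniform ±10% rescaling with trilinear interpolation, after which the
target is renormalized so its peak stays ≤ 1.

Losses: RMSE (sqrt of the batch mean squared voxel error) or Huber
(delta = 1, quadratic below, linear above — the delta is a package choice,
as is per-batch rather than per-window reduction). Regularization: L1 or
L2 on convolution weights (biases excluded), with the weight-decay value
1e-5 doubling as the penalty coefficient — the configuration vocabulary
exposes a single `decay` knob and the package mirrors that. Optimizers:
hand-written RMSprop (rho 0.9) and Adam (0.9/0.999, bias-corrected), both
with epsilon 1e-8, learning rate default 0.005. The studied grid is the
full product {RMSE, Huber} x {L1, L2} x {Adam, RMSprop}; the reference
configuration is RMSE + L1 + RMSprop.

Dataset splitting is seeded and exhaustive: validation and test sizes are
the nearest integer of n·ratio, remainder to train (908 volumes at
80:10:10 give 726/91/91). Validation loss is computed every 50 iterations
on a fixed window set sampled once from the validation share, keeping
learning-curve cost negligible.

## Inference and extraction

Full volumes are predicted by sliding-window tiling with voxelwise uniform
averaging of overlapping windows (stitching weights provably sum to 1; a
constant network stitches to an exactly constant volume). Default
inference windows are full-plane quasi-2D slices, matching the training
regime.

Extraction: (1) a binary ROI mask zeroes voxels farther than 15 mm from
both template landmarks — pre-alignment guarantees the true landmarks are
near the template pair, so false-positive peaks elsewhere are removed by
construction; (2) Gaussian smoothing (sigma 1 voxel); (3) the global
maximum is peak one; (4) a ball of radius `min_separation_mm` (8 mm) is
suppressed and the next global maximum is peak two, which must reach 10%
of peak one (else a missing-landmark error); (5) each peak is refined to
sub-voxel precision; (6) the more anterior refined point is labeled AC,
ties broken by amplitude then lexicographic voxel index.

Sub-voxel refinement defaults to per-axis log-parabolic peak
interpolation: the log-intensity of a Gaussian sphere is exactly
quadratic, so the vertex of the parabola through the peak voxel and its
axis neighbors recovers the fractional center exactly, including the
half-voxel tie case. A local intensity-weighted centroid is available as
an option (`subvoxel_method="centroid"`), but for spheres whose sigma is
wide relative to the refinement window the centroid is pulled toward the
peak-voxel center (a systematic ~0.7 mm bias on ideal sigma-3 heatmaps),
which is why it is not the default.

## Statistics

Localization error is the 3D Euclidean distance (mm) per landmark.
Outliers are errors more than k = 3 scaled MADs from the sample median,
scaled MAD = c · median(|A_i − median(A)|) with
c = −1/(√2 · erfc⁻¹(3/2)) ≈ 1.4826022185, the constant that makes the MAD
a consistent estimator of sigma for Gaussian data. If the MAD collapses to
zero on non-identical values, all non-median values are flagged with a
warning. Summaries report mean ± sample (n−1) standard deviation and max.

Model comparison, per landmark, on outlier-filtered errors: one-way ANOVA
across models, then pairwise unpaired Welch t-tests — one-tailed against
the designated baseline with the alternative "model error smaller than
baseline", two-tailed otherwise. Welch (unequal variances) is used because
nothing guarantees homoscedasticity across models. Each significance level
is divided by a Bonferroni term whose default is the *factorial* of the
model count (6 models → 720), configurable via `StatConfig.n_comparisons`;
p-values below 0.001 are displayed as "<0.001". Multi-annotator consensus
averages per-label coordinates and flags a landmark when any pairwise
inter-annotator distance strictly exceeds 2.0 mm.

## Synthetic phantoms

The phantom generator emulates the pipeline's inputs: rigidly pre-aligned
brain-like volumes with known AC/PC ground truth. Anatomy is procedural —
head and brain ellipsoids, lateral-ventricle-like hypointensities, a
darker interhemispheric midline slab, and a compact hyperintense Gaussian
blob (sigma 2 mm, amplitude 0.5) at each landmark so the landmarks are
predictable from intensity alone. Residual rigid jitter (small random
rotation + translation, default 2 mm scale) stands in for imperfect
registration and moves landmarks and anatomy coherently; a low-order
random polynomial bias field (on by default) and additive Gaussian noise
(sigma 0.03) model intensity inhomogeneity and noise. The canonical
(unjittered) AC/PC positions — 26 mm apart along y, an adult AC–PC
distance — serve as the template landmarks for the sampling prior and the
extraction ROI, exactly as a registration template's known AC/PC would.

What the phantoms do *not* model: MR physics (no T1 relaxation, partial
voluming, or Rician noise), pathology (atrophy, enlarged ventricles), and
inter-subject anatomical variability beyond rigid jitter. Passing tests
therefore demonstrate that the pipeline's machinery — sampling, learning,
stitching, extraction, statistics — is correct and that the network can
learn image-predictable landmarks; they do not demonstrate clinical-grade
accuracy on real MRI.

All randomness flows from explicit seeds (per-phantom seeds derive from a
cohort seed via `SeedSequence`), and single-threaded runs are bitwise
reproducible.

## Desk-scale experiment sizes

The reference end-to-end experiment trains the 8-channel network on 40
phantoms of 64x64x64 voxels for 500 iterations of 16 windows (48, 48, 1),
then evaluates on 10 held-out phantoms — sizes chosen so the whole
experiment runs in minutes on a single CPU core while exercising every
stage at full fidelity. Under these conditions the pipeline reaches a mean
3D localization error well under 1 mm on held-out phantoms (the acceptance
script recomputes the exact figure); this is the desk-scale analogue of a
sub-millimeter claim, not a reproduction of one on real data.

## Numerical and degenerate-input choices

- Network math in float32; losses and stitching accumulate in float64.
- RMSE gradient guards the rmse → 0 singularity with a 1e-12 floor.
- Peak suppression uses world-space (mm) distances, so anisotropic affines
  are handled correctly.
- Landmarks mapping outside the volume raise an error naming the landmark;
  degenerate (all-zero) sampling priors and heatmaps with fewer than two
  credible peaks raise dedicated errors rather than returning garbage.
- `.fcsv` files are accepted in both the numeric (0/1) and textual
  (RAS/LPS) coordinate-system header dialects; LPS positions are negated
  in x and y on load and everything internal is RAS mm.

## Known limitations

- The NumPy network trains at desk scale; full-scale (256x256x150, 16
  channels, 2500 iterations, batch 64) training is possible but slow
  without a GPU framework.
- Single-channel heatmaps cannot represent landmarks closer than the peak
  separation the extractor can resolve (min_separation_mm).
- The orientation augmentation assumes roughly isotropic voxels, as does
  the voxel-unit sigma.
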