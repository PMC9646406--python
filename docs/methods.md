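# Methods

## Problem and scope

`longiseg` segments *new* multiple-sclerosis lesions from a pair of
co-registered longitudinal 3D FLAIR volumes. The two scans are treated as
one 2-channel image; the target is a binary mask of lesions present in the
follow-up but absent at baseline. The package covers the full pipeline —
preprocessing, patch-based training with foreground oversampling and
augmentation, three U-shaped network variants with deep supervision,
sliding-window inference, and voxel-/lesion-level evaluation — plus a
synthetic longitudinal phantom generator so that every stage is testable
without access to clinical data.

## Preprocessing

For each case the baseline and follow-up are concatenated channels-first
(channel 0 = baseline, channel 1 = follow-up), cropped to the minimal box
containing any nonzero voxel, z-scored per channel over *all* voxels of
the cropped volume (no brain masking), and resampled to 1 mm isotropic
voxels — trilinear for images, nearest-neighbor for masks. At inference
the same chain runs without the crop by default (a `crop` flag restores
it), and the predicted probability map is resampled back to the native
grid before thresholding. Resampled grid shapes use
`round_half_away_from_zero(shape * spacing / target)`, so grids are
reproducible; boxes are 0-based and half-open throughout, which makes crop
inversion exact.

## Network

All three variants share one skeleton: a 3x3x3 convolution stem; four
resolution levels whose width doubles at each 2x2x2 stride-2
convolutional downsampling and halves at each 2x2x2 transposed-conv
upsampling; skip concatenation; one block per decoder level (first conv
maps 2w -> w, the nnU-Net convention); and pointwise heads that emit
2-class logits at the three highest decoder resolutions. The auxiliary
half- and quarter-resolution logits exist only in training mode.

Block families (GroupNorm group size 8, LeakyReLU slope 0.01):

* **plain**: [conv3 -> GN -> LeakyReLU] x 2.
* **residual**: conv3 -> GN -> LeakyReLU -> conv3 -> GN, a shortcut added
  between the last GN and the final LeakyReLU; the shortcut is a pointwise
  convolution when the block changes width and the identity otherwise.
* **pre-activation**: [GN -> LeakyReLU -> conv3] x 2 with the same
  shortcut rule and no trailing activation.

The default width is 64 channels at the top level. This is the unique
power of two at which the four-level architecture lands at the published
~28.7 M parameter scale (32 gives ~7 M, 128 gives ~114 M). The
closed-form ledger (`longiseg.network.parameter_ledger`) counts
28,534,662 trainable scalars for the plain variant and 28,707,142 for the
residual variant — the difference is exactly the three decoder shortcut
convolutions. The pre-activation variant counts 28,708,038: its first
norm acts on the concatenated 2w decoder input rather than w, adding
2·(2w−w) scalars per channel-changing block (896 total). The residual
and pre-activation figures are identical at the printed 0.1 M precision
but not to the scalar; exact equality is structurally impossible once the
first normalization precedes the width-changing convolution.

Weights are He-initialized (normal, std = sqrt(2 / fan_in)); biases and
norm offsets start at zero, norm scales at one. The forward pass is
deterministic given the weights — there are no stochastic layers.

### Numerical backend

The networks, losses, and optimizer run on a small reverse-mode autodiff
engine over numpy (`longiseg._autograd`), written for this package to
keep it dependency-light and fully deterministic on CPU. Convolutions are
lowered to BLAS matrix products: stride-1 kernels via a shift-gather of
k^3 input slices, and the 2x2x2 stride-2 (de)convolutions via exact
block reshapes. Every operator's analytic gradient is checked against
central finite differences in float64 in the test suite.

## Loss

The per-scale objective is `L = L_Dice + L_Focal` with

* soft Dice `1 − (2⟨G,P⟩ + ε) / (‖G‖² + ‖P‖² + ε)`, ε = 1e-5, reduced
  jointly over all J×N entries of a patch (the default, as the formula is
  written); a class-averaged variant is available via
  `LossConfig(dice_mode="classwise")` and coincides with the joint form
  for a single class;
* focal `−(1/N) ⟨G, (1−P)^γ log P⟩`, γ = 2, with probabilities clamped to
  [1e-7, 1 − 1e-7] before the logarithm so the loss is finite on the
  whole simplex.

Deep supervision weights the full-, half-, and quarter-resolution terms
by (1, 0.5, 0.25). Lower-resolution ground truths are derived from the
full-resolution mask by nearest-neighbor striding (default; preserves the
one-hot structure) or 2x2x2 max-pooling (keeps one-voxel lesions alive at
the quarter scale). Dice and focal are computed per batch element and
averaged.

## Training

Patches are cropped on the fly: with probability `p_foreground` (default
0.66) the patch center is a uniformly drawn new-lesion voxel (uniform
fallback when a case has none), otherwise uniform over the volume;
boundary-crossing patches are zero-padded. Each patch then passes
through the augmentation stack: random affine (rotation ±15°, isotropic
scale ±10%, one draw shared between image and label; trigger p = 0.2),
per-axis flips (p = 0.5), and — each with trigger p = 0.15 — additive
Gaussian noise (sd 0.01–0.1), Gaussian smoothing (σ 0.5–1.5 voxels),
intensity scale/shift (±10% / ±0.1), a smooth multiplicative bias field
(exp of a degree-3 polynomial, coefficient amplitude 0.3), and gamma
contrast (0.7–1.5) on min-max-normalized intensities. Magnitudes are
package choices — standard for FLAIR lesion pipelines — and fully
configurable; labels are never intensity-transformed.

Optimization is AdamW (decoupled weight decay 1e-2) with cosine annealing
from the initial learning rate to zero over the step budget, no restarts
and no early stopping. The reference schedule is 100,000 steps at batch
size 2 and lr 1e-5; over a 40-case cohort that is 5,000 patches per
subject. Cross-validation uses a deterministic, seed-reproducible 5-fold
split by case (unstratified by default; a stratified option exists).
Checkpoints embed weights, optimizer moments, RNG state and configs, so
interrupted runs resume bit-identically.

### Desk-scale stand-in

CPU-scale tests replace the reference schedule with a pinned miniature
experiment: 3 levels, width 8, 32³ patches, 500 steps, batch 2, lr 5e-3
(a 500-step budget needs a far larger rate than the 100k-step schedule),
class-averaged Dice, max-pool ground-truth pyramid, augmentation off,
trained on four default phantoms. The class-averaged Dice is used here
because at this tiny scale the joint reduction is dominated by the
background class and 500 steps are not enough to escape the all-background
minimum; the classwise form weights the rare foreground equally and
overfits reliably. The run is expected to reach Dice ≥ 0.9 on a training
phantom and ≥ 0.8 on a held-out phantom, and to predict zero lesions on a
held-out lesion-free phantom — a toy mirror of the with-/without-lesion
evaluation split.

## Inference

Full volumes are tiled with fixed-size windows (training patch size) at
50% overlap; origins lie on a regular grid with stride
`window × (1 − overlap)`, the last window clamped to the volume edge, and
sub-window volumes zero-padded. Per voxel, the softmax probabilities of
all covering windows are averaged uniformly (and across ensemble members,
which keeps the output on the probability simplex), the foreground map is
resampled trilinearly to the native grid, and thresholded at 0.5 with
ties counted as lesion.

## Evaluation

Cases whose ground truth contains new lesions are scored with the Dice
overlap and the symmetric Hausdorff distance between mask surfaces
(surface = mask voxels with a 6-neighbor outside; distances in mm between
voxel centers), plus lesion-wise sensitivity, positive predictive value
and F1. Lesions are connected components under 18-connectivity (faces and
edges, not corners); components smaller than 3 mm³ are removed before
matching. A true lesion counts as detected when predicted lesions cover
at least 10% of its volume; a predicted lesion is a false positive when
it intersects no true lesion. The 10% volume-overlap rule is a pinned,
configurable approximation of the challenge evaluator's association
rules, and is logged in every report. Cases without true new lesions
report the number (NLP; component count without a size filter) and total
volume (VLP, mm³) of predicted lesions instead.

Conventions: Dice of two empty masks is 1 (it never enters the stratified
aggregation, which splits by truth status); Hausdorff is undefined for an
empty mask and such cases are excluded from HD aggregation; SEN/PPV/F1
are all 1 when there is nothing to detect and nothing predicted, else
empty denominators score 0.

## Synthetic phantoms

A phantom case is: a smooth positive background (1 + six random
low-frequency cosine harmonics, amplitudes 0.02–0.08); non-overlapping
ellipsoidal lesions (semi-axes 2–5 mm) with a Gaussian-smoothed boundary,
split into *stable* lesions present in both time points and *new* lesions
present only in the follow-up; a follow-up-only global gain (default 1.1)
and multiplicative low-frequency bias field (relative amplitude 0.2)
emulating scanner drift; and i.i.d. Gaussian noise per time point
(sd 0.02). Lesion amplitude is `lesion_contrast` × the background field's
spatial SD; the default of 8 puts lesions ≈ 40% above mean background —
several SDs of the z-scored channel — matching the conspicuity of real
FLAIR lesions. The ground-truth mask is the union of the *hard* new-lesion
ellipsoids, so manifest volumes are exact voxel counts × voxel volume, and
every default lesion clears the 3 mm³ evaluation filter by construction.
The default grid is 64³ at 1 mm so CPU tests stay fast; anisotropic
spacings (e.g. 0.6 × 0.98 × 0.98 mm) are supported via `voxel_size`.
Datasets draw each case without new lesions with probability 11/40,
mirroring the fraction of stable patients in the cohort the defaults are
modelled on, with independent per-case RNG streams spawned from one seed.

What the phantoms do *not* emulate: brain anatomy and tissue classes,
partial-volume effects, Rician noise statistics (Gaussian by default;
z-scoring makes the difference minor at these SNRs), lesion texture,
enlarging lesions, registration error between time points, and
rater-disagreement in the ground truth. Passing desk-scale tests
therefore demonstrates that the machinery — sampling, optimization,
inference, metrics — is correct and can learn conspicuous longitudinal
change; it does not certify clinical-grade accuracy on MRI.

## Known limitations

* CPU-only: the reference 100k-step schedule at width 64 and 128³ patches
  is far outside desk scale; the package trains it correctly but slowly.
* The lesion-detection association rule is a deliberate simplification of
  the challenge evaluator (no many-to-one bookkeeping beyond union
  coverage).
* Resampling keeps the world position of voxel (0, 0, 0) fixed rather
  than the field-of-view center; for the axis-aligned affines produced
  here the difference is a sub-voxel translation.
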