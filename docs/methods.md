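# Methods

This note documents the models, procedures and design choices implemented in
`bcrfusion`, and what the synthetic experiments do and do not demonstrate.

## Problem setting

After radical prostatectomy, roughly a fifth to a third of prostate-cancer
patients develop biochemical recurrence (BCR): two consecutive PSA
measurements ≥ 0.2 ng/mL. The package implements a preoperative BCR
classifier that fuses two co-registered MRI sequences (T2-weighted with fat
suppression, and diffusion-weighted imaging), three anatomical regions
derived from tumor and prostate segmentations, and routine clinical
covariates. Inputs per patient are two NIfTI volumes on a shared grid,
tumor/prostate (and optionally adjacent-organ) masks, and one clinical CSV
row; the output is a recurrence probability.

## Region construction

Three disjoint regions are built from the masks by physical-distance
morphology:

- **ITR** (intratumoral): the tumor mask itself.
- **PTR** (peritumoral): the tumor dilated by a margin (default 5 mm),
  intersected with the prostate, minus the tumor. The shell interpretation —
  PTR excludes the tumor interior — keeps the regions disjoint, which the
  multi-region ablation requires.
- **PPR** (periprostatic): the prostate dilated by the same margin, minus
  the prostate and minus any adjacent-organ exclusion mask.

Dilation thresholds the exact Euclidean distance transform computed with the
voxel spacing in millimetres, so a 5 mm margin is 5 mm in every direction on
anisotropic grids (typically ~3.5 mm through-plane vs ~0.6 mm in-plane).
Membership is decided at voxel centers; a tolerance of 1e-9 guards only
against float rounding at exact-tie distances. Mismatched mask/volume grids
are an error, never silently resampled: the method assumes co-registered
sequences. Tumor voxels outside the prostate are kept in the ITR with a
warning, but the PTR is still clipped to the prostate.

## Preprocessing

Each volume is z-score normalised over the whole volume. For each region the
contiguous axial span of slices intersecting the region is selected; each
slice is cropped to the region's in-plane bounding box (union over the 3-D
region, padded by 10%), masked so non-region pixels are exactly zero,
bilinearly resized to a square input (224 px for the full-size network,
64 px for the desk configuration), and stacked with its partner sequence
into an (H, W, 2) slice pair. A fixed budget of `n_slices` (default 8)
positions per region is enforced: shorter spans are zero-padded (flagged),
longer spans are uniformly subsampled. The fixed budget is needed because
the patient-level head has fixed dimensionality; the aggregation layer
learns to discount padded positions, whose slice scores are forced to zero.

Clinical covariates are encoded to a fixed vector in [0, 1]: numerics (age,
PSA) min–max scaled with statistics fitted **on the training split only**
(validation/test values outside the training range are clipped), ordinal
categoricals (Gleason-sum band, ISUP grade, clinical stage, CAPRA band)
mapped to (code − 1)/(K − 1). Ordinal rather than one-hot coding keeps one
vector slot per variable. The exact covariate set is schema-driven since it
is study-specific.

Training-time augmentation applies, per slice and epoch: rotation uniform in
±10°, horizontal flip with probability 0.5, and brightness/contrast jitter
(shift ±0.1, gain 0.9–1.1) applied to foreground pixels about the foreground
mean, so background zeros are preserved; identical geometry is applied to
both channels, and padding slices pass through untouched.

## Network

A **shared** dual-channel residual CNN encodes every region's slice:
the 18-layer residual network (dual-channel stem; 224 → 7×7×512), or a
light residual variant for CPU-scale work (64 → 4×4×64; a 4×4/stride-4
patchifying stem followed by two residual stages — chosen so one CPU can
train it in minutes). ImageNet-style pretrained weights can be loaded
through `adapt_first_conv`, which averages the three RGB kernels of the
first convolution and duplicates the mean into both input channels; with
both input channels equal, the pre-bias response is exactly 2/3 of the
original response to the RGB-replicated image. With a pretrained start the
first `freeze_prefix` stages (default 2: stem + first residual stage —
"layer" counting in a residual net is ambiguous, so the unit is a stage) are
frozen; the desk configuration trains from random initialisation and
freezes nothing.

Per axial position, the region feature maps are fused by channel
concatenation in the fixed order ITR, PTR, PPR (the fusion operator is not
otherwise constrained; concatenation is the minimal-assumption choice). A
learned axial embedding table — one (h, w) plane per slice position,
broadcast across channels — is added after fusion; because the addition
broadcasts per channel, adding before or after concatenation is the same
operation. The clinical vector is linearly mapped to `d_emb` values
(exposed as configuration, since the dimensionality of this "linear
transformation" is a free choice), each replicated over the (h, w) plane
and concatenated, giving C_total = |regions|·C_I + d_emb channels.

The fused map is read as S = h·w spatial tokens of width C_total. Tokens
are linearly projected to the transformer model dimension (the token width
otherwise never equals the configured hidden size), summed with learned
positional embeddings, and passed through a post-norm transformer encoder
stack (default 4 layers, 8 heads, 256-dim hidden, dropout 0.1 after each
sublayer; Xavier-uniform initialisation). The token outputs are mean-pooled
and a fully connected layer yields the scalar slice score r_i; mean-pooling
before the slice FC is the simplest reading consistent with a scalar
per-slice output. The patient's score vector R = (r_1 … r_N), with padded
positions zeroed, passes through a final FC + sigmoid to give ŷ. The loss
is binary cross-entropy over patients, with probabilities clamped at 1e-7.

The clinical-only baseline is a two-layer perceptron (D_cli → 16 → 1,
sigmoid) trained with the same optimiser and early-stopping protocol.

## Training protocol

AdamW (decoupled weight decay 0.01 on weight matrices only; the decay value
is a conventional default and configurable), initial learning rate 1e-4,
batch size 16, up to 300 epochs, with an epoch-granular cosine annealing
schedule lr(t) = lr0 · ½(1 + cos(πt/T)) with floor 0 and no restarts.
After each epoch the validation AUC is evaluated (AUC is the study's
headline metric, so it is the early-stopping monitor); ties count as
non-improvement, and training halts after 10 non-improving epochs,
restoring the weights of the best epoch. With a constant validation metric
this stops after exactly 11 epochs (best at epoch 1 + 10 stalls).

Resampling: a largest-remainder stratified 80/20 split (so 182 patients
with 38 positives give exactly 146 training / 36 validation, 31 positives
in training), and stratified 5-fold cross-validation repeated 20 times
(100 fold pairs) as the primary protocol. Per-fold clinical min–max
statistics and model selection use only that fold's training portion.
Everything is NumPy-based and single-threaded-deterministic: identical
seeds give identical histories (a different BLAS thread count can perturb
floating-point summation order, which is the one caveat to bit-stability).

The network and its optimiser run on a small reverse-mode automatic
differentiation core written for this package (`bcrfusion.nn`): an
ndarray-valued tape with the operations the model needs (conv2d as
im2col + GEMM in NHWC layout, pooling, batch/layer norm, attention,
dropout, AdamW). Every operation is verified against central-difference
numeric gradients in the test suite.

## Evaluation

Threshold metrics (sensitivity, specificity, accuracy, F1) are computed
from the confusion table at a 0.5 operating threshold by default (the
threshold rule is not otherwise determined; a Youden-J threshold chosen on
training folds is available). Ratios with empty denominators are flagged
undefined, not zeroed. AUC is the tie-aware Mann–Whitney probability.
Repeated-CV results are summarised as the mean with a 95% percentile
interval (2.5th/97.5th percentiles, linear interpolation) over the
fold-repeat estimates; percentile intervals were chosen because the
estimates' distribution over folds is directly available, and
normal-approximation intervals are available by flag. Correlated ROC
curves are compared with the DeLong test: placement values (structural
components) per model, covariance of the paired components, two-sided p
from the standard normal. Identical score vectors return z = 0, p = 1;
zero variance with unequal AUCs is an error, not a silent zero.
Significance annotations use the bands ns / 0.01<p<0.05 / p<0.01.

## Synthetic phantoms

The generator emulates the structure the pipeline needs, not MR physics:
an ellipsoidal prostate (semi-axes 9–13 mm) with an interior spherical
tumor (radius 4–7 mm) on an anisotropic grid (20×64×64 voxels at
3.5×0.6×0.6 mm), plus a posterior "adjacent organ" for the exclusion mask.
Contrast polarity follows the real sequences (gland bright / tumor dark on
the T2-like channel; tumor bright on the DWI-like channel). Label-dependent
signal is planted independently per region — a DWI intensity shift in the
tumor (default 10 = 5× the noise SD), extra texture variance in the
peritumoral shell, a radial intensity ramp in the periprostatic shell — and
label-shifted clinical covariates, so each model variant has its own ground
truth and the multi-region ablation has a synthetic analogue. Positive
prevalence defaults to 0.2, matching a cohort where about one patient in
five recurs. With all effect knobs at zero the classes are identical in
law, giving a null cohort for separability checks. Diffusion b-value
heterogeneity is not simulated (the framework never uses b-values
computationally), and no anatomical realism beyond the region geometry is
attempted: passing tests demonstrate that the architecture, plumbing and
statistics behave as specified, not that the model reaches any particular
accuracy on patient data.

## Desk-scale configuration

CPU-scale experiments (the `desk_config`) use the light encoder at 64 px,
8 slices, a 2-layer/4-head/64-dim transformer with d_emb 8, no frozen
stages (random initialisation), learning rate 3e-4, batch size 8, 15
epochs, and 3-fold CV on a 120-phantom cohort. These sizes were chosen once
so that a full multi-variant comparison trains in minutes on one CPU while
still recovering planted signal (pooled held-out AUC ≈ 0.98 for the
combined model on the default phantom conditions, chance-level on the null
cohort); the learning rate is higher than the full-scale default because
training starts from random weights for far fewer epochs.

## Known limitations

- The full-scale protocol (ResNet18 at 224 px, 100 fold-repeats, 300
  epochs) is implemented but not routinely exercised on CPU; tests cover it
  at the level of shape/gradient contracts and single forward passes.
- Slice-position alignment across regions is nominal: position i of each
  region's stack is fused, although the regions' axial spans differ; the
  learned axial embedding is the mechanism that absorbs cross-patient and
  cross-region misalignment. A position is treated as padding for the
  patient head only when every region is padded there.
- The distributed pretrained weights themselves are not bundled; loading is
  an optional hook and all tests run from random initialisation.
- Real-data effects — scanner harmonisation, b-value heterogeneity,
  segmentation error — are out of scope of the phantom generator.
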