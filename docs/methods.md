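# Methods

## Problem setting

Glioblastomas with a methylated MGMT promoter respond better to alkylating
chemotherapy, so predicting methylation status non-invasively from
pre-operative multi-parametric MRI (T1, T1-CE, T2, FLAIR) is clinically
valuable. The pipeline implemented here follows the standard radiogenomic
recipe for the RSNA-MICCAI BraTS-2021 MGMT cohort: segment the tumor,
discard uninformative axial frames, and classify methylation from the
appearance of tumor-bearing slices. The cohort itself (585 labeled
subjects, ~74k frames) is large and GPU-scale; this package validates the
*pipeline* on synthetic phantoms at desk scale and keeps the published
full-scale numbers only as reference constants for internal-consistency
checks (`gliomgmt.reference_results`).

## Phantom generator

Each phantom case is an ellipsoidal "brain" containing an ellipsoidal
tumor on a 240 x 240 x 155 grid by default and 64 x 64 x 32 for desk-scale
work (`PhantomParams.desk_scale`). Intensities are arbitrary units on
[0, 1000] before noise — MRI has no standard scale, and downstream
normalization must not assume one. Modality contrasts follow radiology:
tumor bright on FLAIR (+420) and T2 (+300), rim-enhanced on T1-CE
(+380 rim / +60 core, rim = tumor minus a 0.65-scaled inner ellipsoid),
mildly dark on T1 (−120). Additive Gaussian noise has sd 30 everywhere.

The methylation label modulates only the *texture variance* inside the
tumor: label-1 cases receive an extra zero-mean speckle field of sd 160
(the `class_effect`) on all modalities inside the tumor. Geometry is
label-independent by design, so segmentation difficulty carries no label
information and the classifier must use appearance — the radiogenomic
premise. The contrast, noise and class-effect magnitudes were fixed once,
as plausibly strong-but-noisy values (class signal ≈ 5x the voxel noise),
and define the study conditions for all recovery experiments.

What the phantoms deliberately omit: skulls (the skull-stripping step of
real pipelines is a no-op hook here), bias fields, k-space artifacts,
multi-focal or irregular tumors, inter-subject anatomical variability.
Passing the recovery experiments therefore shows the pipeline's machinery
is correct and sensitive to an appearance-coded label; it does not show
that real MGMT status is predictable at these accuracies.

## Preprocessing

Axial = third array axis, 0-based indices. For each tumor-bearing slice
(≥ 1 mask pixel), the T1-CE, T2 and FLAIR planes are each min-max
normalized to [0, 1] *per slice and per channel* (a constant plane maps to
zeros rather than dividing by zero), resized by bilinear interpolation,
and stacked in the fixed channel order (T1-CE, T2, FLAIR). Resizing uses
the pixel-center convention: output pixel i samples input coordinate
(i + 0.5)·H/target − 0.5, clamped at the edges; masks use nearest-neighbor
so they stay binary. Plain T1 is loaded when present but unused
downstream. The default target size is 256; desk-scale experiments use 64
(segmentation, native phantom resolution) and 32 (classification), which
trades resolution for minutes-scale CPU runtimes.

Patient-level splits prevent leakage: every slice inherits its patient's
subset. Subset sizes follow largest-remainder rounding of n·(0.8, 0.1,
0.1) with remainder ties resolved toward the later subset (585 cases give
468/58/59). Splits are stratified by label via constrained rounding:
global subset sizes are fixed first, then per-class cells are allocated by
largest remainder subject to those totals.

## Empty-frame rejection

Per frame: linear 8-bit grayscale mapping (min→0, max→255, round half away
from zero; constant frames map to zeros), Otsu's threshold on the 256-bin
histogram (class split ≤ t vs > t, ties toward the smallest t), candidate
foregrounds under both photometric polarities — bright-on-dark is
pixels > t; dark-on-bright is the complement (pixels ≤ t, equivalent to
thresholding the inverted frame at the mirrored threshold) — each refined
by one 3x3 binary opening then closing, then labeled with 8-connectivity.
The polarity whose largest component is bigger wins; ties go to
bright-on-dark (tumor-bright FLAIR prior). Constant frames yield an empty
foreground under both polarities: a flat frame is non-informative by
definition. The frame statistic is largest-component area over H·W.

The dataset threshold fits two 1-D k-means centers (10 restarts, seeded)
and takes their midpoint. Degenerate clusterings — center separation
< 0.05 or either cluster under 5 % of frames — fall back to the 5 %
quantile of the ratios; both constants are module-level and adjustable.
Rejection is strict: ratio < threshold. Note that the midpoint rule
places the threshold in the gap between well-separated ratio modes; on a
given cohort its numeric value depends entirely on that cohort's ratio
distribution (the published full-cohort value, 0.1000, is kept as a
reference constant only). The module is stage-agnostic: it can screen raw
dataset frames or post-segmentation VOI frames identically.

## Segmentation

A 2-D U-Net on axial slices (the flowcharted "3-D U-Net" label conflicts
with the per-slice processing the pipeline actually describes; the 2-D
reading matches the slice-based data flow and is what is implemented).
Per encoder level: two 3x3 conv + ReLU, 2x2 max pool, filters doubling
from `base_filters` (default 32, depth 4; desk scale 8, depth 2). Decoder
levels mirror with nearest 2x upsampling, a 3x3 up-convolution halving
channels, skip concatenation, and two 3x3 convs; a 1x1 conv + sigmoid
emits per-pixel tumor probability, binarized at 0.5 — the same cut as the
classifier's decision rule. Loss is Dice + binary cross-entropy by default
(the protocol never states a segmentation loss; the sum is a standard
robust choice and both pure losses remain selectable). Input spatial dims
must be divisible by 2^depth. Dice/IoU use the both-empty = 1.0
convention, which matters for all-background slices.

## Fusion classifier

Two feature extractors process the slice in parallel; each ends in a 1x1
convolutional stage whose global average pool gives the feature vector;
the two vectors are concatenated and passed through the fixed head
(512 ReLU → dropout 0.3 → 256 ReLU → dropout 0.3 → 1 sigmoid). The
feature tap — GAP of the final convolutional stage — is the standard
reading of "feature maps concatenated". Backbones are compact seeded
CNNs with the stock EfficientNetB0/ResNet50 feature widths (1280, 2048;
fused 3328) by default and reduced widths (32, 48) in the desk-scale
experiments; no pretrained weights exist offline, and requesting them
falls back to seeded random initialization with a warning. Backbones are
fine-tuned by default; `freeze_backbones` restricts training to the head.

Training follows the stated protocol exactly: BCE loss, Adam with initial
learning rate 0.001, batch 32, up to 20 epochs, early stopping on
validation accuracy (patience 5, best weights restored), learning rate
halved after 3 epochs of validation-loss plateau. Both callbacks are pure
state machines (`gliomgmt.nn.callbacks`) verifiable with stubbed metric
streams. Per-epoch training F1 is computed from the epoch's accumulated
confusion counts at the 0.5 cut (the epoch-level definition is otherwise
underspecified). Supervision is per-frame: every kept slice inherits its
case's MGMT label. Study-level output reports the mean probability over
kept slices (labeled by the same > 0.5 rule, so a 0.5 mean falls to
unmethylated) alongside a majority vote; both granularities are emitted
because the full-scale evaluation's granularity is ambiguous.

## Evaluation and Grad-CAM

Positive class = 1 (methylated). Zero-denominator rates are 0. Report
values are additionally rendered at two decimals, rounded half away from
zero, to match the published table's formatting; raw values are retained.
AUC is the Mann-Whitney rank statistic with average ranks (ties = 1/2),
which equals trapezoidal integration of the empirical ROC exactly and is
tie-robust. `reconstruct_confusion_from_report` inverts a printed report
(recall x support, rounded half-up) into the implied 2x2 matrix — the
published matrix exists only as a figure, so this reconstruction is the
consistency check.

Grad-CAM weights each channel of a target convolutional activation by the
spatial mean of d(score)/d(activation), takes the ReLU of the weighted
sum, bilinearly upsamples to the input grid, and min-max normalizes
(identically zero maps stay zero; the map is invariant to positive scaling
of the activations). The score is the sigmoid probability, and the default
target is the final convolutional stage of each backbone with the two maps
averaged.

## Experiment sizes and numerical choices

Desk-scale recovery experiments (`gliomgmt.experiments`) use 64 x 64 x 32
phantoms: segmentation trains a depth-2/8-filter U-Net at 64 x 64 on 16
cases (tumor slices plus every fourth background slice, so the net learns
to emit empty masks off-tumor) and scores assembled VOIs on 4 held-out
cases; classification trains reduced-width backbones at 32 x 32 on 20
cases and classifies 12 fresh-seed held-out studies, with a case-level
label-shuffle negative control. These sizes keep each experiment in the
seconds-to-minutes range on one CPU while leaving wide margins to their
pass criteria (held-out Dice ≥ 0.8; above-majority study accuracy;
shuffled accuracy within binomial noise of the 0.5 majority rate).

Other conventions: Otsu ties break low; polarity ties break bright;
largest-remainder ties break toward the later subset; probability 0.5 is
unmethylated everywhere; empty-vs-empty overlap metrics are 1.0; the
cohort labels CSV allocates exactly round-half-up(n·fraction) methylated
cases. Seeds thread through every stochastic component (phantom noise,
weight init, shuffling, dropout, k-means restarts); identical seeds give
bitwise-identical phantoms and deterministic metric trajectories.

## Known limitations

- Phantom realism is intentionally minimal (see above); headline
  full-cohort metrics (DSC 0.889/IoU 0.801, accuracy 0.95, AUC 0.96) are
  out of desk-scale reach and are not claimed.
- The NumPy autodiff engine is single-threaded CPU code built for
  correctness and small problems, not throughput; full-resolution
  (256 x 256, stock-width) training is architecturally supported but slow.
- Skull stripping is a documented no-op; DICOM ingestion, registration and
  bias-field correction are out of scope (BraTS volumes arrive aligned).
- The empty-frame auto-threshold assumes a roughly bimodal ratio
  distribution; heavily multi-modal distributions land on the fallback
  quantile or an in-gap midpoint that may need manual review.
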