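# Methods

## The model

`rgbdssd` implements a two-branch single-shot detector for greenhouse
tomato fruits over registered RGB-D images, plus a recurrent-attention
GAN that removes specular highlights from the color channel.

Each detector branch is a VGG16-style trunk: conv1–conv5, the dilated
fc6/fc7 convolutions, and four downsampling "extra" stages
(conv8–conv11).  For a 3×300×300 color input (1×300×300 for depth) the
branch emits six feature maps with spatial sizes 38, 19, 10, 5, 3, 1 —
the map at step *n* is a function of the map at step *n−1*, starting
from the input image.  Per-layer 3×3 heads regress, for every prior box
anchored at a feature-map cell, 4 localization offsets and 7 class
scores (6 fruit classes + background).

The six fruit classes are maturity × occlusion: ids 1/3/5 are
non-occluded green (immature), orange (semi-mature), and red (mature)
fruits; ids 2/4/6 their occluded variants.

### Prior boxes

Layer *k* of the 300-pixel detector uses the scale schedule

| layer | grid | s_k (px) | s_{k+1} (px) | ratios a_r | boxes/cell |
|------|------|-----------|---------------|------------|-----------|
| 1 | 38 | 30 | 60 | 1, 2, 1/2 | 4 |
| 2 | 19 | 60 | 111 | 1, 2, 3, 1/2, 1/3 | 6 |
| 3 | 10 | 111 | 162 | 1, 2, 3, 1/2, 1/3 | 6 |
| 4 | 5 | 162 | 213 | 1, 2, 3, 1/2, 1/3 | 6 |
| 5 | 3 | 213 | 264 | 1, 2, 1/2 | 4 |
| 6 | 1 | 264 | 315 | 1, 2, 1/2 | 4 |

At each cell (a, b) of an f×f grid the priors are centered at
((a+0.5)/f, (b+0.5)/f): one square of side s_k, one square of side
√(s_k·s_{k+1}), and for each ratio r>1 the pair (s_k√r, s_k/√r) and its
transpose.  This yields Σ f² · k = 8,732 priors per branch and
8,732 + 8,732 = 17,464 for the fused detector, whose prediction list is
the ordered concatenation (RGB first) of the two branches — a late,
decision-level fusion.

The linear scale rule s_k = s_min + (s_max−s_min)(k−1)/(m−1) with
s_min = 0.2, s_max = 0.9 is also exposed (`anchors.scale_fraction`) and
tested on its own terms.  Note that for m = 6 it produces pixel scales
(60, 102, …, 270) that do not reproduce the schedule above; the tabled
schedule — the canonical 300-pixel one with a special-cased first
layer — is what the detector uses, since it is the one the published
prior counts (8,732 / 17,464) are consistent with.

### Matching, loss, suppression

IoU is computed on continuous corner-form boxes with areas
(x_max−x_min)(y_max−y_min) — no +1 pixel convention.  A prior is
positive when its best IoU against the ground truths strictly exceeds
0.5; in addition every ground truth claims its best still-unclaimed
prior regardless of threshold, so no object is left without
supervision (without this rule small fruits can receive zero positives
and the objective degenerates).  Localization targets use the standard
offset code: center deltas scaled by prior size over variance 0.1, log
size ratios over variance 0.2; decode inverts encode exactly.

The objective is F_loss = (C_loss + L_all_loss)/N over the N matched
priors: softmax cross-entropy over positives plus hard-mined negatives
(the highest-background-loss priors, at most 3 per positive), and
smooth-L1 on the positives' offsets.  The sum is unweighted; an
optional weight on the localization term (default 1) is provided.  With
N = 0 the loss is defined as 0 (an image without matched priors
carries no gradient).  Inference decodes all priors, applies a
per-class greedy NMS (IoU 0.45, top-k 200, score ties broken by index)
and a confidence filter.

### The multi-scale (inception-style) block

An optional shape-preserving block replaces the plain extra stages:
parallel 1×1, factorized 1×3∘3×1 (receptive field 3, same as a full
3×3 but fewer weights), and 3×3 with dilation 1 or 2, concatenated
channelwise, plus an optional pooled projection path.  Receptive-field
arithmetic (`network.receptive_field`) follows the standard recurrence
rf ← rf + dilation·(kernel−1)·(product of preceding strides): two
stacked 3×3 see 5 pixels; 3×3 followed by a dilated-2 3×3 see 7.  The
published architecture does not pin where the block sits in the trunk,
so it is an opt-in replacement for conv8–conv11
(`network.use_inception_extras`), off by default, with its own unit
tests.

### Highlight removal (HRGAN)

The generator attends recursively: the attention map is initialized to
0.5 everywhere, and each of N blocks consumes (image, previous map),
passes features through a small residual stem and a convolutional LSTM
with per-channel peephole terms

    i_t = σ(W_xi X_t + W_hi H_{t−1} + W_ci ⊙ C_{t−1} + b_i)
    f_t = σ(W_xf X_t + W_hf H_{t−1} + W_cf ⊙ C_{t−1} + b_f)
    C_t = f_t ⊙ C_{t−1} + i_t ⊙ tanh(W_xc X_t + W_hc H_{t−1} + b_c)
    o_t = σ(W_xo X_t + W_ho H_{t−1} + W_co ⊙ C_t + b_o)
    H_t = o_t ⊙ tanh(C_t)

and emits a refined mask M_t ∈ [0,1]; a removal head reconstructs the
highlight-free image from (image, M_N).  Training minimizes
L_T = L_M + L_P + L_Adv with

* L_M = Σ_i β_i · MSE(M_i, T_i), β_i = 0.5^(N−i+1) (so β_N = 0.5 and
  Σβ_i = 1 − 0.5^N); truths are block-mean-downsampled to each block's
  mask size when blocks downscale;
* L_P the MSE between features of the restored and clean images under
  an injected fixed extractor (tests use a frozen random convnet; a
  pretrained feature network can be passed in);
* L_Adv = E[log D(I_f)] + E[log(1 − D(G(I_h)))], the discriminator's
  objective; the generator uses the non-saturating −log D(G(I_h))
  form, the standard stabilization of the same game.

The loss stack requires paired supervision (ground-truth masks and
clean images), so training here is paired supervised + adversarial on
synthetic pairs; N defaults to 4 and is configurable.

## Numerical engine

All networks run on a compact tape-based reverse-mode autodiff engine
written on numpy (`rgbdssd.autodiff`): convolution with stride,
padding and dilation (implemented as a channels-last tap loop — one
small matmul per kernel tap — which is markedly faster than im2col at
the narrow channel widths used on a CPU), max pooling with ceil mode,
the usual pointwise nonlinearities, fused softmax cross-entropy and
smooth-L1, Adam/SGD, and global-norm gradient clipping.  Every
operation is verified against central-difference gradients in float64.
Keeping the engine inside the package keeps the dependency footprint
to the standard scientific Python stack and makes the whole pipeline
reproducible from a single integer seed.

## Synthetic scenes

The generator renders what the detector is meant to consume: a
512×424 canvas (the native depth-sensor resolution; the augmentation
pipeline rescales to 300×300), ellipsoidal fruits with
maturity-dependent hue bands (green ≈ 90–140°, orange ≈ 20–40°, red ≈
0–15° HSV), spherically bulging per-fruit depth blobs in a 0.5–4.5 m
range, irregular leaf-shaped occluders placed strictly nearer in
depth, a foliage-textured background at the far plane, and optional
additive elliptical-Gaussian highlight blobs with exact intensity
masks.  Depth is stored as 16-bit millimeters; annotations as
VOC-dialect XML with 1-based inclusive integer corners.

A fruit is labeled occluded when more than 10 % of its mask area is
taken by a strictly nearer object.  No published overlap fraction
exists for that call; 0.10 was chosen once so that clearly visible
partial occlusion counts, and it is configurable
(`occlusion_label_threshold`).

What the generator does **not** emulate: photometric realism (specular
lobes on fruit surfaces, leaf venation, soft shadows), sensor noise
and depth shadows/holes of a structured-light camera, perspective
foreshortening, and the long-tailed class imbalance of a real
greenhouse.  Passing tests therefore demonstrate that the geometry,
matching, objective, and training loop are correct and that the model
class can fit registered RGB-D evidence — not that the reported
field accuracies transfer to real imagery.

## Augmentation

The eight-stage pipeline — ToSensor, PhotometricDistort, Expand,
RandomSampleCrop, RandomMirror, ToPercentCoords, Resize,
SubtractMeans — is composed in that order; the stage names fix the
canonical single-shot recipe, whose standard knobs are adopted
(brightness ±32, contrast/saturation 0.5–1.5, hue ±18°, expand ratio
≤ 4 with p = 0.5, the crop min-IoU menu {0.1,…,0.9}, mirror p = 0.5).
Geometric stages transform RGB and depth with identical parameters;
photometric jitter never touches depth.  Depth is normalized to [0,1]
by the configured (near, far) range before the pipeline, so its pad
value is the far plane (1.0); RGB pads with the dataset channel means.
Channel means are measured from the training split at run time (the
defaults are the measured statistics of the default generator).  An
expansion mode that materializes k augmented copies of a sample is
provided alongside the composed pipeline.  The summary wording of the
source pipeline mentions rotation, but its named stage list contains
no rotation op; the named list is what is implemented.

## Evaluation

Per-class AP uses greedy matching of score-ranked detections at
IoU ≥ 0.5 (first claim wins, duplicates are false positives) and
all-point interpolation of the precision–recall curve; the VOC-2007
11-point variant sits behind a flag.  mAP is the mean over classes
with at least one ground truth; a class with no ground truth is
reported absent, not zero.  Maturity groups (immature = classes 1,2;
semi-mature = 3,4; mature = 5,6) and occlusion groups (non-occluded =
1,3,5; occluded = 2,4,6) default to means of member-class APs — the
reading consistent with the published cross-table relationship (mean
of the occluded-class APs 0.9031/0.9173/0.9082 = 0.9095) — with a
merged-label re-evaluation mode also available.

## Desk-scale presets and problem sizes

The package's own experiments run on one CPU at reduced width: the
`width_multiplier` scales every channel count (0.0625 by default in
the run configuration), with no pretrained weights anywhere.  The
standard smoke experiment trains the fused detector on 8 synthetic
scenes (batch 8, Adam, lr 1e-3, deterministic preprocessing, matching
precomputed) until training mAP ≥ 0.9, evaluated every 25 iterations,
capped at 500 — it typically converges around iteration 75.  The
highlight-removal run uses 16 synthetic 64×64 pairs, N = 4 blocks,
8 base channels, 200 alternating D/G steps.  Full-width training at
batch 8 for 10⁵-iteration schedules is out of reach of this engine and
is not attempted; the published absolute accuracies are consequently
not reproduced here, only the structural and arithmetic claims around
them.

## Known limitations

* The engine is single-threaded numpy; throughput, not correctness, is
  the binding constraint.
* The bare >0.5 matching rule is augmented with forced best-prior
  claiming (standard practice); results with the bare rule alone would
  be undefined on small objects.
* The highlight GAN trains paired; true unpaired (cycle-consistent)
  training is out of scope.
* `scale_fraction` and the tabled pixel schedule disagree by
  construction (see above); the package treats the table as the
  operative geometry.
* Depth is assumed registered to RGB; no calibration or registration
  is performed.
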