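# Methods

## The detection problem

Gastric polyps are raised, roughly elliptical lesions seen in
gastroscopy video frames. The detector's job is to place an axis-aligned
bounding box around every polyp in a frame, in real time. The package
implements a single-shot multibox (SSD) detector whose feature pyramid
is enriched in two ways, and the complete evaluation protocol used to
judge such a detector.

## Order-statistic pooling

A 2x2/stride-2 max-pooling layer keeps one activation per window and
discards the other three. The central idea here is that the discarded
activations are not noise: pooling the same map with the 1st, 2nd, 3rd
and 4th order statistic of each window (Max, Second-Max, Second-Min,
Min) yields four half-resolution maps that together contain *every*
input value. For even spatial dimensions this decomposition is exactly
lossless — the multiset of values across the four pooled maps equals
the multiset of input values, per channel — and the test suite asserts
this multiset equality directly.

Two definitional choices are not forced by the idea itself and were
fixed as follows:

* **Ties.** Rank is defined over the sorted multiset of window values,
  duplicates kept (window `{3,3,1,0}` has Second-Max 3). Any
  deduplicating definition would break the lossless decomposition, which
  is the property the operator exists for.
* **Clipped border windows.** With ceil output rounding, a boundary
  window may contain fewer than 4 valid cells. The rank is clamped to
  the number of valid values rather than padding with zeros, so Min- and
  Second-Min-pooling never emit an artificial 0; every output is a
  genuine input value. Ceil rounding is the default because it is what
  the classic SSD trunk uses (it produces the 75-to-38 reduction the
  300-input pyramid needs).
* **Gradient routing.** Each output cell sends its gradient to the input
  cell it was selected from; among cells tied at the selected value the
  first in row-major order receives it. This is the ordinary
  argmax-pooling convention extended to arbitrary rank.

## The four network variants

All variants share a VGG-style trunk and the standard SSD pyramid
(Conv4_3, Fc7, Conv6_2, Conv7_2, Conv8_2, Conv9_2 at 38/19/10/5/3/1
cells for a 300-pixel input). They differ only in how each pyramid
level is widened before its detection head:

* `ssd` — no widening (the baseline).
* `ssd-p` — a **pooling module** per level: the four order-statistic
  poolings of a 2x-resolution source layer (the stage-3 trunk output for
  Conv4_3, otherwise the previous pyramid level), each followed by a 1x1
  convolution and batch norm, concatenated onto the level.
* `ssd-d` — a **deconvolution module** per level: a stride-2, kernel-2
  transposed convolution of the next-higher pyramid level, batch-normed
  and concatenated. The topmost level has no upper neighbor and keeps
  only its identity path (in `ssd-pd`, only its pooling module).
* `ssd-pd` — both modules; the full gastric-polyp network.

The batch norms exist to bring all concatenated branches to a common
scale before the heads.

Branch widths are a design choice (the architecture only dictates the
wiring): each pooling branch contributes `base_channels/4` and the
deconvolution branch `base_channels/2`, so a fully widened level carries
2.5x its plain width. This keeps the variant ordering in parameter count
(ssd < ssd-p, ssd-d < ssd-pd) and a model-size growth of roughly 50%
for `ssd-pd`, consistent with what is reported for the full method,
without exploding the detection heads.

Where a branch's grid disagrees with its level by up to two cells
(e.g. pooling a 3-cell source gives 2 cells against a 1-cell level;
deconvolving a 1-cell source gives 2 against 3), `force_spatial`
reconciles them: center-crop when larger, bilinear-resize when smaller.
Larger mismatches indicate a mis-wired plan and raise.

## Desk scale

The canonical desk-scale build uses input 96, channel scale 1/8 and four
pyramid levels (12/6/3/1 cells), preserving the full topology: every
level still has its pooling source, every level but the topmost its
deconvolution source, including both force_spatial cases. Two deliberate
deviations from the full-scale recipe, chosen so the network trains from
random initialization in minutes on one CPU core:

* the trunk carries batch norm after every convolution (the full-scale
  trunk, built for transfer from pretrained weights, does not);
* the desk training configuration uses SGD at lr 0.01 (momentum 0.9,
  weight decay 5e-4, batch 8) with a linear warmup over the first 10%
  of iterations and a 10x decay at 80% of the run, rather than the
  full-scale lr 5e-4 / 100k-iteration schedule. The full-scale
  configuration remains the `TrainConfig` default; the desk recipe is
  `desk_train_config()`.

Initialization is Xavier-uniform throughout (no pretrained weights),
seeded, so builds are bit-reproducible. The confidence head's
background logits start at +4 so an untrained network predicts
background nearly everywhere; without this, the first iterations are
dominated by an enormous mined-negative loss and unstable steps.

## Multibox machinery

Priors, matching, loss, decoding and NMS follow the reference SSD
design: per-level prior scales 0.1 then 0.2..0.9 evenly spaced (the
classic 300-input pixel sizes arise from these), aspect ratios
{1, 1', 2, 1/2} plus {3, 1/3} on the middle levels; matching gives every
ground-truth box its best prior unconditionally and additionally every
prior with IoU >= 0.5; offsets are encoded with variances (0.1, 0.2);
the loss is smooth-L1 on positives plus softmax cross-entropy with
hard-negative mining at 3:1 (per image, at least ratio-many negatives
when an image has no positives), normalized by the positive count; NMS
is greedy per class at IoU 0.45. All constants are surfaced in
`TrainConfig` rather than hard-coded. Horizontal-flip augmentation is
available behind a flag (off by default) and implemented by mirroring
images and re-matching mirrored boxes; no claim is made that this equals
the reference pipeline's full crop/photometric augmentation.

## Preprocessing conventions

Boxes are 0-based half-open `[xmin, xmax) x [ymin, ymax)` everywhere
inside the package; Pascal-VOC's 1-based inclusive convention is
converted at the XML boundary. This removes the +1 ambiguity from all
area and IoU arithmetic. Resizing to the square network input uses a
separable Lanczos resampler with support a=4 — an 8x8 source
neighborhood per output pixel, half-pixel-center sampling, edge
replication — implemented in numpy and verified against a direct
non-separable double-loop oracle. Boxes are scaled with the image (the
original frame is kept as metadata so evaluation can restore
original-frame coordinates); boxes that fall below half a pixel after
scaling are dropped with a warning. The only augmentation used by the
dataset split is a 180-degree rotation of training images, applied
after the train/test separation so no rotated twin of a test image can
leak into training.

## Evaluation protocol

A detection is a true positive when it can be matched, processing
detections in descending confidence with at most one detection per
ground truth, to an unmatched same-image truth with IoU >= 0.5;
duplicates are false positives, unmatched truths false negatives. IoU
exactly 0.5 counts as positive (the standard VOC rule; the boundary is
measure-zero anyway). Precision, recall and F1 are percentages;
P-R curves are evaluated on the 19-point confidence grid 0.05..0.95;
average precision is the 11-point interpolated VOC-2007 form (the form
contemporaneous with SSD). The confidence threshold and the IoU
threshold are independent parameters, both defaulting to 0.5.

Size-stratified recall bins ground truths by box area in the *original*
frame (small <= 32x32, medium <= 96x96, large above) — the strata are
meaningless on resized coordinates, which is why `AnnotatedImage`
carries its source frame.

Two models are compared per ground-truth polyp with an exact two-sided
McNemar test on the discordant counts b, c:
`p = min(1, 2*P[X <= min(b,c)])`, `X ~ Binomial(b+c, 1/2)`; b = c = 0
gives p = 1. The exact form (rather than the continuity-corrected
chi-square) is used because it is the variant consistent with the
published paired-table p-value this protocol reproduces
(b=22, c=4 -> p = 0.00053; the corrected chi-square would give 0.00085).

## Synthetic scenes

The generator emulates the gross structure of 560x475 gastroscopy
frames: a reddish base color under a radial vignette, low-frequency
mottling, gaussian speckle and a few specular glints, with 0-3 shaded
elliptical protrusions, each carrying its own glint and a tight
bounding-box label. Default study conditions follow the real
acquisition: frames at 560x475 later resized to the network input;
mostly one polyp per image (weights 0.90/0.08/0.02 for 1/2/3); the
small:medium:large stratum mix 99:76:7, matching the reference
182-polyp population, apportioned by largest remainder so realized
counts sit within one of target. Semi-axis ranges per stratum are chosen
so a polyp's tight box stays inside its stratum's area band at any
orientation (small a,b in [8,15] px, medium [20,45], large [55,90]).

The `difficulty` knob scales polyp contrast up and background
noise/glare down. The *easy* preset (`easy_dataset_spec`) is
single-polyp, large-size, double-contrast, half-noise scenes: the
regime in which the desk-scale network reliably reaches high recall
within 300 iterations. Training problem sizes used by the test suite
and the acceptance script: 64 training scenes, doubled to 128 images by
the pipeline's 180-degree rotation augmentation, 16 held-out scenes,
300 iterations at batch 8.

What passing on these scenes shows — and what it does not: the
operators, wiring, gradients, training loop and the whole metric
protocol function end-to-end; it says nothing about performance on real
tissue, where texture, occlusion, blur and class imbalance dominate.
The appearance model is deliberately crude; no attempt is made to match
the intensity statistics of real endoscopy.

## Numerical choices and degenerate inputs

* All network arithmetic is float32; metrics are float64.
* Batch-norm eps 1e-5, momentum 0.1; L2-normalization scale layer on
  Conv4_3 initialized at 20 (the reference SSD convention).
* Pooling sentinel for clipped windows uses the dtype minimum, so
  inputs must be finite (activations always are).
* Zero-denominator metrics (no detections, empty stratum, no truths)
  return 0 or None with an explicit warning rather than NaN.
* An image with no ground truth is valid everywhere: matching returns
  all-background, the loss falls back to mined negatives only.
* Checkpoints are single `.npz` files carrying the serialized plan, all
  parameters and batch-norm running statistics.

## Known limitations

* No pretrained-backbone transfer: full-scale (300-input) networks
  build and run forward but are not practically trainable here.
* The numpy layer stack is single-threaded CPU code; it is sized for
  desk-scale work, not for the 100k-iteration full-scale schedule.
* Flip augmentation is the only optional train-time augmentation.
* The exact branch widths of the published full-scale model are not
  recoverable from its description; the 2.5x widening here is a
  reasoned reconstruction bounded by the reported model-size growth.
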