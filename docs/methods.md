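# Methods

## Problem and pipeline

`nervedetect` counts nerves in immunohistochemistry (IHC) rasters. In
PGP9.5/DAB-stained tissue, nerves appear as brown structures from ~25 µm²
(about 100 px at 0.5 µm/px, roughly three axon cross-sections) up to large
trunks of tens of thousands of µm², against a pale background with
blue-purple haematoxylin-counterstained nuclei and — the central difficulty —
non-specific brown staining that a colour threshold cannot distinguish from
nerves. The pipeline has five stages:

1. **Colour filter.** RGB is converted to normalised HSV; a pixel is
   stain-positive iff `(0.04, 0.2, 0.4) ≤ (h, s, v) ≤ (0.2, 1, 1)`,
   bounds inclusive on both ends (range-filter semantics; the boundary is
   then testable). Hue wrap-around is not supported — the brown range never
   crosses zero — and a lower hue above the upper is rejected rather than
   wrapped.
2. **Candidate geometry.** A 20 × 20 px morphological closing bridges stain
   fragments closer than the kernel (separated axons of one nerve);
   8-connected components above a strict 100 px pixel-area threshold become
   instances with minimal bounding boxes. 8-connectivity was chosen so thin
   diagonal axonal profiles do not fragment; the area criterion is the
   instance's pixel count, not its box area (configurable).
3. **Model.** A U-Net whose bottleneck also feeds an image-level
   classification branch; the scalar class probability, duplicated to image
   size, multiplies the pixel-wise segmentation sigmoid. A pixel of the
   gated output can exceed the strict 0.5 threshold only when both branches
   exceed it, which is how patch-level context suppresses pixel-level false
   positives. Trained end-to-end with a single binary cross-entropy loss on
   the gated output (no auxiliary classification loss).
4. **Detection.** A 160 × 160 px window slides with 50% overlap over the
   working-resolution raster (windows at the border shift inward, never
   resample); overlapping gated probabilities combine per pixel by maximum —
   equivalent to OR of the binarised maps, so stitching never loses a
   detection. Post-processing repeats stage 2 on the stitched mask and then
   merges boxes that overlap by at least 50% of the *smaller* box's area
   (intersection-over-smaller rather than IoU, so a box nested in another
   always merges; IoU is available by option). Merging iterates in
   ascending (x0, y0) order to a deterministic fixed point.
5. **Evaluation.** Hit-or-miss at object level: any positive-area overlap
   between a prediction box and an expert annotation is a hit; several boxes
   on one annotation count once; one box crossing k annotations credits all
   k (annotations, not boxes, are the sensitivity denominator). Unmatched
   boxes are adjudicated against complete ground truth (or an explicit
   adjudication list standing in for human scorers): TP_a if the box
   contains any true nerve pixel, else FP. Sensitivity is
   TPR = TP_m/(TP_m+FN); precision is PPV = TP/(TP+FP) with TP = TP_m+TP_a.
   A slide with no annotations has undefined TPR and is reported as missing.

**Overall rates are unweighted per-slide means, not pooled ratios.** On the
shipped 22-slide reference counts the pooled ratios (287/318 = 0.90,
3506/4633 = 0.76) disagree with the published overall values, while
per-slide means reproduce them exactly (0.89/0.75 for the CNN, 0.98/0.09 for
the colour filter); pooled aggregation remains available.

## Training-side pipeline

Whole slides are reduced by block-mean downsampling (factor 4 for gigapixel
inputs; factor 1 for desk-scale synthetic tiles — both ROI extraction and
inference run at the same working resolution). The colour filter proposes
ROIs via the stage-2 chain, except that candidate ROI boxes merge on *any*
overlap (not the 50% rule — at this stage the goal is one ROI per stain
cluster). An ROI is a positive training region if it intersects any expert
annotation, negative if it intersects a declared negative region and no
annotation (positive wins with a warning if both), and unlabelled — hence
unused — otherwise. Negative regions must be supplied explicitly; they model
the practice of marking areas rich in non-specific stain and free of nerves.

ROIs become 160 × 160 patches on a 50%-overlap grid: a dimension of d px
needs `ceil(d/P)·2−1` windows (one window when d ≤ P, centred and shifted
inward at raster borders). Windows are never resampled; clipping is by
inward shift, preserving pixel statistics. Pixel labels are
`colour_filter AND annotation`; negative samples carry all-false labels.
Positive samples whose filter-positive signal outside the (closing-dilated)
annotation exceeds 30% of their total filter-positive signal are dropped as
label artifacts — an automated proxy for manual curation, which can also be
mimicked with an explicit exclusion list.

Batches are balanced by construction (half positive, half negative, drawn
with replacement), with flips, 90° rotations and ±10% translations
(reflection fill) applied jointly to image and label. The augmentation
magnitudes are stipulated: the augmentation family was given, its
parameters were not. One epoch is `2·min(pool sizes)/batch_size` steps.
Training pools are sorted by a content hash before sampling, so training is
invariant to how the caller ordered the dataset. Optimisation: Adam,
learning rate 1e-4, binary cross-entropy, 250 epochs, He initialisation —
the full-scale defaults.

## Network details

Each convolution block is two 3 × 3 conv → batch-norm → ReLU stages whose
outputs are concatenated (dense-style within-block skip), so a block emits
2× its filter count. Downsampling is 2 × 2 average pooling; upsampling is
2 × 2 nearest-neighbour interpolation followed by a 2 × 2 convolution
(batch-norm before every activation). Encoder→decoder skips concatenate.
Dropout 0.5 sits between the two convolutions of the lowest-resolution
block. The classification branch is: 1 × 1 conv to 8 channels (BN+ReLU),
dropout 0.5, flatten, FC(64)+BN+ReLU, dropout 0.5, FC(1), sigmoid. Flatten
rather than pooling was chosen for determinism of shape bookkeeping.
Filter counts per level default to 16–256 doubling and are configurable;
none of the quantitative checks depends on matching a specific capacity.
The final 1 × 1 segmentation conv carries a bias and feeds the sigmoid
directly (no BN on the output layer).

The network runs on a small reverse-mode autodiff engine written in numpy
inside the package (`nervedetect.nn`): stride-1 im2col convolution, 2 × 2
average pooling, nearest-neighbour upsampling, concatenation, batch
normalisation (running statistics in inference, so inference is
deterministic), dropout, dense layers, clipped binary cross-entropy, Adam.
Tensors are float32, NHWC. Gradients were verified against central finite
differences on a small configuration. Serialisation stores config, weights
and batch-norm buffers in one `.npz`; reloaded inference is bit-identical.

Numerical choices: probabilities are clipped to [1e-7, 1−1e-7] inside the
loss; the output threshold is strictly greater than 0.5, so a gated value
of exactly 0.5 is negative; batch-norm uses momentum 0.9 and eps 1e-5
(momentum low enough that running statistics settle within short training
runs). Morphological closing pads the raster with background by the kernel
size before operating, which makes it a true closing (extensive and
idempotent) including at borders; for even kernels the erosion origin is
shifted by −1 per axis so dilation and erosion use the same translate set.

## Synthetic slides

No public dataset accompanies the real 112-slide cohort, so a seedable
generator produces IHC-like tiles with exact ground truth. It emulates:

* **Nerves** in four appearance classes — one connected formation;
  2–6 separated small formations; separated clusters; and a smooth
  low-saturation-gradient "smudge". Separated components are laid out with
  gaps of 4–14 px between painted extents so one 20 × 20 closing always
  unifies them into a single counted instance. Painted area hits the
  sampled target within ±20%; targets are log-uniform over the configured
  physical range (default 25–22,500 µm²; a lower bound below 25 µm² must be
  explicitly enabled because it is below the detection size criterion).
  Nerve colours are sampled in H∈[0.06, 0.18], S∈[0.3, 0.9] (smudges at
  the low-saturation end), V∈[0.45, 0.9] — strictly inside the filter range
  with margin enough to survive uint8 quantisation, so label extraction is
  consistent by construction. Non-smudge nerves get speckled value/saturation
  texture (focal, discrete staining); smudges stay smooth.
* **Distractors**, half inside the filter range (pale diffuse washes of
  200–1200 px that defeat the size rule, plus sub-100 px spots that do not)
  and half brown-ish but outside it (weak non-specific uptake: bright,
  desaturated, or slightly off-hue). In-range diffuse washes are the
  distractor class the colour filter cannot reject and the classifier gate
  is supposed to; out-of-range distractors exercise the colour filter
  itself. All painted objects keep >20 px separation (34 px padded
  placement) so closing never bridges two distinct objects and object
  counts stay exact; negative regions are drawn around distractors (plus
  one blank box) and are verified nerve-free.
* **Annotations**: a complete set (every nerve's padded bounding box) and
  an "expert" subset of `round(completeness × n_nerves)` entries, emulating
  coarse, deliberately incomplete manual annotation.
* **Background**: near-white with haematoxylin-like ellipses
  (H∈[0.65, 0.75]) that the filter range excludes; nuclei density ~1 per
  6000 px². This mimics the counterstain's role without stain physics.

What the generator does **not** emulate: stain deconvolution-level colour
mixing, scanner optics and focus artifacts, tissue texture, section
thickness effects, and the long-tailed morphology of real nerves. Passing
the end-to-end tests therefore shows the pipeline's machinery is correct
and that the gate suppresses colour-indistinguishable distractors on images
with these statistics — it does not certify performance on real tissue.

## The desk-scale benchmark

`nervedetect.experiments` fixes a scaled-down study: 640 × 640 px tiles at
0.5 µm/px with six nerves of 100–900 µm² (the annotated-nerve size range —
real coarse annotations start around 100 µm²) and twelve distractors;
training pool of exactly 100 positive + 100 negative patches (64 × 64 px)
drawn from successive seeded slides; a depth-2 network with (4, 8, 16)
filters; Adam at 1e-3 for 40 epochs, batch 16 (the tiny network tolerates a
10× larger rate than the full-scale configuration and converges within 40
epochs); evaluation on five held-out slides against the colour-filter
baseline, with additional detections adjudicated by the generator's truth
mask. On one CPU the whole benchmark — data synthesis, training, detection,
scoring — takes about three minutes.

The benchmark is stochastic: with different training/evaluation seeds the
CNN's object-level sensitivity typically lands between 0.85 and 1.0 and its
precision between roughly 0.55 and 1.0, while the colour-filter baseline
sits near sensitivity 1.0 / precision 0.6 (its false positives are exactly
the in-range diffuse washes, whose count per slide is nearly constant).
The variance is dominated by the training run, not the evaluation slides:
at this capacity and pool size the classifier branch's rejection boundary
for diffuse stain is sensitive to initialisation and batch order, and the
per-pixel-maximum stitching amplifies any residual window-level error
(one firing window among the ~nine covering a blob suffices for a false
positive). Under the benchmark's fixed seeds the CNN clears sensitivity
0.8 and precision 0.7 and beats the baseline's precision.

## Known limitations

* The numpy engine is single-threaded beyond BLAS and unsuitable for
  full-scale 160 × 160/250-epoch training on gigapixel cohorts; the
  architecture and training procedure are nonetheless implemented exactly
  as specified at that scale.
* The generator's appearance parameters are stipulated, not fitted to real
  slides: no quantitative appearance statistics were available to fit.
* Hue wrap-around and non-rectangular annotation geometry (polygons are
  reduced to bounding boxes on read) are unsupported.
* The classifier gate can only reject artifact classes represented in its
  negative training regions; staining artifacts that are both outside the
  colour-filter range and visually nerve-like would pass the gate unseen.
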