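# Methods

## Problem and pipeline

The package estimates canopy coverage of multi-plant hydroponic lettuce
trays from nadir RGB images. Coverage is a pixel ratio: the number of
plant-class pixels over the number of pixels in the viewing area. The
pipeline is (1) semantic segmentation of plant vs background, (2) optional
probability thresholding, (3) pixel counting — for the whole tray (group
coverage) and per 8-connected plant region (individual coverage).

## Segmentation model

The segmenter is PSPNet-shaped: a convolutional backbone produces a deep
feature map F at output stride 8 or 16; a pyramid pooling module (PPM)
average-pools F adaptively to S×S for S ∈ {1, 2, 3, 6}, reduces each
pooled map to C/4 channels with a 1×1 conv + BN + ReLU, upsamples
bilinearly, and concatenates with F (2C channels); a 3×3 fusion conv
reduces to C/4, a 1×1 classifier maps to the two class logits, and the
logits are bilinearly upsampled to input resolution and softmaxed
per pixel. Bilinear resampling uses half-pixel (align_corners=False)
sampling throughout, implemented as two separable row-stochastic matrix
products so the adjoint used in backprop is exact.

Backbones:

- **ResNet-50** (23.5 M parameters in the trunk), stride-2 stages past the
  requested output stride converted to dilation (dilations 2 and 4 at
  output stride 8). Default output stride 8, the standard PSPNet setting.
- **MobileNetV3-Large** (2 971 952 trunk parameters, matching the
  reference implementation's count exactly), same dilation conversion,
  default output stride 16. The large variant was chosen over small to
  keep the 960-channel output the PPM design assumes.

An auxiliary classifier head on the intermediate stage (1024 channels for
ResNet-50, 112 for MobileNetV3) is available but off by default; when on,
its cross-entropy is added with weight 0.4.

## CAS attention

The CAS module sits at the end of the backbone, before the PPM, and
applies three shape-preserving steps in sequence:

1. **Channel gate.** Global average- and max-pooled channel descriptors
   pass through one shared bottleneck MLP (C → C/r → C, ReLU between,
   no biases; r = 16 by default, the CBAM convention); the gate is
   σ(MLP(avg) + MLP(max)), applied per channel. With all weights zero the
   gate is exactly σ(0) = 0.5, which the tests assert to machine
   precision.
2. **Axial enhancement.** Single-head scaled dot-product self-attention
   along every row (sequence length W) and every column (sequence length
   H), with query/key/value projections over the channel dimension that
   are shared between the row and column passes; no positional encoding
   and no extra heads — the simplest member of the axial-attention family,
   since nothing in the design constrains the richer variants. The output
   is R(F) + C(F). With zero Q/K and identity V the softmax is uniform and
   the module reduces to row-mean + column-mean broadcast, the closed form
   used as its oracle.
3. **Spatial gate.** The channel-wise mean and max maps are stacked into a
   2×H×W descriptor and convolved with a single k×k filter (k = 7,
   same-padding, bias on); σ of the result gates every pixel.

The ordering channel → axial → spatial is fixed; ECA (1-D convolution of
kernel 3 over the pooled channel vector), CBAM (channel + spatial without
the axial step) and the bare axial module are available as configurable
baselines.

One design note on the channel gate: the gate is computed strictly as
σ(MLP(avg) + MLP(max)) with the bottleneck ReLU inside the MLP. A
consequence is that a descriptor that is negative everywhere is clamped by
the ReLU before the second linear layer; the unit tests encode this
(gates σ(2) and σ(0) for constant +1/−1 channels under an identity MLP)
rather than the ReLU-free closed form σ(±2).

## Training

Two phases: *freeze* (backbone parameters fixed; attention, PPM and
classifier learn) then *unfreeze* (everything learns, typically at a lower
rate). The freeze contract is enforced by recording a SHA-256 hash of all
backbone parameters each epoch. The loss is mean pixel-wise cross-entropy.
The optimizer, learning rates, per-epoch decay and epoch counts are config
values; the default optimizer is SGD with momentum 0.9 (learning rates
1e-3 freeze / 1e-4 unfreeze), with Adam available and used by the smoke
experiments because it converges in far fewer epochs on tiny batch-of-four
problems. Images are scaled to [0, 1] with no further normalisation — with
no pretrained weights there is no reference statistic to match.
Checkpoints are NumPy archives embedding the model spec as JSON, so
inference rebuilds the network from the file alone; save → load → predict
is bit-identical.

## Metrics

PA, per-class IoU and MIoU are computed from an accumulated confusion
matrix (rows = ground truth, columns = prediction), making metrics over an
image set identical to metrics over the concatenated pixels. A class
absent from both ground truth and prediction has 0/0 IoU; it is reported
as NaN and excluded from the MIoU mean rather than counted as 0, so images
lacking a class do not drag the mean. MIoU averages over both classes
(background and plant). Evaluation runs at the resized training
resolution.

## Coverage statistics

Group coverage is an exact integer ratio (plant pixels / H·W) before any
percentage formatting. Individual coverage labels 8-connected components
of the plant mask; with `min_area` = 1 the per-component fractions
partition the group coverage exactly (asserted in integer arithmetic).
Plants whose leaves touch merge into one component — an accepted
limitation of connected-component instancing in late growth stages, which
the synthetic generator deliberately reproduces. The probability threshold
τ labels a pixel plant iff P(plant) ≥ τ; τ = 0.5 equals the two-class
argmax. Histogram bins are half-open [k·w, (k+1)·w), default width one
percentage point.

## Annotation rasterization and splits

Polygon annotations follow the Labelme JSON layout. Rasterization uses the
pixel-center dialect: a pixel belongs to the polygon iff its center
(x+0.5, y+0.5) is inside under the even-odd (crossing-parity) rule;
overlapping plant polygons union. This dialect is asserted against a
point-in-polygon oracle on random rotated rectangles. Dataset splitting
shuffles each acquisition region independently with a recorded seed and
cuts at the cumulative 6:2:2 ratio with largest-remainder rounding, then
concatenates per-split across regions — so two 500-image regions yield
exactly 600/200/200.

## Synthetic scene generator

Each scene is a rows×cols grid of plants on a dark hydroponic-board
background. A plant is a rosette of 5–12 rotated elliptical leaves whose
count, elongation and green hue band depend on the variety profile (V1
compact mid-green, V2 frilly yellow-green, V3 broad deeper green, plus a
single-disc calibration profile used by geometric tests). The base plant
radius is 0.16·cell·(1 + 0.35·(stage−1)), strictly increasing over the
five growth stages, so expected coverage rises with stage; by stage 5
neighbouring rosettes overlap, exercising the merged-instance regime. The
two regions differ in illumination-gradient amplitude (0.20 vs 0.10), a
proxy for different site lighting. The mask is the analytic union of leaf
supports evaluated at pixel centers — never recovered from the rendered
colours — so additive colour noise, speckle and glints cannot move it.
Scene generation is deterministic per seed, and dataset seeds are spawned
per image so any single image is independently regenerable.

What the generator does *not* emulate: real leaf texture and venation,
specular leaf highlights, perspective (plants are drawn in orthographic
top-down view), cultivar-accurate morphology, and soil/algae clutter.
Passing tests on these scenes therefore demonstrate the correctness of
the pipeline's mechanics (shapes, gradients, metrics, coverage
arithmetic, trainability), not field-ready segmentation accuracy on real
imagery.

## Problem sizes and numerical choices

The test suite and the acceptance script size every experiment for a
single CPU core: synthetic datasets are rendered at 64×64 for counting
and trend checks (the schedule arithmetic and coverage monotonicity are
canvas-independent), and the training smoke experiment uses four 64×64
single-disc scenes, a MobileNetV3 + CAS model at output stride 8 (the
8×8 feature map keeps the largest pyramid scale valid), Adam at 5e-3 with
0.985/epoch decay, 2 freeze + 108 unfreeze epochs, and best-checkpoint
selection by train-set MIoU. Disc scenes are used because the smoke test
asks whether a separable two-class toy can be overfitted: rosette scenes
carry boundary detail finer than the stride-8 logit grid and cap MIoU
around 0.89 regardless of training length, which measures output-stride
resolution, not trainability.

Other numerical choices: BatchNorm eps 1e-5 and momentum 0.1 with
unbiased running variance; Kaiming-normal initialisation for convolutions
and linear layers (fan-in); gates are exact sigmoids, so every gate value
lies strictly inside (0, 1) for finite inputs; softmax and cross-entropy
are computed with max-subtraction for stability; ties in the channel-max
descriptor route gradient to the first maximiser.

## Known limitations

- Connected-component instancing cannot separate touching plants; a
  plant-spacing-aware correction is out of scope.
- No pretrained backbones: results on real imagery would require training
  from scratch or an external weight source.
- The NumPy tensor core is single-threaded BLAS-bound; it is sized for
  method verification and small experiments, not production training.
- Coverage is reported in image pixels; physical leaf area would require
  camera calibration, which the package does not model.
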