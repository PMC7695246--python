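# Methods

## The segmentation problem

The ventricular septum is the muscular wall between the two ventricles of
the fetal heart. In a four-chamber-view ultrasound video it appears as a
small, elongated, curved band whose thickness oscillates with the cardiac
cycle, embedded in speckle noise and acoustic shadows. Whole-frame semantic
segmentation struggles with such targets: the septum occupies a few percent
of the frame, so a pixel-wise learner spends almost all of its capacity on
background, and single-frame appearance is frequently corrupted.

The Cropping-Segmentation-Calibration (CSC) pipeline implemented here
attacks the problem the way a sonographer does: first *look near the
septum*, then *segment*, then *sanity-check against the motion of the
surrounding frames and the overall view*.

## Pipeline

For a clip with target frame `X_t` and context frames `X_{t±3,6,9}`:

1. **Cropping.** A detector proposes boxes `(cx, cy, w, h, confidence)` on
   the target frame. The box with the highest confidence strictly above
   0.01 is selected; with no such box the clip produces no segmentation and
   scores IoU = Dice = 0 downstream. The selected box is scaled by 1.2
   about its center, discretized with outward (floor/ceil) rounding,
   clipped to the canvas, and the window is resized to the crop resolution
   (256 px full scale; 64 px desk scale). All six context frames are
   cropped with the *target* frame's window so the stack stays spatially
   aligned.
2. **Segmentation.** A pix2pix-style U-net (conv + max-pool encoder,
   up-conv decoder, skip connections, ReLU, 50 % dropout before the output
   layer, sigmoid output) maps the normalized crop (`v/127.5 − 1`) to a
   per-pixel confidence map `Seg ∈ [0,1]`.
3. **Calibration.** A context encoder `E` embeds the six cropped context
   frames (stacked as six input channels) into a spatial bottleneck code;
   a frozen backbone embeds the full, uncropped frame into a 2048-vector,
   which is tiled over the bottleneck grid and concatenated channel-wise;
   a decoder `D` maps the concatenation to a per-pixel calibration map
   `Cali ∈ [0,1]`.
4. **Fusion and thresholding.** The final confidence is
   `clip(Seg + Cali, 0, 1)`; pixels strictly above 0.5 form the binary
   mask. The crop-space confidence map is also resized back into the
   original canvas (bilinear, zero outside the window) and thresholded
   there, giving the original-space mask. Binarization happens after
   restoration for original-space output (configurable).

## Training

Training is two-phase, both phases with per-pixel binary cross-entropy,
Adam (lr 0.001, β = (0.9, 0.999)), batch size 12, parameter snapshots every
5 epochs, and selection of the snapshot with the lowest validation loss
(earliest epoch on ties). One-fifth of the training clips are held out as
validation.

* **Phase 1 — context autoencoder.** `E` plus a reconstruction decoder
  `D̂` (same architecture as `D` but emitting six images and lacking the
  global branch) are trained to reproduce the six cropped context frames.
  `D̂` is then discarded and `E` frozen.
* **Phase 2 — joint training.** The U-net and `D` are trained jointly
  against the cropped ground-truth labels through the additive fusion.
  Only `θ_UNET` and `θ_D` receive updates; `θ_E` and the backbone are
  frozen (asserted bit-exact in the tests). Crops are precomputed once per
  dataset — the detector is fixed during training — and clips whose
  detection fails are excluded from training batches but scored 0 in
  evaluation.

The detector itself is *not* part of the gradient path. Two
implementations satisfy the same contract: a mask-derived **oracle**
detector with seeded jitter (used to study the rest of the pipeline under
controlled detection quality), and a trainable **reference** detector — a
small convolutional single-box regressor with a smooth-L1 box loss and a
binary cross-entropy objectness term.

## Numerical choices

These are the package's own choices where the method description leaves
the numerics open; each was adopted for a concrete, observed reason.

* **Fusion clip gradient.** `clip(Seg + Cali, 0, 1)` is non-smooth and the
  fused value can sit exactly on the clamp boundary of the loss, where the
  raw BCE derivative is of order 1/ε = 1e7 and one saturated background
  pixel would drown the gradient of the whole batch. The clip passes
  gradients straight through, and the per-pixel |dL/dp| is capped at 100
  (equivalent to evaluating the gradient with p clamped to roughly
  [1e-2, 1 − 1e-2]). The loss *value* is reported with the standard 1e-7
  clamp.
* **Residual-style calibration init.** The calibration head's bias is
  initialized at logit(0.01): the calibration map starts as a near-zero
  offset and the fused output starts as the U-net's. Initializing both
  heads co-equal (each near 0.5) stalls joint training — the sum saturates
  the [0,1] range immediately. The U-net head starts at logit(0.1), a
  standard background-heavy class-prior init.
* **Normalization.** The U-net and the context encoder use batch
  normalization (configurable). The calibration decoder does not: its
  inputs are *fixed* frozen embeddings, and batch statistics computed over
  them at batch size 12 differ enough from the running averages used at
  inference to destabilize the calibration map.
* **Batching.** Training loops drop an incomplete trailing batch (never
  the only batch). A trailing batch of one sample updates the batch-norm
  running statistics with essentially per-image statistics and measurably
  poisons inference at small n; validation loops keep every sample.
* **Capacity of the calibration branch (desk scale).** The context
  embedding is deliberately narrow (4 channels over an 8×8 grid at desk
  scale). With a wide embedding the decoder can treat the embedding as a
  clip fingerprint and memorize the training residuals — the joint system
  then beats its single-head twin on *training* loss while its U-net stays
  undertrained, and held-out accuracy falls below the crop-only variant,
  inverting the module-ablation direction. A narrow code carries the
  coarse band geometry that the context genuinely provides, not clip
  identity. The same reasoning keeps the decoder's mixing width small
  (8 channels at desk scale).
* **Interpolation.** Intensity images and confidence maps are resized
  bilinearly; binary masks nearest-neighbor (so they stay binary).
  Windows are half-open, 0-based, discretized outward so expansion never
  shrinks a detection.
* **Ties and boundaries.** Confidence gate and pixel threshold are strict
  (`> 0.01`, `> 0.5`); equal-confidence detections keep list order; equal
  validation losses keep the earlier epoch.

## The phantom generator

All training and evaluation run on synthetic clips with exact ground
truth. One clip is parameterized by canvas (640×480 px), frame rate
(40 fps), heart rate (140–160 bpm, so one cycle spans ≈ 15–17 frames and
the ±3/6/9 context offsets sample distinct phases), axis angle (0° =
vertical), band length, base thickness, fractional systolic thickening
(0.2–0.4; the band is *thicker in systole*), quadratic curvature,
multiplicative gamma speckle (mean 1, sd 0.2–0.4) and 1–3 dark shadow
wedges. The band is rendered bright between two dark chamber ellipses and
lightly blurred. Frames are deterministic in (clip seed, frame index);
datasets are byte-identical across runs with the same master seed
(per-clip seeds are splitmix-derived).

Datasets are balanced ≈ 50/50 between apical (axis within ±30° of
vertical, angles folded modulo 180°) and non-apical clips by construction:
the group is a fair coin, then the angle is uniform within the group's
angular range.

What the phantom does *not* model: anatomy beyond the band-and-chambers
sketch, probe geometry, depth-dependent attenuation, temporally coherent
shadows, out-of-plane motion, or any pathology. Passing tests therefore
demonstrate that the pipeline's machinery behaves as specified under
controlled conditions — not clinical performance.

## Evaluation protocol

Per image, IoU = TP/(TP+FP+FN) and Dice = 2TP/(2TP+FP+FN) are computed in
crop space (prediction vs. ground truth cropped with the same window) and
original space (restored prediction vs. full-frame truth). Failed
detections score 0. Means (mIoU, mDice) are arithmetic means over all
images including those zeros. Both-empty mask pairs are defined to score 1
(cannot occur on generator data, where every clip contains a band).
Stratified tables split by axis group and cardiac phase. Cross-validation
splits shuffle the ids with a seed, partition them into three near-equal
test blocks (2:1 train:test per fold) and hold out one-fifth (floor) of
each fold's remainder as validation; for 615 ids this yields
328/82/205 per fold.

## Scaled-down study sizes

Everything runs on one CPU. The desk configuration uses 64-px crops, a
depth-3/base-6 U-net, a depth-3/base-6 context encoder with a 4-channel
code, an 8-channel decoder, and a small frozen random-init backbone
(224-px input, 2048-d output; an ImageNet-pretrained VGG-16 can be plugged
in where weights are available on disk, but nothing here requires a
download). The module-ablation benchmark trains on 120 phantom clips and
evaluates on 60 (oracle detector, jitter 0.1), 10 phase-1 and 30 phase-2
epochs, three training seeds on a fixed dataset. On this benchmark the
module ordering reproduces the clinical study's direction: detection-gated
cropping is worth ≈ +0.2 mIoU over the whole-frame U-net, the calibration
branch adds a small further refinement, and crop-space scores sit at or
marginally above original-space scores. The absolute numbers are phantom
numbers; they are far higher than the clinical ones because the phantom
task is easier.

## Known limitations

* The backbone defaults to a frozen random-init CNN, which provides a
  fixed global-image sketch rather than semantic ImageNet features; its
  contribution on phantoms is accordingly small.
* The joint phase-2 objective shares credit between the U-net and the
  calibration decoder; with very few clips (tens) the decoder can still
  memorize and the U-net undertrain. The benchmark sizes avoid that
  regime; users fitting tiny datasets should prefer the crop-only
  configuration.
* Only one box per frame is considered (the selection rule makes
  multi-detection irrelevant), and the detector contract deliberately
  excludes anchor boxes and non-maximum suppression.
* Phase labels of the generator are exact; real systole/diastole labels
  would carry annotation noise that is not modeled.
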