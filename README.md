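# cscseg

Pixel-wise segmentation of the **ventricular septum** in fetal cardiac
ultrasound video with the **Cropping–Segmentation–Calibration (CSC)**
pipeline, plus an ultrasound phantom-video generator so that the whole
method trains and evaluates on one CPU with no external data.

The package is for researchers in medical image analysis who want a
self-contained, fully testable implementation of detection-gated video
segmentation: every stage — detector contract, U-net, temporal-context
calibration, two-phase training, stratified evaluation — is an importable,
seeded, deterministic component.

## The method

The septum is small, elongated, and deforms with every heartbeat; frames
are corrupted by speckle and acoustic shadows. Whole-frame segmentation
wastes nearly all capacity on background. CSC instead composes three
modules around a clip — one annotated target frame `X_t` plus six
unannotated context frames `X_{t±3,6,9}` (40 fps video, fetal heart rates
of 140–160 bpm, so the offsets sample distinct cardiac phases):

1. **Cropping** — a detector proposes boxes; the most confident box with
   confidence > 0.01 is expanded ×1.2 and defines the crop window
   `Crop(·)` (no qualifying box ⇒ no segmentation, scored 0);
2. **Segmentation** — a pix2pix-style U-net maps the cropped frame to
   per-pixel confidences, `Seg(X_t) = UNET(Crop(X_t, X_t))` ∈ [0,1];
3. **Calibration** — an encoder `E` embeds the six cropped context
   frames, a frozen backbone embeds the full frame into a 2048-vector,
   and a decoder `D` turns their concatenation into a calibration map:
   `Cali(·) = D(E(Crop(X_{t±3,6,9})) ‖ VGG(X_t))`.

The final confidence is the element-wise sum `Seg + Cali`, clipped to
[0,1] and thresholded at 0.5; the crop-space mask is also restored into
the original canvas. Training is two-phase (Phase 1: context autoencoder
for `E`; Phase 2: joint `UNET` + `D` against ground-truth labels through
the fusion), with per-pixel binary cross-entropy, Adam at lr 0.001, batch
size 12, checkpoints every 5 epochs and lowest-validation-loss selection.
Evaluation reports mIoU and mDice per image in crop and original space,
with detection failures scored 0, stratified by cardiac-axis group
(apical = septum within ±30° of vertical) and cardiac phase
(systole/diastole), over three-fold 2:1 cross-validation splits with
one-fifth validation.

See `docs/methods.md` for the full model description, the numerical
choices, and what the phantom generator does and does not emulate.

## Worked example

```python
from cscseg import CSCConfig, CSCModel, make_clips

train_clips = make_clips(60, master_seed=7)   # phantom clips with ground truth
test_clips = make_clips(20, master_seed=8)
model = CSCModel(train_clips, CSCConfig.desk())  # 64 px crops, tiny nets
results = model.fit(seed=0)                   # phase 1 + phase 2
print(results.summary(test_clips))
```

prints

```
CSC segmentation results
============================================================
modules:              U-net + crop + ED + backbone
crop size:            64 px   detector: oracle
train / val clips:    48 / 12   detection failures: 0
phase 1 (context AE): 10 epochs, best val BCE 0.4209
phase 2 (joint):      30 epochs, best val BCE 0.1460
------------------------------------------------------------
held-out clips:       20
      crop space:  mIoU 0.7415  mDice 0.8468  (n=20, failed=0)
  original space:  mIoU 0.7278  mDice 0.8371  (n=20, failed=0)
============================================================
```

Reading the report: 60 clips were split 48/12 into training and
validation (the one-fifth rule); the context autoencoder reached a
reconstruction cross-entropy of 0.42 (an uninformative all-0.5 predictor
scores ln 2 ≈ 0.69); the joint phase selected the checkpoint with
validation loss 0.146; and on 20 unseen clips the fused, thresholded
masks overlap the ground truth with a mean IoU of ≈ 0.73–0.74. Crop-space
scores sit slightly above original-space scores because restoring the
crop to the full canvas can only lose boundary precision.

`results.evaluate(clips)` returns the per-image records as a DataFrame
(IoU, Dice, detection flag, axis and phase group, per space) for custom
aggregation, and `results.predict(clip)` runs single-clip inference.
The same workflow is scriptable from the shell:

```bash
cscseg simulate --n 60 --seed 7 --out data/
cscseg train-phase2 --data data/ --out run/ --config config.yaml
cscseg infer --model run/ --clips data/ --out pred/
cscseg evaluate --model run/ --data data/ --out eval/
cscseg ablate --out ablation/            # module-combination benchmark
```

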