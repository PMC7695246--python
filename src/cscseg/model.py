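"""Model facade: build a CSC model from clips, fit it, evaluate the results.

``CSCModel`` holds the data and configuration; ``fit()`` runs detection-based
crop preparation, Phase-1 context-autoencoder training and Phase-2 joint
training, and returns a ``CSCResults`` carrying the trained networks, the
loss histories, and ``predict`` / ``evaluate`` / ``summary`` methods.

Module combinations are configuration, which is how the ablation study is
expressed: ``use_crop`` toggles detection-gated cropping (off = plain U-net
on the resized full frame), ``use_ed`` the temporal encoder–decoder,
``use_backbone`` the global-image branch.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import calibration
from .detector import (EXPAND_FACTOR, MIN_CONFIDENCE, DetectorModel, detect,
                       select_box, train_reference_detector)
from .geometry import crop, make_crop_record, normalize_input, resize
from .inference import CSCModels, CSCResult, FrameClip, csc_infer, threshold_mask
from .evaluation import evaluate_results, summarize
from .nn import CalibDecoder, ContextEncoder, GlobalBackbone, UNet
from .phantom import PhantomClip, derive_seed, load_dataset
from .training import Checkpoint, TrainConfig, train_phase1, train_phase2
from .unet import build_unet

__all__ = ["CSCConfig", "CSCModel", "CSCResults", "FitSample", "prepare_samples"]


@dataclass(frozen=True)
class CSCConfig:
    """Pipeline and training configuration.

    The full-scale defaults mirror the method's stated settings (256 px
    crops, 224 px / 2048-d backbone, Adam lr 0.001, batch 12, 200 epochs,
    5-epoch checkpoints).  ``desk()`` gives a small configuration for
    CPU-scale experiments on phantoms.
    """

    # module combination
    use_crop: bool = True
    use_ed: bool = True
    use_backbone: bool = True
    # geometry
    crop_size: int = 256
    expand: float = EXPAND_FACTOR
    # segmentation net
    unet_depth: int = 4
    unet_base: int = 16
    batch_norm: bool = True
    # calibration nets
    ed_depth: int = 4
    enc_base: int = 16
    ctx_channels: int = 32
    mix_channels: int = 32
    cali_init_conf: float = 0.01   # initial output level of the calibration head
    cali_batch_norm: bool = False  # decoder D runs on fixed embeddings; see docs
    backbone_input: int = 224
    # detector
    detector_kind: str = "oracle"
    detector_jitter: float = 0.1
    detector_input: int = 64
    detector_epochs: int = 60
    min_confidence: float = MIN_CONFIDENCE
    # training
    epochs_phase1: int = 200
    epochs_phase2: int = 200
    batch_size: int = 12
    learning_rate: float = 0.001
    checkpoint_interval: int = 5
    val_fraction: float = 0.2

    def __post_init__(self):
        if self.use_ed and not self.use_crop:
            raise ValueError("the temporal encoder-decoder requires cropping "
                             "(use_crop=True); uncropped ED variants are out of scope")
        if self.use_backbone and not self.use_ed:
            raise ValueError("the global backbone feeds the calibration decoder; "
                             "enable use_ed to use it")

    @classmethod
    def desk(cls, **overrides) -> "CSCConfig":
        """Small CPU-scale configuration: 64 px crops, tiny networks."""
        base = dict(crop_size=64, unet_depth=3, unet_base=6,
                    ed_depth=3, enc_base=6, ctx_channels=4, mix_channels=8,
                    backbone_input=224, epochs_phase1=10, epochs_phase2=30)
        base.update(overrides)
        return cls(**base)


@dataclass
class FitSample:
    """Precomputed per-clip training inputs (crops are static during training)."""

    clip_id: str
    detected: bool
    record: object | None = None
    x_crop: np.ndarray | None = None    # (S, S) float32 in [-1, 1]
    y_crop: np.ndarray | None = None    # (S, S) float32 {0, 1}
    ctx_crop: np.ndarray | None = None  # (S, S, 6) float32 in [-1, 1]
    glob: np.ndarray | None = None      # (2048,) float32
    x_full: np.ndarray | None = None    # no-crop variant input
    y_full: np.ndarray | None = None


def prepare_samples(clips: Sequence[PhantomClip], det: DetectorModel,
                    cfg: CSCConfig, backbone: GlobalBackbone | None,
                    seed: int) -> list[FitSample]:
    """Detect, select, expand, crop and embed every clip once.

    Crops are computed with the detector that will be used at inference and
    cached; clips whose detection fails are flagged and later excluded from
    training batches (they still count as failures in evaluation).
    """
    s = cfg.crop_size
    out = []
    for i, pc in enumerate(clips):
        samp = FitSample(clip_id=pc.clip_id, detected=False)
        if not cfg.use_crop:
            samp.detected = True
            samp.x_full = normalize_input(resize(pc.clip.target.pixels, (s, s)))
            samp.y_full = resize(pc.truth, (s, s), mask=True).astype(np.float32)
            out.append(samp)
            continue
        dets = detect(det, pc.clip.target, truth_mask=pc.truth,
                      seed=derive_seed(seed, 50000 + i))
        box = select_box(dets, cfg.min_confidence)
        record = None if box is None else make_crop_record(
            box, pc.clip.target.size, cfg.expand, (s, s))
        if record is None:
            out.append(samp)
            continue
        samp.detected = True
        samp.record = record
        samp.x_crop = normalize_input(crop(pc.clip.target, record))
        samp.y_crop = crop(pc.truth, record, mask=True).astype(np.float32)
        if cfg.use_ed:
            samp.ctx_crop = normalize_input(
                np.stack([crop(f, record) for f in pc.clip.context], axis=-1))
        if backbone is not None:
            samp.glob = calibration.embed_global(backbone, pc.clip.target)
        out.append(samp)
    return out


def _stack(samples: list[FitSample], attr: str) -> np.ndarray:
    return np.stack([getattr(s, attr) for s in samples]).astype(np.float32)


class CSCModel:
    """A CSC segmentation model over a set of clips.

    Parameters
    ----------
    clips : sequence of PhantomClip
        Training clips with ground-truth masks and labels.
    config : CSCConfig, optional
        Defaults to the full-scale configuration.
    """

    def __init__(self, clips: Sequence[PhantomClip], config: CSCConfig | None = None):
        if len(clips) == 0:
            raise ValueError("no clips")
        self.clips = list(clips)
        self.config = config or CSCConfig()

    @classmethod
    def from_directory(cls, path, config: CSCConfig | None = None) -> "CSCModel":
        return cls(load_dataset(path), config)

    # -- fitting ----------------------------------------------------------
    def fit(self, seed: int = 0, encoder_state: dict | None = None,
            phases: tuple[str, ...] = ("1", "2")) -> "CSCResults":
        """Run the two training phases and return the fitted results.

        One-fifth of the clips (seeded shuffle) are held out as validation
        for checkpoint selection in both phases.  ``encoder_state`` skips
        Phase 1 by loading a previously trained context encoder.
        """
        cfg = self.config
        rng = np.random.default_rng(derive_seed(seed, 3))
        order = rng.permutation(len(self.clips))
        n_val = max(int(round(len(self.clips) * cfg.val_fraction)), 1) \
            if len(self.clips) > 1 else 0
        val_clips = [self.clips[i] for i in order[:n_val]]
        train_clips = [self.clips[i] for i in order[n_val:]]

        det = self._build_detector(train_clips, seed)
        backbone = None
        if cfg.use_backbone:
            backbone = GlobalBackbone(input_size=cfg.backbone_input,
                                      seed=derive_seed(seed, 15), frozen=True)
        train_s = [s for s in prepare_samples(train_clips, det, cfg, backbone, seed)
                   if s.detected]
        val_all = prepare_samples(val_clips, det, cfg, backbone,
                                  derive_seed(seed, 4))
        val_s = [s for s in val_all if s.detected]
        if not train_s or not val_s:
            raise ValueError("detection failed on too many clips to train")
        n_failed = (len(train_clips) - len(train_s)) + (len(val_all) - len(val_s))

        unet = build_unet(cfg.crop_size, cfg.unet_depth, cfg.unet_base,
                          cfg.batch_norm, seed=derive_seed(seed, 11))
        encoder = decoder = None
        hist1 = hist2 = None
        ckpts1: list[Checkpoint] = []
        if cfg.use_ed:
            encoder = ContextEncoder(input_size=cfg.crop_size, depth=cfg.ed_depth,
                                     base_channels=cfg.enc_base,
                                     out_channels=cfg.ctx_channels,
                                     batch_norm=cfg.batch_norm,
                                     seed=derive_seed(seed, 12))
            if encoder_state is not None:
                encoder.load_state_dict(encoder_state)
            elif "1" in phases:
                recon = CalibDecoder(ctx_channels=cfg.ctx_channels, glob_dim=0,
                                     mix_channels=cfg.mix_channels, depth=cfg.ed_depth,
                                     out_channels=6, batch_norm=cfg.batch_norm,
                                     seed=derive_seed(seed, 13))
                tc1 = TrainConfig(epochs=cfg.epochs_phase1, batch_size=cfg.batch_size,
                                  learning_rate=cfg.learning_rate,
                                  checkpoint_interval=cfg.checkpoint_interval,
                                  seed=derive_seed(seed, 21))
                hist1, ckpts1 = train_phase1(encoder, recon,
                                             _stack(train_s, "ctx_crop"),
                                             _stack(val_s, "ctx_crop"), tc1)
            encoder.freeze()
            from .nn.networks import logit
            decoder = CalibDecoder(ctx_channels=cfg.ctx_channels,
                                   glob_dim=GlobalBackbone.OUT_DIM if cfg.use_backbone else 0,
                                   mix_channels=cfg.mix_channels, depth=cfg.ed_depth,
                                   out_channels=1, batch_norm=cfg.cali_batch_norm,
                                   head_bias=logit(cfg.cali_init_conf),
                                   seed=derive_seed(seed, 14))

        ckpts2: list[Checkpoint] = []
        if "2" in phases:
            xattr, yattr = ("x_crop", "y_crop") if cfg.use_crop else ("x_full", "y_full")
            X, Y = _stack(train_s, xattr)[..., None], _stack(train_s, yattr)[..., None]
            Xv, Yv = _stack(val_s, xattr)[..., None], _stack(val_s, yattr)[..., None]
            ctx = ctxv = glob = globv = None
            if cfg.use_ed:
                ctx = self._embed_all(encoder, train_s)
                ctxv = self._embed_all(encoder, val_s)
                if cfg.use_backbone:
                    glob = _stack(train_s, "glob")
                    globv = _stack(val_s, "glob")
            tc2 = TrainConfig(epochs=cfg.epochs_phase2, batch_size=cfg.batch_size,
                              learning_rate=cfg.learning_rate,
                              checkpoint_interval=cfg.checkpoint_interval,
                              seed=derive_seed(seed, 22))
            hist2, ckpts2 = train_phase2(unet, decoder, X, Y, Xv, Yv, tc2,
                                         ctx, glob, ctxv, globv)

        models = CSCModels(unet=unet, detector=det, encoder=encoder, decoder=decoder,
                           backbone=backbone, expand=cfg.expand,
                           min_confidence=cfg.min_confidence,
                           crop_size=(cfg.crop_size, cfg.crop_size))
        return CSCResults(model=self, models=models, fit_seed=seed,
                          history_phase1=hist1, history_phase2=hist2,
                          checkpoints_phase1=ckpts1, checkpoints_phase2=ckpts2,
                          n_train=len(train_s), n_val=len(val_s),
                          n_detection_failures=n_failed)

    def _build_detector(self, train_clips: list[PhantomClip], seed: int) -> DetectorModel:
        cfg = self.config
        if cfg.detector_kind == "oracle":
            return DetectorModel(kind="oracle", jitter_frac=cfg.detector_jitter,
                                 min_confidence=cfg.min_confidence)
        frames = [pc.clip.target.pixels for pc in train_clips]
        boxes = [pc.tight_box for pc in train_clips]
        det, _ = train_reference_detector(frames, boxes, input_size=cfg.detector_input,
                                          epochs=cfg.detector_epochs,
                                          batch_size=cfg.batch_size,
                                          learning_rate=cfg.learning_rate,
                                          seed=derive_seed(seed, 31))
        det.min_confidence = cfg.min_confidence
        return det

    @staticmethod
    def _embed_all(encoder: ContextEncoder, samples: list[FitSample],
                   batch: int = 12) -> np.ndarray:
        ctx = _stack(samples, "ctx_crop")
        return np.concatenate([encoder.forward(ctx[i:i + batch])
                               for i in range(0, len(ctx), batch)])


@dataclass
class CSCResults:
    """Fitted CSC model: trained networks, training diagnostics, evaluation."""

    model: CSCModel
    models: CSCModels
    fit_seed: int
    history_phase1: pd.DataFrame | None
    history_phase2: pd.DataFrame | None
    checkpoints_phase1: list[Checkpoint]
    checkpoints_phase2: list[Checkpoint]
    n_train: int
    n_val: int
    n_detection_failures: int

    # -- inference --------------------------------------------------------
    def predict(self, clip, *, truth_mask: np.ndarray | None = None,
                detect_seed: int = 0) -> CSCResult:
        """Segment one clip (a FrameClip, or a PhantomClip whose truth feeds
        the oracle detector)."""
        if isinstance(clip, PhantomClip):
            truth_mask = clip.truth if truth_mask is None else truth_mask
            clip = clip.clip
        cfg = self.model.config
        if cfg.use_crop:
            return csc_infer(self.models, clip, truth_mask=truth_mask,
                             detect_seed=detect_seed)
        s = cfg.crop_size
        x = normalize_input(resize(clip.target.pixels, (s, s)))
        conf = self.models.unet.forward(x[None, :, :, None])[0, :, :, 0]
        original = resize(conf, clip.target.size)
        return CSCResult(detected=True, crop_record=None,
                         crop_mask=conf, original_mask=original,
                         binary_crop=threshold_mask(conf),
                         binary_original=threshold_mask(original),
                         clip_id=clip.clip_id)

    # -- evaluation -------------------------------------------------------
    def evaluate(self, clips: Sequence[PhantomClip], seed: int = 0) -> pd.DataFrame:
        """Per-image IoU/Dice records on held-out clips.

        Crop-space scores are reported only for cropping configurations.
        """
        results, truths, labels = [], [], []
        for i, pc in enumerate(clips):
            results.append(self.predict(pc, detect_seed=derive_seed(seed, 90000 + i)))
            truths.append(pc.truth)
            labels.append(dict(axis_angle_deg=pc.axis_angle_deg, phase=pc.phase_label))
        spaces = ("crop", "original") if self.model.config.use_crop else ("original",)
        return evaluate_results(results, truths, labels, spaces=spaces)

    def summary(self, test_clips: Sequence[PhantomClip] | None = None) -> str:
        """Human-readable fit report, optionally with held-out metrics."""
        cfg = self.model.config
        combo = ["U-net"]
        if cfg.use_crop:
            combo.append("crop")
        if cfg.use_ed:
            combo.append("ED")
        if cfg.use_backbone:
            combo.append("backbone")
        lines = [
            "CSC segmentation results",
            "=" * 60,
            f"modules:              {' + '.join(combo)}",
            f"crop size:            {cfg.crop_size} px   detector: {cfg.detector_kind}",
            f"train / val clips:    {self.n_train} / {self.n_val}"
            f"   detection failures: {self.n_detection_failures}",
        ]
        if self.history_phase1 is not None:
            best1 = min(c.validation_loss for c in self.checkpoints_phase1)
            lines.append(f"phase 1 (context AE): {len(self.history_phase1)} epochs, "
                         f"best val BCE {best1:.4f}")
        if self.history_phase2 is not None:
            best2 = min(c.validation_loss for c in self.checkpoints_phase2)
            lines.append(f"phase 2 (joint):      {len(self.history_phase2)} epochs, "
                         f"best val BCE {best2:.4f}")
        if test_clips is not None:
            tab = summarize(self.evaluate(test_clips))
            lines.append("-" * 60)
            lines.append(f"held-out clips:       {len(test_clips)}")
            for _, row in tab.iterrows():
                lines.append(f"  {row['space']:>8s} space:  mIoU {row['miou']:.4f}  "
                             f"mDice {row['mdice']:.4f}  (n={row['n']}, "
                             f"failed={row['n_failed']})")
        lines.append("=" * 60)
        return "\n".join(lines)

    def plot_training(self, ax=None):
        """Plot train/validation loss curves of both phases.

        Returns the matplotlib axes (created on a new figure when ``ax`` is
        None).
        """
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        for name, hist in (("phase 1", self.history_phase1),
                           ("phase 2", self.history_phase2)):
            if hist is None:
                continue
            ax.plot(hist.epoch, hist.train_loss, label=f"{name} train")
            vals = hist.dropna(subset=["val_loss"])
            ax.plot(vals.epoch, vals.val_loss, "o--", label=f"{name} val")
        ax.set_xlabel("epoch")
        ax.set_ylabel("BCE loss")
        ax.legend()
        return ax

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        """Write networks (npz) and config (json) under ``path``."""
        p = Path(path)
        p.mkdir(parents=True, exist_ok=True)
        (p / "config.json").write_text(json.dumps(asdict(self.model.config), indent=1))
        meta = {"fit_seed": self.fit_seed, "n_train": self.n_train,
                "n_val": self.n_val,
                "n_detection_failures": self.n_detection_failures}
        (p / "fit.json").write_text(json.dumps(meta, indent=1))
        nets = {"unet": self.models.unet, "encoder": self.models.encoder,
                "decoder": self.models.decoder, "backbone": self.models.backbone,
                "detector": self.models.detector.net}
        for name, net in nets.items():
            if net is not None:
                np.savez(p / f"{name}.npz",
                         __config__=json.dumps(net.config), **net.state_dict())
        if self.history_phase1 is not None:
            self.history_phase1.to_csv(p / "phase1_metrics.csv", index=False)
        if self.history_phase2 is not None:
            self.history_phase2.to_csv(p / "phase2_metrics.csv", index=False)

    @classmethod
    def load(cls, path, clips: Sequence[PhantomClip] | None = None) -> "CSCResults":
        """Reload a saved results directory (histories are not restored)."""
        from .nn import ReferenceDetectorNet
        p = Path(path)
        cfg = CSCConfig(**json.loads((p / "config.json").read_text()))
        meta = json.loads((p / "fit.json").read_text())

        def load_net(name, ctor):
            f = p / f"{name}.npz"
            if not f.exists():
                return None
            with np.load(f) as z:
                st = {k: z[k] for k in z.files if k != "__config__"}
                net = ctor(**json.loads(str(z["__config__"])))
            net.load_state_dict(st)
            return net

        unet = load_net("unet", UNet)
        encoder = load_net("encoder", ContextEncoder)
        if encoder is not None:
            encoder.freeze()
        decoder = load_net("decoder", CalibDecoder)
        backbone = load_net("backbone", GlobalBackbone)
        detnet = load_net("detector", ReferenceDetectorNet)
        det = DetectorModel(kind=cfg.detector_kind, net=detnet,
                            jitter_frac=cfg.detector_jitter,
                            min_confidence=cfg.min_confidence)
        if detnet is not None:
            det.input_size = (detnet.input_size, detnet.input_size)
        models = CSCModels(unet=unet, detector=det, encoder=encoder, decoder=decoder,
                           backbone=backbone, expand=cfg.expand,
                           min_confidence=cfg.min_confidence,
                           crop_size=(cfg.crop_size, cfg.crop_size))
        dummy = CSCModel.__new__(CSCModel)
        dummy.clips = list(clips) if clips else []
        dummy.config = cfg
        return CSCResults(model=dummy, models=models, fit_seed=meta["fit_seed"],
                          history_phase1=None, history_phase2=None,
                          checkpoints_phase1=[], checkpoints_phase2=[],
                          n_train=meta["n_train"], n_val=meta["n_val"],
                          n_detection_failures=meta["n_detection_failures"])
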