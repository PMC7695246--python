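"""End-to-end CSC inference on a clip.

Pipeline per clip: detect on the target frame -> select the most confident
box (> 0.01) -> expand x1.2, crop target *and* the six context frames with
the same window -> U-net on the cropped target, calibration decoder on the
context embedding and global embedding -> additive fusion -> threshold at
0.5 -> restore the confidence map to the original canvas and threshold
there as well.  A clip whose detection fails yields all-zero masks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import calibration
from .detector import (EXPAND_FACTOR, MIN_CONFIDENCE, DetectorModel, detect,
                       select_box)
from .geometry import (CropRecord, ImageFrame, crop, make_crop_record,
                       normalize_input, restore)
from .nn import CalibDecoder, ContextEncoder, GlobalBackbone, UNet
from .unet import seg_forward

__all__ = ["CONTEXT_OFFSETS", "context_indices", "FrameClip", "CSCResult",
           "CSCModels", "threshold_mask", "csc_infer", "SEG_THRESHOLD"]

#: context frames sit at these offsets around the target frame
CONTEXT_OFFSETS = (-9, -6, -3, 3, 6, 9)

#: per-pixel confidence threshold for binarization
SEG_THRESHOLD = 0.5


def context_indices(target_index: int, n_frames: int | None = None) -> tuple[int, ...]:
    """Frame indices of the six context frames around a target index."""
    idx = tuple(target_index + o for o in CONTEXT_OFFSETS)
    last = (n_frames - 1) if n_frames is not None else None
    if idx[0] < 0 or (last is not None and idx[-1] > last):
        raise ValueError(f"target index {target_index} leaves context offsets "
                         f"{CONTEXT_OFFSETS} out of range")
    return idx


@dataclass(frozen=True)
class FrameClip:
    """The unit of inference: one target frame plus six context frames."""

    target: ImageFrame
    context: tuple[ImageFrame, ...]
    clip_id: str = ""

    def __post_init__(self):
        if len(self.context) != 6:
            raise ValueError(f"a clip needs exactly six context frames, got {len(self.context)}")


@dataclass
class CSCResult:
    """Per-clip inference output in crop and original space."""

    detected: bool
    crop_record: CropRecord | None = None
    crop_mask: np.ndarray | None = None       # confidence, crop resolution
    original_mask: np.ndarray | None = None   # confidence, original resolution
    binary_crop: np.ndarray | None = None
    binary_original: np.ndarray | None = None
    clip_id: str = ""


@dataclass
class CSCModels:
    """Trained components plus the pipeline hyper-parameters."""

    unet: UNet
    detector: DetectorModel
    encoder: ContextEncoder | None = None
    decoder: CalibDecoder | None = None
    backbone: GlobalBackbone | None = None
    expand: float = EXPAND_FACTOR
    min_confidence: float = MIN_CONFIDENCE
    crop_size: tuple[int, int] = (256, 256)

    @property
    def use_calibration(self) -> bool:
        return self.encoder is not None and self.decoder is not None


def threshold_mask(mask: np.ndarray, thr: float = SEG_THRESHOLD) -> np.ndarray:
    """Binarize a confidence mask: pixel = 1 iff confidence strictly > thr."""
    if not 0.0 < thr < 1.0:
        raise ValueError(f"threshold must be in (0,1), got {thr}")
    return (np.asarray(mask) > thr).astype(np.uint8)


def _failed(models: CSCModels, clip: FrameClip) -> CSCResult:
    h, w = clip.target.pixels.shape
    cw, chh = models.crop_size
    return CSCResult(detected=False, crop_record=None,
                     crop_mask=np.zeros((chh, cw), dtype=np.float32),
                     original_mask=np.zeros((h, w), dtype=np.float32),
                     binary_crop=np.zeros((chh, cw), dtype=np.uint8),
                     binary_original=np.zeros((h, w), dtype=np.uint8),
                     clip_id=clip.clip_id)


def csc_infer(models: CSCModels, clip: FrameClip, *,
              truth_mask: np.ndarray | None = None, detect_seed: int = 0,
              binarize_original: str = "after_restore") -> CSCResult:
    """Run the full pipeline on one clip.

    ``truth_mask``/``detect_seed`` are forwarded to the oracle detector when
    that detector kind is configured.  All context frames are cropped with
    the window derived from the *target* frame's detection, which guarantees
    their spatial alignment with the segmentation crop.

    ``binarize_original`` controls the original-space mask: thresholding the
    restored confidence map (``"after_restore"``, default) or restoring the
    crop-space binary mask with nearest-neighbor (``"before_restore"``).
    The two differ only at interpolated boundary pixels.
    """
    if binarize_original not in ("after_restore", "before_restore"):
        raise ValueError(f"unknown binarize_original {binarize_original!r}")
    dets = detect(models.detector, clip.target, truth_mask=truth_mask, seed=detect_seed)
    box = select_box(dets, models.min_confidence)
    if box is None:
        return _failed(models, clip)
    record = make_crop_record(box, clip.target.size, models.expand, models.crop_size)
    if record is None:
        return _failed(models, clip)

    x_crop = normalize_input(crop(clip.target, record))
    seg = seg_forward(models.unet, x_crop)
    if models.use_calibration:
        ctx = np.stack([crop(f, record) for f in clip.context])
        ctx_emb = calibration.embed_context(models.encoder, ctx)
        glob = None
        if models.backbone is not None:
            glob = calibration.embed_global(models.backbone, clip.target)
        conf = calibration.fuse(seg, calibration.cali_forward(models.decoder, ctx_emb, glob))
    else:
        conf = seg

    original = restore(conf, record)
    binary_crop = threshold_mask(conf)
    if binarize_original == "after_restore":
        binary_original = threshold_mask(original)
    else:
        from .geometry import resize
        x0, x1, y0, y1 = record.window
        binary_original = np.zeros_like(original, dtype=np.uint8)
        binary_original[y0:y1, x0:x1] = resize(binary_crop, (x1 - x0, y1 - y0),
                                               mask=True)
    return CSCResult(detected=True, crop_record=record,
                     crop_mask=conf.astype(np.float32),
                     original_mask=original,
                     binary_crop=binary_crop,
                     binary_original=binary_original,
                     clip_id=clip.clip_id)
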