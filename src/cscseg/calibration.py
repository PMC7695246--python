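"""Calibration stage: temporal-context embedding, global-image embedding,
calibration decoding and additive fusion with the segmentation output.

The six cropped context frames enter the context encoder stacked as six
input channels; the full (uncropped) frame is embedded by a frozen backbone
into a 2048-vector which is tiled over the context embedding's spatial grid
and concatenated channel-wise before decoding.  The decoder emits per-pixel
calibration confidences that are added to the U-net output and clipped back
to [0, 1].
"""

from __future__ import annotations

import numpy as np

from .geometry import _pixels, normalize_input, resize
from .nn import CalibDecoder, ContextEncoder, GlobalBackbone

__all__ = ["embed_context", "embed_global", "cali_forward", "fuse",
           "prepare_context_stack", "prepare_backbone_input"]


def prepare_context_stack(context_crops: np.ndarray) -> np.ndarray:
    """(6, S, S) cropped context frames -> (S, S, 6) float32 in [-1, 1]."""
    ctx = np.asarray(context_crops)
    if ctx.ndim != 3 or ctx.shape[0] != 6:
        raise ValueError(f"expected exactly six context frames, got shape {ctx.shape}")
    return np.ascontiguousarray(normalize_input(ctx).transpose(1, 2, 0))


def embed_context(encoder: ContextEncoder, context_crops: np.ndarray) -> np.ndarray:
    """Embed six cropped context frames into the spatial bottleneck code."""
    x = prepare_context_stack(context_crops)
    return encoder.forward(x[None])[0]


def prepare_backbone_input(backbone: GlobalBackbone, original) -> np.ndarray:
    """Full frame -> (S, S, 3) normalized input (grayscale replicated)."""
    px = _pixels(original)
    s = backbone.input_size
    x = normalize_input(resize(px, (s, s)))
    return np.repeat(x[:, :, None], 3, axis=2)


def embed_global(backbone: GlobalBackbone, original) -> np.ndarray:
    """Embed the full original frame into a 2048-length vector."""
    x = prepare_backbone_input(backbone, original)
    v = backbone.forward(x[None])[0]
    return v


def cali_forward(decoder: CalibDecoder, ctx_embedding: np.ndarray,
                 glob: np.ndarray | None = None) -> np.ndarray:
    """Decode (context embedding || tiled global vector) to a calibration mask."""
    glob_b = None if glob is None else np.asarray(glob, dtype=np.float32)[None]
    return decoder.forward(ctx_embedding[None], glob_b)[0, :, :, 0]


def fuse(seg: np.ndarray, cali: np.ndarray) -> np.ndarray:
    """Element-wise addition of the two confidence maps, clipped to [0, 1]."""
    seg = np.asarray(seg)
    cali = np.asarray(cali)
    if seg.shape != cali.shape:
        raise ValueError(f"shape mismatch: {seg.shape} vs {cali.shape}")
    return np.clip(seg + cali, 0.0, 1.0)
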