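"""Segmentation stage: the pix2pix-style U-net over cropped frames.

``build_unet`` constructs the network from a flat config; ``seg_forward``
runs inference on a single normalized crop.  Training happens in
:mod:`cscseg.training`.
"""

from __future__ import annotations

import numpy as np

from .nn import UNet

__all__ = ["build_unet", "seg_forward"]


def build_unet(input_size: int = 256, depth: int = 4, base_channels: int = 16,
               batch_norm: bool = True, seed: int = 0) -> UNet:
    """U-net mapping a normalized crop to a per-pixel confidence mask.

    ``input_size`` must be divisible by ``2**depth``.  The default 256 px
    matches the crop resolution; desk-scale experiments use 64 px with few
    channels.
    """
    return UNet(input_size=input_size, depth=depth, base_channels=base_channels,
                in_channels=1, batch_norm=batch_norm, seed=seed)


def seg_forward(model: UNet, cropped: np.ndarray) -> np.ndarray:
    """Confidence mask for one normalized crop (values in [-1, 1]).

    Deterministic: dropout is inactive outside training.
    """
    x = np.asarray(cropped, dtype=np.float32)
    if x.ndim != 2:
        raise ValueError(f"expected a 2-D crop, got shape {x.shape}")
    if x.min() < -1.0 - 1e-6 or x.max() > 1.0 + 1e-6:
        raise ValueError("input must be normalized to [-1, 1]")
    return model.forward(x[None, :, :, None])[0, :, :, 0]
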