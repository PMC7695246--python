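"""Coordinate conventions, box geometry, crop/restore transforms, PNG I/O.

Conventions used throughout the package:

* images are 2-D numpy arrays indexed ``[y, x]`` (row-major), 8-bit ``uint8``
  for intensities and ``{0, 1}`` ``uint8`` for binary masks;
* sizes are ``(width, height)`` tuples, matching how box widths/heights are
  stated;
* crop windows are 0-based half-open rectangles ``[x0, x1) x [y0, y1)``;
* detection failure is an expected, data-dependent outcome and is signalled
  by ``None`` returns, never by exceptions.

Intensity images are resized bilinearly; binary masks with nearest-neighbor
so they stay binary.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "ImageFrame", "DetBox", "CropRecord",
    "scale_box", "box_to_window", "make_crop_record", "tight_box",
    "crop", "restore", "resize", "normalize_input",
    "read_png", "write_png", "read_mask", "write_mask",
]

Size = tuple[int, int]  # (width, height)


@dataclass(frozen=True)
class ImageFrame:
    """One grayscale video frame."""

    pixels: np.ndarray  # (H, W) uint8
    frame_index: int = 0

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.dtype != np.uint8:
            raise ValueError("ImageFrame.pixels must be a 2-D uint8 array")
        object.__setattr__(self, "pixels", px)

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def size(self) -> Size:
        return (self.width, self.height)


@dataclass(frozen=True)
class DetBox:
    """Center/size bounding box with a detection confidence.

    Coordinates are pixels of ``reference_size = (width, height)``; boxes can
    be re-expressed on another pixel grid with :meth:`to_reference`.
    """

    cx: float
    cy: float
    w: float
    h: float
    confidence: float = 1.0
    reference_size: Size | None = None

    def __post_init__(self):
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"box sides must be positive, got w={self.w}, h={self.h}")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must be in [0,1], got {self.confidence}")

    def to_reference(self, size: Size) -> "DetBox":
        """Rescale coordinates from ``reference_size`` to ``size`` pixels."""
        if self.reference_size is None:
            raise ValueError("box has no reference_size to map from")
        sx = size[0] / self.reference_size[0]
        sy = size[1] / self.reference_size[1]
        return replace(self, cx=self.cx * sx, cy=self.cy * sy,
                       w=self.w * sx, h=self.h * sy, reference_size=size)


@dataclass(frozen=True)
class CropRecord:
    """Everything needed to crop and to restore crop-space output.

    ``window = (x0, x1, y0, y1)`` is half-open in original-image pixels.
    """

    window: tuple[int, int, int, int]
    original_size: Size
    crop_output_size: Size

    def __post_init__(self):
        x0, x1, y0, y1 = self.window
        ow, oh = self.original_size
        if not (0 <= x0 < x1 <= ow and 0 <= y0 < y1 <= oh):
            raise ValueError(f"window {self.window} invalid for canvas {self.original_size}")

    @property
    def window_size(self) -> Size:
        x0, x1, y0, y1 = self.window
        return (x1 - x0, y1 - y0)


def scale_box(box: DetBox, factor: float) -> DetBox:
    """Multiply the box sides by ``factor`` about its center (the x1.2 rule)."""
    if factor <= 0:
        raise ValueError(f"scale factor must be positive, got {factor}")
    return replace(box, w=box.w * factor, h=box.h * factor)


def box_to_window(box: DetBox, canvas: Size) -> tuple[int, int, int, int] | None:
    """Discretize a box to an integer window, clipped to the canvas.

    Rounds outward (floor/ceil) so discretization never shrinks the box, then
    intersects with the canvas.  Returns ``None`` (detection failure) when
    the intersection is empty.
    """
    cw, ch = canvas
    if cw < 1 or ch < 1:
        raise ValueError(f"canvas must be at least 1x1, got {canvas}")
    x0 = int(np.floor(box.cx - box.w / 2))
    x1 = int(np.ceil(box.cx + box.w / 2))
    y0 = int(np.floor(box.cy - box.h / 2))
    y1 = int(np.ceil(box.cy + box.h / 2))
    x0, x1 = max(x0, 0), min(x1, cw)
    y0, y1 = max(y0, 0), min(y1, ch)
    if x0 >= x1 or y0 >= y1:
        return None
    return (x0, x1, y0, y1)


def make_crop_record(box: DetBox, canvas: Size, expand: float = 1.2,
                     out_size: Size = (256, 256)) -> CropRecord | None:
    """Expand a detection by ``expand``, discretize and clip it to the canvas.

    Returns ``None`` when the expanded box falls entirely outside the canvas.
    """
    window = box_to_window(scale_box(box, expand), canvas)
    if window is None:
        return None
    return CropRecord(window=window, original_size=canvas, crop_output_size=out_size)


def tight_box(mask: np.ndarray, confidence: float = 1.0) -> DetBox | None:
    """Tight bounding box of a binary mask's foreground, or None if empty."""
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        return None
    x0, x1 = int(xs.min()), int(xs.max()) + 1
    y0, y1 = int(ys.min()), int(ys.max()) + 1
    return DetBox(cx=(x0 + x1) / 2, cy=(y0 + y1) / 2, w=x1 - x0, h=y1 - y0,
                  confidence=confidence,
                  reference_size=(mask.shape[1], mask.shape[0]))


def resize(arr: np.ndarray, out_size: Size, *, mask: bool = False) -> np.ndarray:
    """Resize to ``(width, height)``: bilinear for intensities/confidences,
    nearest-neighbor when ``mask=True``."""
    arr = np.asarray(arr)
    if arr.shape[::-1] == tuple(out_size):
        return arr.copy()
    if mask:
        im = Image.fromarray(arr.astype(np.uint8))
        out = im.resize(out_size, Image.NEAREST)
        return np.asarray(out, dtype=arr.dtype)
    if arr.dtype == np.uint8:
        out = Image.fromarray(arr).resize(out_size, Image.BILINEAR)
        return np.asarray(out, dtype=np.uint8)
    out = Image.fromarray(arr.astype(np.float32), mode="F").resize(out_size, Image.BILINEAR)
    return np.asarray(out, dtype=np.float32)


def _pixels(image) -> np.ndarray:
    return image.pixels if isinstance(image, ImageFrame) else np.asarray(image)


def crop(image, record: CropRecord, *, mask: bool = False) -> np.ndarray:
    """Extract the record's window and resize it to ``crop_output_size``."""
    px = _pixels(image)
    if (px.shape[1], px.shape[0]) != tuple(record.original_size):
        raise ValueError(f"image size {px.shape[::-1]} does not match "
                         f"record.original_size {record.original_size}")
    x0, x1, y0, y1 = record.window
    return resize(px[y0:y1, x0:x1], record.crop_output_size, mask=mask)


def restore(mask_crop: np.ndarray, record: CropRecord) -> np.ndarray:
    """Resize a crop-space confidence mask back to the window size and embed
    it at the window position in a zero canvas of the original size."""
    m = np.asarray(mask_crop, dtype=np.float32)
    if (m.shape[1], m.shape[0]) != tuple(record.crop_output_size):
        raise ValueError(f"mask size {m.shape[::-1]} does not match "
                         f"record.crop_output_size {record.crop_output_size}")
    x0, x1, y0, y1 = record.window
    ow, oh = record.original_size
    canvas = np.zeros((oh, ow), dtype=np.float32)
    canvas[y0:y1, x0:x1] = resize(m, (x1 - x0, y1 - y0))
    return canvas


def normalize_input(image) -> np.ndarray:
    """Map 8-bit intensities affinely onto [-1, 1]: v -> v/127.5 - 1."""
    px = _pixels(image)
    return (px.astype(np.float32) / 127.5) - 1.0


def read_png(path) -> np.ndarray:
    """Read a PNG as 8-bit grayscale (RGB converted by luminance)."""
    path = Path(path)
    try:
        with Image.open(path) as im:
            if im.mode != "L":
                im = im.convert("L")
            return np.asarray(im, dtype=np.uint8)
    except (OSError, SyntaxError) as e:
        raise OSError(f"cannot read PNG {path}: {e}") from e


def write_png(path, image) -> None:
    px = _pixels(image)
    if px.dtype != np.uint8:
        raise ValueError("write_png expects uint8 pixels")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(px, mode="L").save(path, format="PNG")


def read_mask(path) -> np.ndarray:
    """Read a {0,255}-coded mask PNG into a {0,1} uint8 array."""
    return (read_png(path) > 127).astype(np.uint8)


def write_mask(path, mask: np.ndarray) -> None:
    m = np.asarray(mask)
    if not np.isin(m, (0, 1)).all():
        raise ValueError("binary mask must contain only {0,1}")
    write_png(path, (m * 255).astype(np.uint8))
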