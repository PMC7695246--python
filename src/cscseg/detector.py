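"""Detection contract for the cropping stage.

The cropping stage needs only a box proposer: produce candidate boxes for
the septum, select the most confident one (strictly above a confidence
floor, 0.01 by default), expand it by 1.2 and crop.  Two interchangeable
implementations are provided:

* an **oracle detector** that derives the tight box from a ground-truth mask
  and perturbs it with seeded jitter — used to study the rest of the
  pipeline under a controllable detection quality;
* a **reference detector**, a small convolutional single-box regressor
  trained on phantom data with a smooth-L1 box loss and a binary
  cross-entropy objectness term.

Both honor the same interface, so downstream code never knows which is in
use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import DetBox, _pixels, normalize_input, resize, tight_box
from .nn import Adam, ReferenceDetectorNet

__all__ = ["DetectorModel", "select_box", "oracle_detect", "detect",
           "train_reference_detector", "MIN_CONFIDENCE", "EXPAND_FACTOR"]

#: a box is usable only with confidence strictly greater than this
MIN_CONFIDENCE = 0.01
#: selected boxes are expanded by this factor before cropping
EXPAND_FACTOR = 1.2


@dataclass
class DetectorModel:
    """Detector state: either 'oracle' (mask-derived) or 'reference' (trained)."""

    kind: str = "oracle"
    net: ReferenceDetectorNet | None = None
    input_size: tuple[int, int] = (416, 416)
    min_confidence: float = MIN_CONFIDENCE
    jitter_frac: float = 0.0  # oracle only

    def __post_init__(self):
        if self.kind not in ("oracle", "reference"):
            raise ValueError(f"unknown detector kind {self.kind!r}")
        if not 0.0 <= self.min_confidence <= 1.0:
            raise ValueError("min_confidence must be in [0,1]")


def select_box(detections: list[DetBox], min_confidence: float = MIN_CONFIDENCE) -> DetBox | None:
    """Pick the detection with maximal confidence strictly above the floor.

    Ties keep the earliest box in list order.  Returns ``None`` (detection
    failure) when no detection qualifies; the pipeline then produces no
    segmentation for the clip.
    """
    if not 0.0 <= min_confidence <= 1.0:
        raise ValueError("min_confidence must be in [0,1]")
    best = None
    for box in detections:
        if box.confidence > min_confidence and (best is None or box.confidence > best.confidence):
            best = box
    return best


def oracle_detect(mask: np.ndarray, jitter_frac: float = 0.0, seed: int = 0) -> list[DetBox]:
    """Tight box of a ground-truth mask with seeded multiplicative jitter.

    Each of (cx, cy, w, h) is perturbed by a uniform relative amount in
    [-jitter_frac, jitter_frac] (center offsets relative to the side
    lengths).  With nonzero jitter the confidence is drawn uniformly from
    (0.01, 1]; with jitter 0 the output is the exact tight box with
    confidence 1, fully deterministic.  An empty mask yields no detections.
    """
    if jitter_frac < 0:
        raise ValueError("jitter_frac must be non-negative")
    box = tight_box(np.asarray(mask))
    if box is None:
        return []
    if jitter_frac == 0.0:
        return [box]
    rng = np.random.default_rng(seed)
    dx, dy, dw, dh = rng.uniform(-jitter_frac, jitter_frac, size=4)
    w = max(box.w * (1.0 + dw), 1.0)
    h = max(box.h * (1.0 + dh), 1.0)
    conf = float(MIN_CONFIDENCE + (1.0 - MIN_CONFIDENCE) * rng.random())
    return [DetBox(cx=box.cx + dx * box.w, cy=box.cy + dy * box.h, w=w, h=h,
                   confidence=conf, reference_size=box.reference_size)]


def _net_forward_boxes(model: DetectorModel, frames: np.ndarray,
                       native_size: tuple[int, int]) -> list[list[DetBox]]:
    """Run the reference net on a batch of frames already resized/normalized."""
    out = model.net.forward(frames)
    s = 1.0 / (1.0 + np.exp(-out.astype(np.float64)))  # (N, 5) in (0,1)
    w, h = native_size
    boxes = []
    for cx, cy, bw, bh, conf in s:
        boxes.append([DetBox(cx=cx * w, cy=cy * h, w=max(bw * w, 1.0),
                             h=max(bh * h, 1.0), confidence=float(conf),
                             reference_size=native_size)])
    return boxes


def detect(model: DetectorModel, image, *, truth_mask: np.ndarray | None = None,
           seed: int = 0) -> list[DetBox]:
    """Produce candidate boxes on the image's native pixel grid.

    The oracle detector requires ``truth_mask`` (it is a test stand-in for a
    trained object detector); the reference detector runs its network on the
    frame resized to ``model.input_size``.
    """
    px = _pixels(image)
    if model.kind == "oracle":
        if truth_mask is None:
            raise ValueError("oracle detector needs truth_mask")
        return oracle_detect(truth_mask, model.jitter_frac, seed)
    x = normalize_input(resize(px, model.input_size))[None, :, :, None]
    return _net_forward_boxes(model, x, (px.shape[1], px.shape[0]))[0]


def _smooth_l1(x: np.ndarray, beta: float = 0.1) -> tuple[float, np.ndarray]:
    ax = np.abs(x)
    quad = ax < beta
    loss = np.where(quad, 0.5 * x * x / beta, ax - 0.5 * beta)
    grad = np.where(quad, x / beta, np.sign(x))
    return float(loss.mean()), grad / x.size


def train_reference_detector(frames: list[np.ndarray], boxes: list[DetBox],
                             *, input_size: int = 64, epochs: int = 60,
                             batch_size: int = 12, learning_rate: float = 1e-3,
                             seed: int = 0) -> tuple[DetectorModel, list[float]]:
    """Train the single-box regressor on (frame, tight box) pairs.

    Boxes must carry a ``reference_size``; targets are normalized to [0,1] by
    the frame size.  Returns the model and the per-epoch training loss.
    """
    if len(frames) == 0:
        raise ValueError("empty training set")
    if len(frames) != len(boxes):
        raise ValueError("frames and boxes must be parallel lists")
    rng = np.random.default_rng(seed)
    net = ReferenceDetectorNet(input_size=input_size, seed=seed)
    opt = Adam(net.params(), lr=learning_rate)
    X = np.stack([normalize_input(resize(_pixels(f), (input_size, input_size)))
                  for f in frames])[..., None]
    T = np.array([[b.cx / b.reference_size[0], b.cy / b.reference_size[1],
                   b.w / b.reference_size[0], b.h / b.reference_size[1]]
                  for b in boxes], dtype=np.float64)
    n = len(frames)
    losses = []
    for _ in range(epochs):
        order = rng.permutation(n)
        ep_loss = 0.0
        for i in range(0, n, batch_size):
            idx = order[i:i + batch_size]
            out = net.forward(X[idx], train=True)
            s = 1.0 / (1.0 + np.exp(-out.astype(np.float64)))
            box_loss, gbox = _smooth_l1(s[:, :4] - T[idx])
            # objectness: every phantom frame contains the septum
            p = np.clip(s[:, 4], 1e-7, 1 - 1e-7)
            obj_loss = float(-np.log(p).mean())
            gobj = (-1.0 / p) / p.size
            gs = np.concatenate([gbox, gobj[:, None]], axis=1)
            gout = (gs * s * (1.0 - s)).astype(np.float32)
            opt.zero_grad()
            net.backward(gout)
            opt.step()
            ep_loss += (box_loss + obj_loss) * len(idx)
        losses.append(ep_loss / n)
    model = DetectorModel(kind="reference", net=net, input_size=(input_size, input_size))
    return model, losses
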