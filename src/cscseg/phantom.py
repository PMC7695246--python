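"""Ultrasound phantom-video generator.

Emulates what the pipeline consumes from a fetal four-chamber-view clip: a
small bright elongated band (the ventricular septum) whose thickness
oscillates with the cardiac cycle, flanked by dark chamber ellipses,
degraded by multiplicative speckle and dark shadow wedges.  Defaults follow
the acquisition conditions of the clinical recordings the method targets:
640 x 480 px frames at 40 fps with heart rates in the 140-160 bpm range, so
one cardiac cycle spans roughly 15-17 frames and the +-3/6/9-frame context
offsets sample distinct phases.

Every clip carries exact ground truth: the target-frame mask, its tight
bounding box, the cardiac-phase label (systole = thicker band) and the axis
angle (0 deg = vertical, apical within +-30 deg of vertical).  Datasets are
balanced ~50/50 apical/non-apical by construction: the axis group is drawn
by fair coin, then the angle uniformly within the group's angular range.

No anatomical realism is attempted beyond these features; the generator
exists so training and evaluation run with known truth and no downloads.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry import DetBox, ImageFrame, read_mask, read_png, tight_box, write_mask, write_png
from .inference import CONTEXT_OFFSETS, FrameClip

__all__ = ["PhantomConfig", "PhantomClip", "septum_mask", "render_frame",
           "phase_label", "generate_clip", "make_clips", "generate_dataset",
           "load_dataset", "derive_seed"]


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of one phantom clip."""

    canvas: tuple[int, int] = (640, 480)   # (width, height) px
    fps: float = 40.0
    heart_rate_bpm: float = 150.0
    axis_angle_deg: float = 20.0           # 0 = vertical
    septum_length: float = 200.0           # px
    base_thickness: float = 16.0           # px
    thickness_amplitude: float = 0.3       # fractional systolic thickening
    curvature: float = 0.0015              # 1/px, quadratic bow of the band
    speckle_scale: float = 0.3             # std of multiplicative speckle
    shadow_count: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if not 0.0 <= self.thickness_amplitude < 1.0:
            raise ValueError("thickness_amplitude must be in [0, 1)")
        if self.base_thickness < 2:
            raise ValueError("base_thickness must be at least 2 px")


@dataclass(frozen=True)
class PhantomClip:
    """A frame clip with its ground truth and stratification labels."""

    clip: FrameClip
    truth: np.ndarray                 # (H, W) uint8 {0,1}, target frame
    axis_angle_deg: float
    phase_label: str                  # 'systole' | 'diastole'
    tight_box: DetBox
    config: PhantomConfig

    @property
    def clip_id(self) -> str:
        return self.clip.clip_id


def _band_coords(cfg: PhantomConfig):
    w, h = cfg.canvas
    y, x = np.mgrid[0:h, 0:w].astype(np.float32)
    a = np.deg2rad(cfg.axis_angle_deg)
    # axis direction measured from vertical; (x right, y down)
    ux, uy = np.sin(a), np.cos(a)
    dx, dy = x - (w - 1) / 2.0, y - (h - 1) / 2.0
    s = dx * ux + dy * uy            # along-axis coordinate
    d = dx * uy - dy * ux            # across-axis coordinate
    return s, d


def _thickness(cfg: PhantomConfig, t: int) -> tuple[float, float]:
    f = cfg.heart_rate_bpm / 60.0
    cyc = float(np.sin(2.0 * np.pi * f * t / cfg.fps))
    return cfg.base_thickness * (1.0 + cfg.thickness_amplitude * cyc), cyc


def phase_label(cfg: PhantomConfig, t: int) -> str:
    """'systole' while the band is thickening above baseline (sin > 0)."""
    return "systole" if _thickness(cfg, t)[1] > 0 else "diastole"


def septum_mask(cfg: PhantomConfig, t: int) -> np.ndarray:
    """Binary mask of the curved band at frame index ``t``."""
    thick, _ = _thickness(cfg, t)
    if thick < 1.0:
        raise ValueError(f"degenerate band: thickness {thick:.2f} px < 1")
    s, d = _band_coords(cfg)
    band = (np.abs(d - cfg.curvature * s * s) <= thick / 2.0) & \
           (np.abs(s) <= cfg.septum_length / 2.0)
    return band.astype(np.uint8)


def render_frame(cfg: PhantomConfig, t: int) -> ImageFrame:
    """Render one frame: bright band, dark chambers, speckle, shadows.

    Deterministic in (cfg.seed, t); the speckle/shadow noise stream of each
    frame index is independent.
    """
    w, h = cfg.canvas
    thick, _ = _thickness(cfg, t)
    s, d = _band_coords(cfg)
    dc = d - cfg.curvature * s * s
    img = np.full((h, w), 35.0, dtype=np.float32)
    # chambers: dark ellipses flanking the band
    off = thick / 2.0 + 0.22 * cfg.septum_length
    for side in (-1.0, 1.0):
        ell = (s / (0.42 * cfg.septum_length)) ** 2 + \
              ((dc - side * off) / (0.20 * cfg.septum_length)) ** 2
        img[ell <= 1.0] = 8.0
    band = (np.abs(dc) <= thick / 2.0) & (np.abs(s) <= cfg.septum_length / 2.0)
    img[band] = 190.0
    img = gaussian_filter(img, sigma=1.5)

    rng = np.random.default_rng(derive_seed(cfg.seed, 7919 + t))
    if cfg.speckle_scale > 0:
        shape = 1.0 / cfg.speckle_scale ** 2
        img *= rng.gamma(shape, 1.0 / shape, size=img.shape).astype(np.float32)
    if cfg.shadow_count > 0:
        y, x = np.mgrid[0:h, 0:w].astype(np.float32)
        for _ in range(cfg.shadow_count):
            xa = rng.uniform(0.1 * w, 0.9 * w)
            center = rng.uniform(-0.4, 0.4)          # wedge direction (rad from down)
            half = rng.uniform(0.05, 0.18)           # angular half-width (rad)
            depth = rng.uniform(0.35, 0.6)           # attenuation strength
            ang = np.arctan2(x - xa, y + 1.0)
            img *= 1.0 - depth * (np.abs(ang - center) <= half)
    return ImageFrame(np.clip(img, 0, 255).astype(np.uint8), frame_index=t)


def generate_clip(cfg: PhantomConfig, clip_id: str = "") -> PhantomClip:
    """Render one clip: the target frame plus context at +-3, 6, 9 frames.

    The target index is drawn (seeded) within one cardiac period past the
    earliest index that leaves room for the context offsets, so every clip
    samples a different phase of one continuous cycle.
    """
    rng = np.random.default_rng(derive_seed(cfg.seed, 104729))
    period = max(int(round(cfg.fps * 60.0 / cfg.heart_rate_bpm)), 1)
    t0 = -CONTEXT_OFFSETS[0] + int(rng.integers(0, period))
    target = render_frame(cfg, t0)
    context = tuple(render_frame(cfg, t0 + o) for o in CONTEXT_OFFSETS)
    truth = septum_mask(cfg, t0)
    box = tight_box(truth)
    if box is None:  # pragma: no cover - config invariants keep the band on canvas
        raise ValueError("phantom truth mask is empty; check the config")
    return PhantomClip(clip=FrameClip(target=target, context=context, clip_id=clip_id),
                       truth=truth, axis_angle_deg=cfg.axis_angle_deg,
                       phase_label=phase_label(cfg, t0), tight_box=box, config=cfg)


def derive_seed(master_seed: int, k: int) -> int:
    """Splitmix64-style derivation of independent per-item seeds (< 2^31)."""
    mask = (1 << 64) - 1
    z = (int(master_seed) + int(k) * 0x9E3779B97F4A7C15) & mask
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & mask
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & mask
    return (z ^ (z >> 31)) & 0x7FFFFFFF


def sample_config(rng: np.random.Generator, seed: int,
                  canvas: tuple[int, int] = (640, 480)) -> PhantomConfig:
    """Draw one clip's parameters from the study-condition distributions."""
    apical = rng.random() < 0.5
    if apical:
        u = rng.uniform(0.0, 60.0)
        angle = u if u <= 30.0 else 120.0 + u
    else:
        angle = rng.uniform(30.0, 150.0)
    scale = min(canvas) / 480.0
    return PhantomConfig(
        canvas=canvas,
        heart_rate_bpm=rng.uniform(140.0, 160.0),
        axis_angle_deg=float(angle),
        septum_length=float(rng.uniform(160.0, 240.0) * scale),
        base_thickness=float(max(rng.uniform(12.0, 20.0) * scale, 2.0)),
        thickness_amplitude=float(rng.uniform(0.2, 0.4)),
        curvature=float(rng.uniform(-0.002, 0.002) / scale),
        speckle_scale=float(rng.uniform(0.2, 0.4)),
        shadow_count=int(rng.integers(1, 4)),
        seed=seed,
    )


def make_clips(n: int, master_seed: int,
               canvas: tuple[int, int] = (640, 480)) -> list[PhantomClip]:
    """Generate ``n`` clips in memory with independently-seeded parameters."""
    rng = np.random.default_rng(derive_seed(master_seed, 1))
    return [generate_clip(sample_config(rng, derive_seed(master_seed, 1000 + k), canvas),
                          clip_id=f"clip_{k:04d}")
            for k in range(n)]


def generate_dataset(n: int, master_seed: int, out_dir) -> list[PhantomClip]:
    """Generate ``n`` clips and write them under ``out_dir``.

    Layout per clip: ``clip_<k>/frame_<offset>.png`` (offset 0 is the
    target), ``mask.png`` ({0,255}-coded truth) and ``label.json``.
    Byte-identical across runs with the same ``master_seed``.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise OSError(f"cannot create output directory {out}: {e}") from e
    clips = make_clips(n, master_seed)
    for pc in clips:
        d = out / pc.clip_id
        d.mkdir(exist_ok=True)
        write_png(d / "frame_+0.png", pc.clip.target)
        for off, frame in zip(CONTEXT_OFFSETS, pc.clip.context):
            write_png(d / f"frame_{off:+d}.png", frame)
        write_mask(d / "mask.png", pc.truth)
        b = pc.tight_box
        label = {
            "clip_id": pc.clip_id,
            "axis_angle_deg": pc.axis_angle_deg,
            "phase": pc.phase_label,
            "box": {"cx": b.cx, "cy": b.cy, "w": b.w, "h": b.h,
                    "confidence": b.confidence},
            "seed": pc.config.seed,
            "config": asdict(pc.config),
        }
        (d / "label.json").write_text(json.dumps(label, indent=1, sort_keys=True))
    return clips


def load_dataset(root) -> list[PhantomClip]:
    """Load a dataset written by :func:`generate_dataset`."""
    root = Path(root)
    clips = []
    for d in sorted(p for p in root.iterdir() if p.is_dir()):
        label = json.loads((d / "label.json").read_text())
        cfgd = label["config"]
        cfgd["canvas"] = tuple(cfgd["canvas"])
        cfg = PhantomConfig(**cfgd)
        target = ImageFrame(read_png(d / "frame_+0.png"))
        context = tuple(ImageFrame(read_png(d / f"frame_{o:+d}.png"))
                        for o in CONTEXT_OFFSETS)
        truth = read_mask(d / "mask.png")
        box = DetBox(reference_size=(truth.shape[1], truth.shape[0]), **label["box"])
        clips.append(PhantomClip(
            clip=FrameClip(target=target, context=context, clip_id=label["clip_id"]),
            truth=truth, axis_angle_deg=label["axis_angle_deg"],
            phase_label=label["phase"], tight_box=box, config=cfg))
    return clips
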