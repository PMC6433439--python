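"""Seeded generator of endoscopy-like scenes with ground-truth boxes.

Real gastroscopy frames are 560x475 true-color images: a reddish mucosal
background with uneven illumination (vignette), sensor speckle and a few
specular highlights, containing one to a few roughly elliptical polyp
protrusions. The generator emulates exactly those gross features — a
shaded ellipse with a highlight on a textured reddish background — and
nothing subtler; it exists so the whole pipeline (resizing, training,
coordinate restoration, size strata) is exercisable without any data
download, not to imitate tissue appearance.

Polyp sizes are sampled per stratum of the evaluation protocol
(small <= 32x32 px, medium <= 96x96, large above, in the 560x475 frame),
with the stratum mix defaulting to the 99:76:7 proportions of the
protocol's reference population. All sampling is driven by a single
integer seed; rendering the same spec twice is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image

from .preprocess import AnnotatedImage, Box, read_voc_xml, write_voc_xml

__all__ = ["PolypSpec", "SceneSpec", "DatasetSpec", "easy_dataset_spec",
           "sample_scene_specs", "render_scene", "generate_dataset", "load_dataset",
           "DEFAULT_FRAME", "DEFAULT_STRATA_MIX"]

DEFAULT_FRAME = (560, 475)  # (W, H)
# small : medium : large polyp proportions of the reference population
DEFAULT_STRATA_MIX = (99 / 182, 76 / 182, 7 / 182)

# semi-axis ranges per stratum, chosen so the tight bounding box of any
# orientation stays inside the stratum's area band (area = 4*ex*ey):
# small  a,b in [8, 15]   -> box area in [256, 900]      <= 1024
# medium a,b in [20, 45]  -> box area in [1600, 8100]    in (1024, 9216]
# large  a,b in [55, 90]  -> box area in [12100, 32400]  > 9216
_AXIS_RANGES = {"small": (8.0, 15.0), "medium": (20.0, 45.0), "large": (55.0, 90.0)}
# the easy regime narrows the large band so scene difficulty is homogeneous
_EASY_AXIS_RANGE = (60.0, 82.0)


@dataclass(frozen=True)
class PolypSpec:
    center: tuple[float, float]      # (cx, cy) pixels
    semi_axes: tuple[float, float]   # (a, b) pixels
    orientation: float               # radians
    brightness: float                # peak color lift, in [0, 1] units

    def extents(self) -> tuple[float, float]:
        """Half-widths (ex, ey) of the tight axis-aligned bounding box."""
        a, b = self.semi_axes
        c, s = np.cos(self.orientation), np.sin(self.orientation)
        return (float(np.hypot(a * c, b * s)), float(np.hypot(a * s, b * c)))

    def bounding_box(self, frame: tuple[int, int]) -> Box:
        ex, ey = self.extents()
        cx, cy = self.center
        return Box(cx - ex, cy - ey, cx + ex, cy + ey, frame=frame)


@dataclass(frozen=True)
class SceneSpec:
    """Everything needed to render one frame deterministically."""

    seed: int
    image_id: str
    polyps: tuple[PolypSpec, ...] = ()
    frame: tuple[int, int] = DEFAULT_FRAME
    base_color: tuple[float, float, float] = (0.58, 0.26, 0.22)
    vignette: float = 0.45           # brightness drop at the corners
    speckle: float = 0.02            # gaussian noise sigma
    n_highlights: int = 3            # specular glints on the mucosa

    def __post_init__(self):
        if not 0 <= len(self.polyps) <= 3:
            raise ValueError("a scene holds 0-3 polyps")
        w, h = self.frame
        for p in self.polyps:
            ex, ey = p.extents()
            cx, cy = p.center
            if not (ex <= cx <= w - ex and ey <= cy <= h - ey):
                raise ValueError(f"polyp ellipse at {p.center} leaves the {self.frame} frame")


@dataclass(frozen=True)
class DatasetSpec:
    """A batch of scenes: size, polyp-count weights, stratum mix, contrast."""

    n_images: int
    seed: int = 0
    frame: tuple[int, int] = DEFAULT_FRAME
    polyp_count_weights: tuple[float, ...] = (0.0, 0.90, 0.08, 0.02)  # P(0..3 polyps)
    strata_mix: tuple[float, float, float] = DEFAULT_STRATA_MIX
    difficulty: float = 1.0  # >1 = easier: more polyp contrast, less noise/glare
    brightness_range: tuple[float, float] = (0.18, 0.28)  # pre-difficulty color lift
    axis_ranges: dict[str, tuple[float, float]] | None = None  # per-stratum override

    def __post_init__(self):
        if self.n_images <= 0:
            raise ValueError("n_images must be positive")
        if len(self.polyp_count_weights) != 4 or min(self.polyp_count_weights) < 0:
            raise ValueError("polyp_count_weights must be 4 non-negative weights for 0-3")
        if min(self.strata_mix) < 0 or sum(self.strata_mix) <= 0:
            raise ValueError("strata mix must be non-negative and not all zero")


def easy_dataset_spec(n_images: int, seed: int = 0) -> DatasetSpec:
    """High-contrast, low-noise single-polyp scenes of large size — the
    regime a desk-scale detector can learn in a few hundred iterations."""
    return DatasetSpec(n_images=n_images, seed=seed,
                       polyp_count_weights=(0.0, 1.0, 0.0, 0.0),
                       strata_mix=(0.0, 0.0, 1.0), difficulty=2.0,
                       brightness_range=(0.24, 0.30),
                       axis_ranges={"large": _EASY_AXIS_RANGE})


def _apportion(total: int, weights: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of ``total`` into len(weights) bins."""
    w = np.asarray(weights, dtype=float)
    quota = total * w / w.sum()
    counts = np.floor(quota).astype(int)
    rem = total - counts.sum()
    order = np.argsort(-(quota - counts), kind="stable")
    counts[order[:rem]] += 1
    return counts


def sample_scene_specs(spec: DatasetSpec) -> list[SceneSpec]:
    """Draw the scene parameters for a whole dataset.

    Polyp counts follow ``polyp_count_weights``; the pooled polyps are
    apportioned over the size strata by largest remainder, so realized
    stratum totals sit within one of the target proportions.
    """
    rng = np.random.default_rng(spec.seed)
    w, h = spec.frame
    counts = rng.choice(4, size=spec.n_images,
                        p=np.array(spec.polyp_count_weights) / sum(spec.polyp_count_weights))
    total = int(counts.sum())
    strata_counts = _apportion(total, np.array(spec.strata_mix))
    labels = np.repeat(["small", "medium", "large"], strata_counts)
    rng.shuffle(labels)
    label_iter = iter(labels)

    scenes = []
    for i in range(spec.n_images):
        polyps = []
        taken: list[Box] = []
        for _ in range(counts[i]):
            stratum = next(label_iter)
            ranges = {**_AXIS_RANGES, **(spec.axis_ranges or {})}
            lo, hi = ranges[stratum]
            b_lo, b_hi = spec.brightness_range
            for _attempt in range(50):
                a, b = rng.uniform(lo, hi, size=2)
                theta = rng.uniform(0, np.pi)
                p = PolypSpec(center=(0.0, 0.0), semi_axes=(float(a), float(b)),
                              orientation=float(theta),
                              brightness=float(rng.uniform(b_lo, b_hi) * spec.difficulty))
                ex, ey = p.extents()
                cx = rng.uniform(ex + 4, w - ex - 4)
                cy = rng.uniform(ey + 4, h - ey - 4)
                p = replace(p, center=(float(cx), float(cy)))
                box = p.bounding_box(spec.frame)
                if all(_box_iou(box, t) < 0.2 for t in taken):
                    break
            polyps.append(p)
            taken.append(p.bounding_box(spec.frame))
        scenes.append(SceneSpec(seed=int(rng.integers(0, 2**31 - 1)),
                                image_id=f"scene_{spec.seed:05d}_{i:04d}",
                                polyps=tuple(polyps), frame=spec.frame,
                                speckle=0.02 / spec.difficulty,
                                n_highlights=max(0, round(3 / spec.difficulty))))
    return scenes


def _box_iou(a: Box, b: Box) -> float:
    iw = min(a.xmax, b.xmax) - max(a.xmin, b.xmin)
    ih = min(a.ymax, b.ymax) - max(a.ymin, b.ymin)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    return inter / (a.area + b.area - inter)


def render_scene(spec: SceneSpec) -> AnnotatedImage:
    """Render one frame; each polyp's tight bounding box is its label."""
    rng = np.random.default_rng(spec.seed)
    w, h = spec.frame
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float32)
    img = np.empty((h, w, 3), dtype=np.float32)
    img[:] = spec.base_color

    # radial vignette around a jittered optical center
    ocx = w / 2 + rng.uniform(-w * 0.05, w * 0.05)
    ocy = h / 2 + rng.uniform(-h * 0.05, h * 0.05)
    r2 = ((xx - ocx) ** 2 + (yy - ocy) ** 2) / ((w / 2) ** 2 + (h / 2) ** 2)
    img *= (1.0 - spec.vignette * r2)[..., None]

    # broad low-frequency mottling of the mucosa
    for _ in range(4):
        bx, by = rng.uniform(0, w), rng.uniform(0, h)
        sig = rng.uniform(0.15, 0.35) * max(w, h)
        amp = rng.uniform(-0.05, 0.05)
        img += amp * np.exp(-(((xx - bx) ** 2 + (yy - by) ** 2) / (2 * sig**2)))[..., None]

    for p in spec.polyps:
        a, b = p.semi_axes
        cx, cy = p.center
        c, s = np.cos(p.orientation), np.sin(p.orientation)
        u = ((xx - cx) * c + (yy - cy) * s) / a
        v = (-(xx - cx) * s + (yy - cy) * c) / b
        rho = np.sqrt(u * u + v * v)
        inside = np.clip((1.0 - rho) / 0.08, 0.0, 1.0)  # soft rim, zero at rho=1
        dome = np.sqrt(np.clip(1.0 - np.minimum(rho, 1.0) ** 2, 0.0, 1.0))
        shade = inside * (0.45 + 0.55 * dome)
        tint = np.array([1.0, 0.55, 0.45], dtype=np.float32) * p.brightness
        img += shade[..., None] * tint
        # specular glint offset toward the illumination axis
        gx, gy = cx - 0.3 * a * c, cy - 0.3 * b * s
        glint = np.exp(-(((xx - gx) ** 2 + (yy - gy) ** 2) / (2 * (0.12 * min(a, b) + 1.0) ** 2)))
        img += (0.35 * p.brightness) * glint[..., None]

    # mucosal specular highlights away from the polyps
    for _ in range(spec.n_highlights):
        hx, hy = rng.uniform(0, w), rng.uniform(0, h)
        sig = rng.uniform(2.0, 6.0)
        glint = np.exp(-(((xx - hx) ** 2 + (yy - hy) ** 2) / (2 * sig**2)))
        img += 0.18 * glint[..., None]

    img += rng.normal(0.0, spec.speckle, size=img.shape).astype(np.float32)
    img8 = np.clip(np.rint(img * 255.0), 0, 255).astype(np.uint8)
    boxes = [p.bounding_box(spec.frame) for p in spec.polyps]
    return AnnotatedImage(image=img8, boxes=boxes, id=spec.image_id,
                          source_frame=spec.frame)


def generate_dataset(spec: DatasetSpec, out_dir) -> list[str]:
    """Render a dataset to ``out_dir``: PNG + VOC XML per scene plus a
    newline-delimited ``manifest.txt`` of image ids. Returns the ids."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise OSError(f"cannot create output directory {out}: {e}") from e
    ids = []
    for scene in sample_scene_specs(spec):
        ann = render_scene(scene)
        Image.fromarray(ann.image).save(out / f"{ann.id}.png")
        write_voc_xml(ann, out / f"{ann.id}.xml")
        ids.append(ann.id)
    (out / "manifest.txt").write_text("".join(f"{i}\n" for i in ids))
    return ids


def load_dataset(in_dir) -> list[AnnotatedImage]:
    """Read back a generated dataset (manifest + PNG + VOC XML)."""
    root = Path(in_dir)
    manifest = root / "manifest.txt"
    if not manifest.exists():
        raise FileNotFoundError(f"no manifest.txt under {root}")
    anns = []
    for image_id in manifest.read_text().split():
        img = np.asarray(Image.open(root / f"{image_id}.png").convert("RGB"))
        _, frame, boxes, _ = read_voc_xml(root / f"{image_id}.xml")
        anns.append(AnnotatedImage(image=img, boxes=boxes, id=image_id,
                                   source_frame=frame))
    return anns
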