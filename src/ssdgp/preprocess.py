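"""Image and annotation preparation.

Gastroscopy frames arrive at 560x475 with endoscopist-drawn bounding
boxes; the detector consumes square inputs (300 canonical, 96 at desk
scale). This module owns the coordinate conventions and the resampling:

* Boxes are 0-based, half-open ``[xmin, xmax) x [ymin, ymax)`` in pixel
  units, tagged with the frame size they refer to. All area/IoU math in
  the package uses this convention; Pascal-VOC's 1-based inclusive
  convention is converted at the XML boundary (subtract 1 from the mins
  on read, add it back on write).
* Resizing uses a separable Lanczos resampler with support a=4 (an 8x8
  source neighborhood per output pixel, half-pixel-center sampling).
* The only label-preserving augmentation is a 180-degree rotation,
  applied to the training split after the train/test separation so no
  rotated twin of a test frame can leak into training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from lxml import etree

__all__ = [
    "Box", "AnnotatedImage", "lanczos4_resize", "resize_to_input",
    "rotate180", "read_voc_xml", "write_voc_xml", "split_dataset",
]


@dataclass(frozen=True)
class Box:
    """Axis-aligned rectangle, 0-based half-open, in frame (W, H)."""

    xmin: float
    ymin: float
    xmax: float
    ymax: float
    frame: tuple[int, int]  # (W, H)

    def __post_init__(self):
        w, h = self.frame
        if not (0 <= self.xmin < self.xmax <= w and 0 <= self.ymin < self.ymax <= h):
            raise ValueError(f"box ({self.xmin},{self.ymin},{self.xmax},{self.ymax}) "
                             f"violates frame {self.frame}")

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin

    @property
    def area(self) -> float:
        return self.width * self.height

    def as_array(self) -> np.ndarray:
        return np.array([self.xmin, self.ymin, self.xmax, self.ymax], dtype=np.float64)


@dataclass
class AnnotatedImage:
    """An H x W x 3 uint8 image with its boxes and an identifier.

    ``source_frame`` records the frame the annotations originally lived
    in (e.g. 560x475) so size-stratified evaluation can be carried out
    in original-frame coordinates after resizing to the network input.
    """

    image: np.ndarray
    boxes: list[Box]
    id: str
    source_frame: tuple[int, int] | None = None

    def __post_init__(self):
        h, w = self.image.shape[:2]
        for b in self.boxes:
            if b.frame != (w, h):
                raise ValueError(f"box frame {b.frame} does not match image ({w},{h})")

    @property
    def frame(self) -> tuple[int, int]:
        h, w = self.image.shape[:2]
        return (w, h)


# ---------------------------------------------------------------- Lanczos-4


def _lanczos_kernel(x: np.ndarray, a: int) -> np.ndarray:
    out = np.sinc(x) * np.sinc(x / a)
    out[np.abs(x) >= a] = 0.0
    return out


def _resample_axis(img: np.ndarray, n_out: int, axis: int, a: int = 4) -> np.ndarray:
    """Separable Lanczos resample of one axis (half-pixel-center convention)."""
    n_in = img.shape[axis]
    src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    base = np.floor(src).astype(int)
    taps = np.arange(-a + 1, a + 1)  # 2a taps, e.g. 8 for a=4
    idx = base[:, None] + taps[None, :]
    wts = _lanczos_kernel(src[:, None] - idx, a)
    wts /= wts.sum(axis=1, keepdims=True)
    idx = np.clip(idx, 0, n_in - 1)  # edge replication
    moved = np.moveaxis(img, axis, 0).astype(np.float64)
    out = np.einsum("ot,ot...->o...", wts, moved[idx])
    return np.moveaxis(out, 0, axis)


def lanczos4_resize(image: np.ndarray, out_w: int, out_h: int) -> np.ndarray:
    """Resize an H x W (x C) image with the 8x8-neighborhood Lanczos filter."""
    out = _resample_axis(image, out_h, axis=0)
    out = _resample_axis(out, out_w, axis=1)
    if np.issubdtype(image.dtype, np.integer):
        info = np.iinfo(image.dtype)
        out = np.clip(np.rint(out), info.min, info.max).astype(image.dtype)
    else:
        out = out.astype(image.dtype)
    return out


def resize_to_input(ann: AnnotatedImage, edge: int = 300) -> AnnotatedImage:
    """Resize to a square network input, scaling boxes accordingly.

    The original frame is kept as metadata; boxes that collapse to zero
    area under scaling are dropped with a warning.
    """
    w, h = ann.frame
    if w < 1 or h < 1:
        raise ValueError("image has empty spatial dims")
    sx, sy = edge / w, edge / h
    image = lanczos4_resize(ann.image, edge, edge)
    boxes = []
    for b in ann.boxes:
        x1, y1 = b.xmin * sx, b.ymin * sy
        x2, y2 = min(b.xmax * sx, edge), min(b.ymax * sy, edge)
        if x2 - x1 < 0.5 or y2 - y1 < 0.5:  # sub-pixel: zero area once rasterized
            warnings.warn(f"dropping zero-area box after resize in image {ann.id!r}")
            continue
        boxes.append(Box(x1, y1, x2, y2, frame=(edge, edge)))
    return AnnotatedImage(image=image, boxes=boxes, id=ann.id,
                          source_frame=ann.source_frame or (w, h))


def rotate180(ann: AnnotatedImage, suffix: str = "_rot180") -> AnnotatedImage:
    """Rotate image and boxes by 180 degrees (an involution)."""
    w, h = ann.frame
    image = ann.image[::-1, ::-1].copy()
    boxes = [Box(w - b.xmax, h - b.ymax, w - b.xmin, h - b.ymin, frame=(w, h))
             for b in ann.boxes]
    new_id = ann.id[: -len(suffix)] if ann.id.endswith(suffix) else ann.id + suffix
    return AnnotatedImage(image=image, boxes=boxes, id=new_id, source_frame=ann.source_frame)


# ---------------------------------------------------------------- VOC XML


def write_voc_xml(ann: AnnotatedImage, path, class_name: str = "polyp") -> None:
    """Write annotations as Pascal-VOC XML (1-based inclusive pixels)."""
    w, h = ann.frame
    root = etree.Element("annotation")
    etree.SubElement(root, "filename").text = f"{ann.id}.png"
    size = etree.SubElement(root, "size")
    etree.SubElement(size, "width").text = str(w)
    etree.SubElement(size, "height").text = str(h)
    etree.SubElement(size, "depth").text = "3"
    for b in ann.boxes:
        obj = etree.SubElement(root, "object")
        etree.SubElement(obj, "name").text = class_name
        etree.SubElement(obj, "difficult").text = "0"
        bb = etree.SubElement(obj, "bndbox")
        etree.SubElement(bb, "xmin").text = str(int(round(b.xmin)) + 1)
        etree.SubElement(bb, "ymin").text = str(int(round(b.ymin)) + 1)
        etree.SubElement(bb, "xmax").text = str(int(round(b.xmax)))
        etree.SubElement(bb, "ymax").text = str(int(round(b.ymax)))
    etree.ElementTree(root).write(str(path), pretty_print=True,
                                  xml_declaration=False, encoding="utf-8")


def read_voc_xml(path) -> tuple[str, tuple[int, int], list[Box], list[str]]:
    """Read a Pascal-VOC XML file.

    Returns ``(image_id, (W, H), boxes, class_names)`` with boxes in the
    internal 0-based half-open convention.
    """
    try:
        root = etree.parse(str(path)).getroot()
    except etree.XMLSyntaxError as e:
        raise ValueError(f"malformed VOC XML {path}: {e}") from e
    fname = root.findtext("filename") or ""
    image_id = fname.rsplit(".", 1)[0] if "." in fname else fname
    w = int(root.findtext("size/width"))
    h = int(root.findtext("size/height"))
    boxes, names = [], []
    for obj in root.findall("object"):
        bb = obj.find("bndbox")
        xmin = float(bb.findtext("xmin")) - 1
        ymin = float(bb.findtext("ymin")) - 1
        xmax = float(bb.findtext("xmax"))
        ymax = float(bb.findtext("ymax"))
        try:
            boxes.append(Box(xmin, ymin, xmax, ymax, frame=(w, h)))
        except ValueError as e:
            raise ValueError(f"invalid box in {path}: {e}") from e
        names.append(obj.findtext("name") or "polyp")
    return image_id, (w, h), boxes, names


# ---------------------------------------------------------------- split


def split_dataset(items: list, n_test: int, seed: int, augment: bool = True):
    """Shuffle-split into (train, test); optionally append 180-degree
    rotations of the training items (never of test items)."""
    if n_test >= len(items):
        raise ValueError(f"n_test={n_test} must be smaller than the dataset ({len(items)})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(items))
    test = [items[i] for i in order[:n_test]]
    train = [items[i] for i in order[n_test:]]
    if augment:
        train = train + [rotate180(a) for a in train]
    return train, test
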