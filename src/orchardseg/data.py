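"""Data model and I/O for instance-segmentation samples.

An :class:`ImageSample` couples an 8-bit RGB raster with a list of
:class:`InstanceAnnotation` (class id + normalised polygon).  Labels are
read and written in the YOLO-segmentation text dialect (``class x1 y1 x2
y2 ...`` per line, coordinates normalised to [0, 1]); COCO instance JSON
import/export is provided for interoperability.  Rasterisation of
polygons uses an even-odd scanline fill sampled at pixel centres, the
convention every mask-level contract in this package is stated in.

Coordinates are 0-based with pixel-centre convention; boxes are half-open
``[x_min, x_max)`` in normalised units.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

CLASS_NAMES = ("apple", "stem")


class AnnotationParseError(ValueError):
    """Raised on malformed label input, naming the offending line."""


@dataclass
class InstanceAnnotation:
    """One labelled object: class id and normalised polygon."""

    class_id: int
    polygon: np.ndarray  # (N, 2) float, normalised (x, y) in [0, 1]

    def __post_init__(self):
        self.polygon = np.asarray(self.polygon, dtype=np.float64)
        if self.polygon.ndim != 2 or self.polygon.shape[1] != 2:
            raise ValueError("polygon must be an (N, 2) array")
        if len(self.polygon) < 3:
            raise ValueError("polygon needs at least 3 vertices")
        if self.polygon.min() < -1e-9 or self.polygon.max() > 1 + 1e-9:
            raise ValueError("polygon coordinates must lie in [0, 1]")
        if self.area == 0:
            raise ValueError("polygon has zero area")

    @property
    def bbox(self) -> tuple[float, float, float, float]:
        """Tight axis-aligned bounds (x_min, y_min, x_max, y_max), normalised."""
        x, y = self.polygon[:, 0], self.polygon[:, 1]
        return (float(x.min()), float(y.min()), float(x.max()), float(y.max()))

    @property
    def area(self) -> float:
        """Shoelace area in normalised units."""
        x, y = self.polygon[:, 0], self.polygon[:, 1]
        return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2)

    def mask(self, height: int, width: int) -> np.ndarray:
        return polygon_to_mask(self.polygon, height, width)


@dataclass
class ImageSample:
    """An RGB raster plus its instance annotations."""

    image: np.ndarray  # (H, W, 3) uint8
    instances: list[InstanceAnnotation] = field(default_factory=list)
    source_id: str = ""

    def __post_init__(self):
        self.image = np.asarray(self.image)
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError("image must be (H, W, 3)")
        if self.image.dtype != np.uint8:
            self.image = np.clip(self.image, 0, 255).astype(np.uint8)

    @property
    def height(self) -> int:
        return self.image.shape[0]

    @property
    def width(self) -> int:
        return self.image.shape[1]


@dataclass
class SplitFractions:
    train: float = 0.70
    test: float = 0.20
    validation: float = 0.10

    def __post_init__(self):
        if min(self.train, self.test, self.validation) < 0:
            raise ValueError("fractions must be non-negative")
        if abs(self.train + self.test + self.validation - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


# -- label text ------------------------------------------------------------

def parse_yolo_seg(text: str, num_classes: int = len(CLASS_NAMES)) -> list[InstanceAnnotation]:
    """Parse YOLO-segmentation label text (one instance per line)."""
    out = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        tokens = line.split()
        try:
            class_id = int(tokens[0])
            coords = [float(t) for t in tokens[1:]]
        except ValueError as e:
            raise AnnotationParseError(f"line {lineno}: unparseable token ({e})") from None
        if class_id < 0 or class_id >= num_classes:
            raise AnnotationParseError(f"line {lineno}: unknown class {class_id}")
        if len(coords) % 2 or len(coords) < 6:
            raise AnnotationParseError(
                f"line {lineno}: expected an even coordinate count >= 6, got {len(coords)}")
        if min(coords) < 0 or max(coords) > 1:
            raise AnnotationParseError(f"line {lineno}: coordinate outside [0, 1]")
        try:
            out.append(InstanceAnnotation(class_id, np.array(coords).reshape(-1, 2)))
        except ValueError as e:
            raise AnnotationParseError(f"line {lineno}: {e}") from None
    return out


def format_yolo_seg(instances: list[InstanceAnnotation]) -> str:
    """Serialise instances as YOLO-segmentation text, 6-decimal coordinates."""
    lines = []
    for inst in instances:
        coords = " ".join(f"{v:.6f}" for v in inst.polygon.ravel())
        lines.append(f"{inst.class_id} {coords}")
    return "\n".join(lines) + ("\n" if lines else "")


def read_yolo_seg(label_path, image_path) -> ImageSample:
    """Read an image and its YOLO-segmentation label file."""
    image = np.asarray(Image.open(image_path).convert("RGB"))
    text = Path(label_path).read_text()
    instances = parse_yolo_seg(text)
    return ImageSample(image, instances, source_id=str(image_path))


def write_yolo_seg(sample: ImageSample, label_path, image_path=None) -> None:
    Path(label_path).write_text(format_yolo_seg(sample.instances))
    if image_path is not None:
        Image.fromarray(sample.image).save(image_path)


# -- rasterisation ---------------------------------------------------------

def polygon_to_mask(polygon: np.ndarray, height: int, width: int) -> np.ndarray:
    """Even-odd scanline fill of a normalised polygon, sampled at pixel
    centres (x = j + 0.5, y = i + 0.5 in denormalised coordinates)."""
    poly = np.asarray(polygon, dtype=np.float64)
    mask = np.zeros((height, width), dtype=bool)
    x, y = poly[:, 0] * width, poly[:, 1] * height
    area = abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2
    if area == 0:
        warnings.warn("degenerate zero-area polygon rasterised to empty mask")
        return mask
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    i_lo = max(int(np.floor(y.min() - 0.5)), 0)
    i_hi = min(int(np.ceil(y.max())), height)
    for i in range(i_lo, i_hi):
        yc = i + 0.5
        cross = ((y <= yc) & (y1 > yc)) | ((y1 <= yc) & (y > yc))
        if not cross.any():
            continue
        xs = np.sort(x[cross] + (yc - y[cross]) * (x1[cross] - x[cross])
                     / (y1[cross] - y[cross]))
        for a, b in zip(xs[0::2], xs[1::2]):
            j0 = max(int(np.ceil(a - 0.5)), 0)
            j1 = min(int(np.ceil(b - 0.5)), width)
            if j1 > j0:
                mask[i, j0:j1] = True
    return mask


def save_mask_png(mask: np.ndarray, path) -> None:
    Image.fromarray((mask.astype(np.uint8)) * 255, mode="L").save(path)


def load_mask_png(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L")) >= 128


# -- resizing --------------------------------------------------------------

def bilinear_resize(img: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Half-pixel-centre bilinear resampling (edge clamped); channels last
    or 2-D.  Returns float64 for float input, uint8 for uint8 input."""
    h, w = img.shape[:2]
    if (h, w) == (out_h, out_w):
        return img.copy()
    ys = (np.arange(out_h) + 0.5) * h / out_h - 0.5
    xs = (np.arange(out_w) + 0.5) * w / out_w - 0.5
    y0 = np.floor(ys)
    x0 = np.floor(xs)
    fy = (ys - y0)[:, None]
    fx = (xs - x0)[None, :]
    y0i = np.clip(y0.astype(int), 0, h - 1)
    y1i = np.clip(y0.astype(int) + 1, 0, h - 1)
    x0i = np.clip(x0.astype(int), 0, w - 1)
    x1i = np.clip(x0.astype(int) + 1, 0, w - 1)
    im = img.astype(np.float64)
    if im.ndim == 3:
        fy, fx = fy[..., None], fx[..., None]
    top = im[y0i][:, x0i] * (1 - fx) + im[y0i][:, x1i] * fx
    bot = im[y1i][:, x0i] * (1 - fx) + im[y1i][:, x1i] * fx
    out = top * (1 - fy) + bot * fy
    if img.dtype == np.uint8:
        return np.clip(np.round(out), 0, 255).astype(np.uint8)
    return out


def resize_to_square(sample: ImageSample, size: int = 640,
                     letterbox: bool = False) -> ImageSample:
    """Resample a sample's raster to ``size`` x ``size``.

    Default is a direct anisotropic bilinear resize, under which the
    normalised polygon coordinates are unchanged by construction.  With
    ``letterbox=True`` the aspect ratio is preserved by padding with grey
    borders and the polygons are rescaled into the padded frame.
    """
    if size <= 0:
        raise ValueError("size must be positive")
    if not letterbox:
        image = bilinear_resize(sample.image, size, size)
        return ImageSample(image, list(sample.instances), sample.source_id)
    h, w = sample.height, sample.width
    scale = size / max(h, w)
    nh, nw = max(int(round(h * scale)), 1), max(int(round(w * scale)), 1)
    resized = bilinear_resize(sample.image, nh, nw)
    canvas = np.full((size, size, 3), 114, dtype=np.uint8)
    top, left = (size - nh) // 2, (size - nw) // 2
    canvas[top:top + nh, left:left + nw] = resized
    instances = []
    for inst in sample.instances:
        poly = inst.polygon * [nw, nh] + [left, top]
        instances.append(InstanceAnnotation(inst.class_id, np.clip(poly / size, 0, 1)))
    return ImageSample(canvas, instances, sample.source_id)


# -- splitting -------------------------------------------------------------

def split_sizes(n: int, fractions: SplitFractions) -> tuple[int, int, int]:
    """(train, test, validation) sizes: round(n f_train), round(n f_test),
    remainder to validation."""
    n_train = int(round(n * fractions.train))
    n_test = int(round(n * fractions.test))
    return n_train, n_test, n - n_train - n_test


def split_dataset(samples, fractions: SplitFractions | None = None, seed: int = 0,
                  group_key=None):
    """Deterministic random (train, test, validation) partition.

    ``group_key(sample)`` enables per-group stratified splitting: each
    group is split with the stated proportions independently (useful when
    acquisition setups should each be split 70/20/10).
    """
    fractions = fractions or SplitFractions()
    samples = list(samples)
    if group_key is not None:
        groups: dict = {}
        for s in samples:
            groups.setdefault(group_key(s), []).append(s)
        train, test, val = [], [], []
        for gi, key in enumerate(sorted(groups, key=str)):
            tr, te, va = split_dataset(groups[key], fractions, seed + gi)
            train += tr
            test += te
            val += va
        return train, test, val
    n = len(samples)
    n_train, n_test, _ = split_sizes(n, fractions)
    order = np.random.default_rng(seed).permutation(n)
    train = [samples[i] for i in order[:n_train]]
    test = [samples[i] for i in order[n_train:n_train + n_test]]
    val = [samples[i] for i in order[n_train + n_test:]]
    return train, test, val


# -- COCO interchange ------------------------------------------------------

def coco_export(samples: list[ImageSample], path) -> None:
    """Write samples as COCO instance JSON (polygon segmentation)."""
    images, annotations = [], []
    ann_id = 1
    for img_id, s in enumerate(samples, start=1):
        images.append({"id": img_id, "width": s.width, "height": s.height,
                       "file_name": s.source_id or f"image_{img_id}.png"})
        for inst in s.instances:
            poly = inst.polygon * [s.width, s.height]
            x0, y0, x1, y1 = inst.bbox
            annotations.append({
                "id": ann_id, "image_id": img_id, "category_id": inst.class_id + 1,
                "segmentation": [poly.ravel().round(2).tolist()],
                "bbox": [round(x0 * s.width, 2), round(y0 * s.height, 2),
                         round((x1 - x0) * s.width, 2), round((y1 - y0) * s.height, 2)],
                "area": round(inst.area * s.width * s.height, 2), "iscrowd": 0,
            })
            ann_id += 1
    cats = [{"id": i + 1, "name": n} for i, n in enumerate(CLASS_NAMES)]
    Path(path).write_text(json.dumps(
        {"images": images, "annotations": annotations, "categories": cats}))


def coco_import(path, image_loader=None) -> list[ImageSample]:
    """Read COCO instance JSON back into samples.

    ``image_loader(file_name) -> (H, W, 3) uint8`` supplies rasters; by
    default a black raster of the recorded size is used (annotations-only
    round-trips).
    """
    doc = json.loads(Path(path).read_text())
    by_img = {im["id"]: im for im in doc["images"]}
    insts: dict[int, list] = {i: [] for i in by_img}
    for ann in doc["annotations"]:
        im = by_img[ann["image_id"]]
        poly = np.array(ann["segmentation"][0], dtype=float).reshape(-1, 2)
        poly = poly / [im["width"], im["height"]]
        insts[ann["image_id"]].append(
            InstanceAnnotation(ann["category_id"] - 1, np.clip(poly, 0, 1)))
    out = []
    for img_id in sorted(by_img):
        im = by_img[img_id]
        if image_loader is not None:
            raster = image_loader(im["file_name"])
        else:
            raster = np.zeros((im["height"], im["width"], 3), dtype=np.uint8)
        out.append(ImageSample(raster, insts[img_id], source_id=im["file_name"]))
    return out
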