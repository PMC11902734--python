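"""Synthetic orchard scenes with exact instance ground truth.

Every scene contains 1-3 shaded elliptical "apples", each carrying exactly
one thin curved "stem" attached at its top boundary — reproducing the
statistical structure that makes real fruit/stem segmentation hard: stems
occupy a far smaller area than fruits and are sometimes partially hidden
by them.  Ground-truth polygons are exact by construction (the apple is
the polygonised ellipse; the stem is the thick-curve outline, clipped
against every apple so occluded parts are excluded from the label).

Backgrounds mirror the variety of real acquisition setups: plain,
vertical-gradient, low-frequency textured and dark scenes, with a random
illumination gain on top.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from shapely.geometry import Polygon, box as shapely_box
from shapely.ops import unary_union

from .data import ImageSample, InstanceAnnotation, bilinear_resize, format_yolo_seg
from PIL import Image

BACKGROUND_MODES = ("plain", "gradient", "textured", "dark", "varied")
_APPLE_PALETTE = ((200, 35, 45), (120, 180, 60), (225, 200, 70))
_ELLIPSE_VERTICES = 48


@dataclass
class SceneConfig:
    """Ranges from which each scene's geometry and photometry are drawn."""

    image_size: int = 320
    n_apples: tuple[int, int] = (1, 3)
    apple_radius_frac: tuple[float, float] = (0.12, 0.30)
    stem_length_frac: tuple[float, float] = (0.05, 0.15)
    stem_width_px: tuple[int, int] = (2, 6)
    background_mode: str = "varied"
    occlusion_prob: float = 0.15
    illumination_gain: tuple[float, float] = (0.6, 1.4)

    def __post_init__(self):
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64")
        for name in ("n_apples", "apple_radius_frac", "stem_length_frac",
                     "stem_width_px", "illumination_gain"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"empty range for {name}")
        if self.background_mode not in BACKGROUND_MODES:
            raise ValueError(f"unknown background_mode {self.background_mode!r}")
        if not 0.0 <= self.occlusion_prob <= 1.0:
            raise ValueError("occlusion_prob must be in [0, 1]")


class SceneGenerationError(RuntimeError):
    """Raised when instances cannot be placed without full overlap."""


def _ellipse_polygon(cx, cy, rx, ry, n=_ELLIPSE_VERTICES) -> np.ndarray:
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.stack([cx + rx * np.cos(t), cy + ry * np.sin(t)], axis=1)


def _stem_polygon(base: np.ndarray, tip: np.ndarray, ctrl: np.ndarray,
                  width: float, n: int = 14) -> np.ndarray:
    """Outline of a thick quadratic-Bezier curve from base to tip."""
    t = np.linspace(0, 1, n)[:, None]
    pts = ((1 - t) ** 2 * base + 2 * t * (1 - t) * ctrl + t ** 2 * tip)
    d = np.gradient(pts, axis=0)
    norm = np.linalg.norm(d, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    normals = np.stack([-d[:, 1], d[:, 0]], axis=1) / norm
    left = pts + normals * width / 2
    right = pts - normals * width / 2
    return np.concatenate([left, right[::-1]], axis=0)


def _background(size: int, mode: str, rng: np.random.Generator) -> np.ndarray:
    if mode == "varied":
        mode = ("plain", "gradient", "textured", "dark")[rng.integers(0, 4)]
    img = np.empty((size, size, 3), dtype=np.float64)
    if mode == "plain":
        img[:] = rng.uniform(70, 180, size=3)
    elif mode == "gradient":
        top = rng.uniform(60, 170, size=3)
        bottom = rng.uniform(60, 170, size=3)
        ramp = np.linspace(0, 1, size)[:, None, None]
        img[:] = top * (1 - ramp) + bottom * ramp
    elif mode == "textured":
        coarse = rng.uniform(50, 190, size=(8, 8, 3))
        img[:] = bilinear_resize(coarse, size, size)
    else:  # dark chamber
        img[:] = rng.uniform(5, 35, size=3)
    return img


def _shade_apple(img: np.ndarray, cx, cy, rx, ry, color, rng) -> None:
    size = img.shape[0]
    yy, xx = np.mgrid[0:size, 0:size]
    de2 = ((xx + 0.5 - cx) / rx) ** 2 + ((yy + 0.5 - cy) / ry) ** 2
    inside = de2 <= 1.0
    de = np.sqrt(np.clip(de2[inside], 0, 1))
    shade = 0.55 + 0.45 * (1 - de ** 2)
    hx, hy = cx - 0.35 * rx, cy - 0.35 * ry
    hd2 = ((xx + 0.5 - hx) ** 2 + (yy + 0.5 - hy) ** 2)[inside]
    shade = shade + 0.35 * np.exp(-hd2 / (0.3 * rx) ** 2)
    img[inside] = np.asarray(color)[None, :] * shade[:, None]


def _paint_polygon(img: np.ndarray, poly: np.ndarray, color) -> None:
    from .data import polygon_to_mask
    size = img.shape[0]
    mask = polygon_to_mask(poly / size, size, size)
    img[mask] = color


def _place_instances(config: SceneConfig, rng: np.random.Generator,
                     n_apples: int, S: int):
    """Place n apples (each with stem geometry) without mutual overlap.

    Per apple up to 100 placement attempts; if a layout dead-ends, the
    whole scene placement restarts (deterministically, on the same RNG
    stream) up to 6 times before raising a generation error.
    """
    lo, hi = config.apple_radius_frac
    for _restart in range(6):
        apples, stems, placed = [], [], []
        dead_end = False
        for _k in range(n_apples):
            for attempt in range(100):
                # crowded scenes draw smaller fruit, and later attempts
                # shrink further, so n apples can fit without overlap
                crowd = (1.0, 0.6, 0.45)[min(len(placed), 2)]
                hi_eff = max(lo, lo + (hi - lo) * crowd * (1.0 - attempt / 30.0))
                r = rng.uniform(lo, hi_eff) * S
                rx = r
                ry = r * rng.uniform(0.85, 1.0)
                L = rng.uniform(*config.stem_length_frac) * S
                wst = rng.uniform(config.stem_width_px[0], config.stem_width_px[1])
                cx = rng.uniform(rx + 2, S - rx - 2)
                cy = rng.uniform(ry + L + wst + 4, S - ry - 2)
                if all((cx - px) ** 2 + (cy - py) ** 2 >= (1.05 * (r + pr)) ** 2
                       for px, py, pr in placed):
                    break
            else:
                dead_end = True
                break
            placed.append((cx, cy, r))
            occluded = rng.uniform() < config.occlusion_prob
            base_y = cy - ry + (0.35 * L if occluded else 0.0)
            base = np.array([cx, base_y])
            tip = np.array([cx + rng.uniform(-0.45, 0.45) * L, base_y - L])
            ctrl = np.array([cx + rng.uniform(-0.35, 0.35) * L, base_y - 0.5 * L])
            apples.append({"cx": cx, "cy": cy, "rx": rx, "ry": ry,
                           "color": np.asarray(_APPLE_PALETTE[rng.integers(0, 3)], float)
                           * rng.uniform(0.85, 1.1),
                           "poly": _ellipse_polygon(cx, cy, rx, ry)})
            stems.append({"base": base, "tip": tip, "ctrl": ctrl, "width": wst,
                          "color": np.array([90, 65, 30], float) * rng.uniform(0.8, 1.2)})
        if not dead_end:
            return apples, stems
    raise SceneGenerationError(
        f"could not place {n_apples} apples without full overlap "
        "after 100 attempts")


def generate_scene(config: SceneConfig, rng_seed: int) -> ImageSample:
    """Render one deterministic scene; exactly one stem per apple."""
    rng = np.random.default_rng(rng_seed)
    S = config.image_size
    n_apples = int(rng.integers(config.n_apples[0], config.n_apples[1] + 1))
    frame = shapely_box(1.0, 1.0, S - 1.0, S - 1.0)

    apples, stems = _place_instances(config, rng, n_apples, S)

    # clip every stem against all apple ellipses (occlusion) and the frame
    apple_union = unary_union([Polygon(a["poly"]) for a in apples])
    stem_polys = []
    for st in stems:
        raw = Polygon(_stem_polygon(st["base"], st["tip"], st["ctrl"], st["width"]))
        vis = raw.buffer(0).difference(apple_union).intersection(frame)
        if vis.geom_type == "MultiPolygon":
            vis = max(vis.geoms, key=lambda g: g.area)
        if vis.is_empty or vis.area < 4.0:
            raise SceneGenerationError("stem fully occluded; scene invalid")
        stem_polys.append(np.asarray(vis.exterior.coords)[:-1])

    # paint: background, shaded apples, then visible stem polygons
    img = _background(S, config.background_mode, rng)
    for a in apples:
        _shade_apple(img, a["cx"], a["cy"], a["rx"], a["ry"], a["color"], rng)
    for st, poly in zip(stems, stem_polys):
        _paint_polygon(img, poly, st["color"])
    img += rng.normal(0, 6.0, img.shape)
    img *= rng.uniform(*config.illumination_gain)
    raster = np.clip(img, 0, 255).astype(np.uint8)

    instances = []
    for a in apples:
        instances.append(InstanceAnnotation(0, np.clip(a["poly"] / S, 0, 1)))
    for poly in stem_polys:
        instances.append(InstanceAnnotation(1, np.clip(poly / S, 0, 1)))
    return ImageSample(raster, instances, source_id=f"synthetic:{rng_seed}")


def generate_dataset(n: int, config: SceneConfig, seed: int, out_dir) -> dict:
    """Write ``n`` scenes (PNG + YOLO-seg labels) and a JSON manifest.

    Per-scene seed is ``seed + i`` so any single scene is regenerable in
    isolation.  Returns the manifest (also written to ``manifest.json``).
    """
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "labels").mkdir(parents=True, exist_ok=True)
    entries = []
    for i in range(n):
        scene_seed = seed + i
        sample = generate_scene(config, scene_seed)
        img_path = out / "images" / f"scene_{i:05d}.png"
        lbl_path = out / "labels" / f"scene_{i:05d}.txt"
        Image.fromarray(sample.image).save(img_path)
        label_text = format_yolo_seg(sample.instances)
        lbl_path.write_text(label_text)
        digest = hashlib.sha256(sample.image.tobytes()
                                + label_text.encode()).hexdigest()[:16]
        entries.append({"image": str(img_path.relative_to(out)),
                        "label": str(lbl_path.relative_to(out)),
                        "seed": scene_seed, "checksum": digest})
    manifest = {"n": n, "seed": seed, "config": asdict(config), "entries": entries}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def generate_samples(n: int, config: SceneConfig, seed: int) -> list[ImageSample]:
    """In-memory convenience: ``n`` scenes with per-scene seeds ``seed + i``."""
    return [generate_scene(config, seed + i) for i in range(n)]
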