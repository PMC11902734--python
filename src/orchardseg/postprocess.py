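"""Decoding raw head outputs into instance detections.

The anchor-free head predicts, at every grid cell of every scale, a
discrete distribution over ``reg_max`` bins for each of the four box-side
distances (left, top, right, bottom), class logits, and a coefficient
vector over the shared mask prototypes.  Decoding takes the expectation
of each side distribution, scales by the stride, and offsets from the
cell centre; duplicates are removed by classwise greedy non-maximum
suppression; each survivor's mask is the thresholded sigmoid of its
linear combination of prototypes, upsampled and cropped to its box.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .data import ImageSample, bilinear_resize
from .model import RawPredictions, SegmentationModel


@dataclass
class Detection:
    """One predicted instance in pixel coordinates of its raster."""

    class_id: int
    score: float
    box: tuple[float, float, float, float]  # x_min, y_min, x_max, y_max
    mask: np.ndarray | None = None  # bool (H, W)

    def __post_init__(self):
        x0, y0, x1, y1 = self.box
        if not (x0 < x1 and y0 < y1):
            raise ValueError(f"degenerate box {self.box}")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must be in [0, 1]")


def make_anchors(input_size: int, strides=(8, 16, 32)) -> tuple[np.ndarray, np.ndarray]:
    """Grid-cell centre points (A, 2) in input pixels and per-anchor strides."""
    pts, strd = [], []
    for s in strides:
        n = input_size // s
        xs = (np.arange(n) + 0.5) * s
        gx, gy = np.meshgrid(xs, xs)
        pts.append(np.stack([gx.ravel(), gy.ravel()], axis=1))
        strd.append(np.full(n * n, s, dtype=np.float64))
    return np.concatenate(pts), np.concatenate(strd)


def expected_distances(box_logits: np.ndarray, reg_max: int) -> np.ndarray:
    """Softmax expectation of the per-side bin distributions.

    box_logits: (..., 4*reg_max) -> distances (..., 4) in bin units.
    """
    shaped = box_logits.reshape(*box_logits.shape[:-1], 4, reg_max)
    z = shaped - shaped.max(axis=-1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=-1, keepdims=True)
    return p @ np.arange(reg_max, dtype=np.float64)


def dist_to_boxes(dist: np.ndarray, anchors: np.ndarray,
                  strides: np.ndarray) -> np.ndarray:
    """(l, t, r, b) distances in bin units -> (x0, y0, x1, y1) pixel boxes."""
    d = dist * strides[:, None]
    return np.stack([anchors[:, 0] - d[:, 0], anchors[:, 1] - d[:, 1],
                     anchors[:, 0] + d[:, 2], anchors[:, 1] + d[:, 3]], axis=1)


def flatten_predictions(preds: RawPredictions, image_index: int = 0):
    """Per-image flattening of per-scale maps into anchor-major arrays.

    Returns (box_logits (A, 4*reg_max), cls_logits (A, nc), coefs (A, nm),
    protos (nm, hp, wp)) as plain numpy arrays.
    """
    def flat(maps):
        rows = []
        for m in maps:
            arr = m.data if hasattr(m, "data") else m
            c = arr.shape[1]
            rows.append(arr[image_index].reshape(c, -1).T)
        return np.concatenate(rows, axis=0)

    protos = preds.protos.data if hasattr(preds.protos, "data") else preds.protos
    return (flat(preds.box), flat(preds.cls), flat(preds.coef),
            protos[image_index])


def decode(preds: RawPredictions, input_size: int, reg_max: int,
           conf_threshold: float = 0.25, image_index: int = 0):
    """Raw predictions -> candidate arrays (boxes px, scores, classes, coefs)."""
    box_l, cls_l, coef, protos = flatten_predictions(preds, image_index)
    anchors, strides = make_anchors(input_size, preds.strides)
    scores_all = expit(cls_l)
    cls_ids = scores_all.argmax(axis=1)
    scores = scores_all[np.arange(len(cls_ids)), cls_ids]
    keep = scores >= conf_threshold
    dist = expected_distances(box_l[keep], reg_max)
    boxes = dist_to_boxes(dist, anchors[keep], strides[keep])
    return boxes, scores[keep], cls_ids[keep], coef[keep], protos


def box_iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU of (N, 4) and (M, 4) xyxy boxes."""
    if len(a) == 0 or len(b) == 0:
        return np.zeros((len(a), len(b)))
    lt = np.maximum(a[:, None, :2], b[None, :, :2])
    rb = np.minimum(a[:, None, 2:], b[None, :, 2:])
    wh = np.clip(rb - lt, 0, None)
    inter = wh[..., 0] * wh[..., 1]
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / np.maximum(union, 1e-12), 0.0)


def nms(boxes: np.ndarray, scores: np.ndarray, class_ids: np.ndarray,
        iou_threshold: float = 0.7) -> np.ndarray:
    """Classwise greedy suppression; returns kept indices (original order
    of candidates breaks score ties, lower index first)."""
    keep: list[int] = []
    for c in np.unique(class_ids):
        idx = np.flatnonzero(class_ids == c)
        # stable sort so equal scores keep lower candidate index first
        order = idx[np.argsort(-scores[idx], kind="stable")]
        while len(order):
            i = order[0]
            keep.append(int(i))
            if len(order) == 1:
                break
            ious = box_iou_matrix(boxes[i:i + 1], boxes[order[1:]])[0]
            order = order[1:][ious <= iou_threshold]
    return np.array(sorted(keep), dtype=int)


def assemble_mask(coefficients: np.ndarray, protos: np.ndarray,
                  box: tuple, out_size: int | tuple[int, int],
                  threshold: float = 0.5) -> np.ndarray:
    """sigmoid(coef . prototypes), bilinearly upsampled to ``out_size``,
    thresholded (>= is foreground) and zeroed outside ``box``."""
    nm, hp, wp = protos.shape
    logits = np.tensordot(coefficients, protos.reshape(nm, hp * wp), axes=1)
    prob = expit(logits.reshape(hp, wp))
    oh, ow = (out_size, out_size) if np.isscalar(out_size) else out_size
    up = bilinear_resize(prob, oh, ow)
    mask = up >= threshold
    x0, y0, x1, y1 = box
    crop = np.zeros_like(mask)
    ix0, iy0 = max(int(np.floor(x0)), 0), max(int(np.floor(y0)), 0)
    ix1, iy1 = min(int(np.ceil(x1)), ow), min(int(np.ceil(y1)), oh)
    if ix1 > ix0 and iy1 > iy0:
        crop[iy0:iy1, ix0:ix1] = mask[iy0:iy1, ix0:ix1]
    return crop


def segment_image(model: SegmentationModel, raster: np.ndarray,
                  conf: float = 0.25, iou: float = 0.7,
                  max_det: int = 300) -> list[Detection]:
    """Full pipeline on one RGB raster: resize -> forward -> decode -> NMS
    -> mask assembly, with geometry mapped back to the input raster."""
    sample = ImageSample(raster)
    H, W = sample.height, sample.width
    S = model.spec.input_size
    resized = bilinear_resize(sample.image, S, S)
    x = resized.astype(np.float32).transpose(2, 0, 1)[None] / 255.0
    preds = model.predict_raw(x)
    boxes, scores, cls_ids, coefs, protos = decode(
        preds, S, model.spec.reg_max, conf_threshold=conf)
    valid = (boxes[:, 2] - boxes[:, 0] > 1e-6) & (boxes[:, 3] - boxes[:, 1] > 1e-6)
    boxes, scores, cls_ids, coefs = boxes[valid], scores[valid], cls_ids[valid], coefs[valid]
    kept = nms(boxes, scores, cls_ids, iou_threshold=iou)
    if len(kept) > max_det:
        kept = kept[np.argsort(-scores[kept], kind="stable")[:max_det]]
        kept = np.sort(kept)
    out = []
    sx, sy = W / S, H / S
    for i in kept:
        mask_model = assemble_mask(coefs[i], protos, boxes[i], S)
        mask = bilinear_resize(mask_model.astype(np.float64), H, W) >= 0.5 \
            if (H, W) != (S, S) else mask_model
        x0 = float(np.clip(boxes[i, 0] * sx, 0, W - 1))
        y0 = float(np.clip(boxes[i, 1] * sy, 0, H - 1))
        x1 = float(np.clip(boxes[i, 2] * sx, x0 + 1e-3, W))
        y1 = float(np.clip(boxes[i, 3] * sy, y0 + 1e-3, H))
        out.append(Detection(int(cls_ids[i]), float(scores[i]),
                             (x0, y0, x1, y1), mask))
    return out


# -- results interchange ---------------------------------------------------

def mask_to_rle(mask: np.ndarray) -> dict:
    """Uncompressed column-major run-length encoding (COCO convention)."""
    flat = np.asarray(mask, dtype=bool).T.ravel()
    changes = np.flatnonzero(flat[1:] != flat[:-1]) + 1
    runs = np.diff(np.concatenate([[0], changes, [flat.size]]))
    counts = runs.tolist()
    if flat.size and flat[0]:  # RLE starts with a background run
        counts = [0] + counts
    return {"size": list(mask.shape), "counts": counts}


def rle_to_mask(rle: dict) -> np.ndarray:
    h, w = rle["size"]
    flat = np.zeros(h * w, dtype=bool)
    pos, val = 0, False
    for run in rle["counts"]:
        if val:
            flat[pos:pos + run] = True
        pos += run
        val = not val
    return flat.reshape(w, h).T


def detections_to_coco(detections: list[Detection], image_id: int) -> list[dict]:
    out = []
    for d in detections:
        x0, y0, x1, y1 = d.box
        rec = {"image_id": image_id, "category_id": d.class_id + 1,
               "score": round(d.score, 5),
               "bbox": [round(x0, 2), round(y0, 2), round(x1 - x0, 2), round(y1 - y0, 2)]}
        if d.mask is not None:
            rec["segmentation"] = mask_to_rle(d.mask)
        out.append(rec)
    return out
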