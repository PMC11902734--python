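"""Detection/segmentation evaluation: precision, recall, AP@50, AP@50-95.

Average precision follows the COCO convention: predictions are ranked by
confidence over the whole dataset, matched greedily within each image
(each ground truth claimed at most once, highest-IoU unmatched same-class
ground truth wins), the precision-recall curve is made monotone from the
right and integrated at 101 evenly spaced recall points.  AP@50-95
averages AP over IoU thresholds 0.50:0.05:0.95.  Box and mask modes are
computed independently; mask IoU is evaluated at the raster's original
resolution.  Scalar precision/recall are reported at the per-class
confidence that maximises F1.  The "All" row is the unweighted mean over
classes with defined metrics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .data import CLASS_NAMES, ImageSample
from .postprocess import Detection, box_iou_matrix, rle_to_mask

IOU_THRESHOLDS_50_95 = np.arange(0.50, 0.96, 0.05).round(2)


def iou(a, b) -> float:
    """IoU of two boxes (xyxy 4-sequences) or two boolean masks."""
    a_arr, b_arr = np.asarray(a), np.asarray(b)
    if a_arr.ndim == 2:
        inter = np.logical_and(a_arr, b_arr).sum()
        union = np.logical_or(a_arr, b_arr).sum()
        return float(inter / union) if union else 0.0
    return float(box_iou_matrix(a_arr[None].astype(float),
                                b_arr[None].astype(float))[0, 0])


def _pairwise_iou(preds: list[Detection], gts: list, mode: str) -> np.ndarray:
    """IoU matrix (n_pred, n_gt); gts are (class_id, box, mask) triples."""
    if mode == "box":
        pb = np.array([d.box for d in preds], dtype=float).reshape(-1, 4)
        gb = np.array([g[1] for g in gts], dtype=float).reshape(-1, 4)
        return box_iou_matrix(pb, gb)
    out = np.zeros((len(preds), len(gts)))
    for i, d in enumerate(preds):
        for j, g in enumerate(gts):
            out[i, j] = iou(d.mask, g[2])
    return out


def match_detections(preds: list[Detection], gts: list, iou_thresh: float,
                     mode: str = "box",
                     iou_matrix: np.ndarray | None = None) -> np.ndarray:
    """Greedy TP/FP flags for one image.

    ``preds`` must be sorted by descending score; ``gts`` are
    (class_id, box_xyxy, mask) triples.  Each prediction matches the
    highest-IoU unmatched same-class ground truth at IoU >= thresh.
    """
    flags = np.zeros(len(preds), dtype=bool)
    if not preds or not gts:
        return flags
    mat = _pairwise_iou(preds, gts, mode) if iou_matrix is None else iou_matrix
    taken = np.zeros(len(gts), dtype=bool)
    gt_cls = np.array([g[0] for g in gts])
    for i, d in enumerate(preds):
        cand = np.flatnonzero((gt_cls == d.class_id) & ~taken
                              & (mat[i] >= iou_thresh))
        if len(cand):
            j = cand[np.argmax(mat[i, cand])]
            taken[j] = True
            flags[i] = True
    return flags


def average_precision(tp_flags: np.ndarray, n_gt: int) -> float | None:
    """101-point interpolated AP from score-ordered TP flags.

    Returns None (undefined) when there are neither ground truths nor
    predictions; 0.0 when predictions exist but no ground truth does.
    """
    tp_flags = np.asarray(tp_flags, dtype=bool)
    if n_gt == 0:
        return None if len(tp_flags) == 0 else 0.0
    if len(tp_flags) == 0:
        return 0.0
    tp = np.cumsum(tp_flags)
    fp = np.cumsum(~tp_flags)
    recall = tp / n_gt
    precision = tp / (tp + fp)
    # monotone envelope from the right
    prec_env = np.maximum.accumulate(precision[::-1])[::-1]
    r_points = np.linspace(0, 1, 101)
    idx = np.searchsorted(recall, r_points, side="left")
    p_at = np.where(idx < len(prec_env), prec_env[np.minimum(idx, len(prec_env) - 1)], 0.0)
    return float(p_at.mean())


@dataclass
class ClassMetrics:
    precision: float = 0.0
    recall: float = 0.0
    ap50: float = 0.0
    ap50_95: float = 0.0


@dataclass
class EvalReport:
    """Per-class and overall metrics, separately for boxes and masks."""

    box: dict[str, ClassMetrics] = field(default_factory=dict)
    mask: dict[str, ClassMetrics] = field(default_factory=dict)
    class_names: tuple = CLASS_NAMES

    def to_json(self, path=None) -> str:
        doc = {"box": {k: asdict(v) for k, v in self.box.items()},
               "mask": {k: asdict(v) for k, v in self.mask.items()}}
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    def table(self) -> str:
        """Aligned text table: one block per match mode."""
        lines = []
        for mode in ("box", "mask"):
            metrics = getattr(self, mode)
            lines.append(f"[{mode}]")
            lines.append(f"{'Class':12s} {'Precision':>9s} {'Recall':>9s} "
                         f"{'mAP@50':>9s} {'mAP@50-95':>10s}")
            for name in ("All", *self.class_names):
                if name not in metrics:
                    continue
                m = metrics[name]
                lines.append(f"{name:12s} {m.precision:9.3f} {m.recall:9.3f} "
                             f"{m.ap50:9.3f} {m.ap50_95:10.3f}")
        return "\n".join(lines)


def _gt_triples(sample: ImageSample, with_masks: bool) -> list:
    out = []
    for inst in sample.instances:
        x0, y0, x1, y1 = inst.bbox
        box = (x0 * sample.width, y0 * sample.height,
               x1 * sample.width, y1 * sample.height)
        mask = inst.mask(sample.height, sample.width) if with_masks else None
        out.append((inst.class_id, box, mask))
    return out


def _class_eval(per_image: list[tuple[list[Detection], list, np.ndarray]],
                class_id: int, thresholds: np.ndarray):
    """Dataset-level evaluation of one class at several IoU thresholds.

    per_image: (class-filtered score-sorted preds, class gts, IoU matrix).
    Returns (scores sorted desc, tp flag matrix (n_thresh, n_pred), n_gt).
    """
    scores, flags_per_t = [], [[] for _ in thresholds]
    n_gt = 0
    for preds, gts, mat in per_image:
        n_gt += len(gts)
        scores.extend(d.score for d in preds)
        for ti, t in enumerate(thresholds):
            flags_per_t[ti].extend(
                match_detections(preds, gts, t, iou_matrix=mat))
    scores = np.asarray(scores)
    order = np.argsort(-scores, kind="stable")
    flags = np.asarray(flags_per_t, dtype=bool).reshape(len(thresholds), -1)
    return scores[order], flags[:, order] if flags.size else flags, n_gt


def _max_f1_point(scores: np.ndarray, tp: np.ndarray, n_gt: int):
    """Precision/recall at the confidence threshold maximising F1."""
    if len(scores) == 0 or n_gt == 0:
        return 0.0, 0.0
    tp_c = np.cumsum(tp)
    fp_c = np.cumsum(~tp)
    precision = tp_c / (tp_c + fp_c)
    recall = tp_c / n_gt
    f1 = 2 * precision * recall / np.maximum(precision + recall, 1e-12)
    i = int(np.argmax(f1))
    return float(precision[i]), float(recall[i])


def evaluate(predictions: list[list[Detection]], gt_samples: list[ImageSample],
             modes: tuple = ("box", "mask"),
             class_names: tuple = CLASS_NAMES) -> EvalReport:
    """Evaluate per-image detection lists against ground-truth samples."""
    if len(predictions) != len(gt_samples):
        raise ValueError("predictions and ground truth must align per image")
    report = EvalReport(class_names=class_names)
    for mode in modes:
        with_masks = mode == "mask"
        cache = []
        for preds, sample in zip(predictions, gt_samples):
            gts = _gt_triples(sample, with_masks)
            cache.append((sorted(preds, key=lambda d: -d.score), gts))
        per_class = {}
        for c, cname in enumerate(class_names):
            per_image = []
            for preds, gts in cache:
                p = [d for d in preds if d.class_id == c]
                g = [t for t in gts if t[0] == c]
                mat = _pairwise_iou(p, g, mode) if p and g else \
                    np.zeros((len(p), len(g)))
                per_image.append((p, g, mat))
            scores, flags, n_gt = _class_eval(per_image, c, IOU_THRESHOLDS_50_95)
            aps = [average_precision(flags[ti] if flags.size else np.array([]), n_gt)
                   for ti in range(len(IOU_THRESHOLDS_50_95))]
            if n_gt == 0 and len(scores) == 0:
                continue  # class absent from both: excluded from the mean
            ap50 = aps[0] if aps[0] is not None else 0.0
            defined = [a for a in aps if a is not None]
            ap5095 = float(np.mean(defined)) if defined else 0.0
            p, r = _max_f1_point(scores, flags[0] if flags.size else np.array([]), n_gt)
            per_class[cname] = ClassMetrics(p, r, ap50, ap5095)
        if per_class:
            per_class["All"] = ClassMetrics(
                *(float(np.mean([getattr(m, f) for m in per_class.values()]))
                  for f in ("precision", "recall", "ap50", "ap50_95")))
        getattr(report, mode).update(per_class)
    return report


def map_50_95(predictions: list[list[Detection]], gt_samples: list[ImageSample],
              mode: str = "box") -> float:
    """Mean AP over IoU 0.50:0.05:0.95, then over classes."""
    rep = evaluate(predictions, gt_samples, modes=(mode,))
    return getattr(rep, mode)["All"].ap50_95


def load_coco_results(path, image_sizes: list[tuple[int, int]]) -> list[list[Detection]]:
    """Read a COCO-results JSON (produced by this package) back into
    per-image detection lists; ``image_sizes`` gives (H, W) per image id
    (1-based order)."""
    recs = json.loads(Path(path).read_text())
    out: list[list[Detection]] = [[] for _ in image_sizes]
    for r in recs:
        i = r["image_id"] - 1
        x, y, w, h = r["bbox"]
        mask = rle_to_mask(r["segmentation"]) if "segmentation" in r else None
        out[i].append(Detection(r["category_id"] - 1, r["score"],
                                (x, y, x + w, y + h), mask))
    for dets in out:
        dets.sort(key=lambda d: -d.score)
    return out
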