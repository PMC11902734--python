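"""Target assignment, the four-component loss, augmentations and the
training loop.

The loss follows the anchor-free detection-with-masks recipe: task-aligned
assignment of grid cells to ground truths, complete-IoU box loss,
binary-cross-entropy classification over all cells, distribution focal
loss over the discretised box-side distances, and a per-pixel
binary-cross-entropy mask loss on the assembled prototype masks, cropped
to the ground-truth box and normalised by box area.  Optimisation is SGD
with momentum 0.937, weight decay 0.0005 and initial learning rate 0.01
(linear warmup, cosine decay), with early stopping on validation loss.

Augmentations (mosaic, flips, pixel shifting, coarse dropout) operate on
the sample's polygons as well as its raster, so every augmented sample
remains a valid labelled scene.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from shapely.geometry import Polygon, box as shapely_box

from . import autodiff as ad
from .autodiff import Tensor
from .data import (ImageSample, InstanceAnnotation, bilinear_resize,
                   polygon_to_mask, resize_to_square)
from .model import ModelSpec, RawPredictions, SegmentationModel
from .postprocess import box_iou_matrix, make_anchors


@dataclass
class TrainConfig:
    epochs: int = 500
    patience: int = 100
    momentum: float = 0.937
    weight_decay: float = 0.0005
    lr0: float = 0.01
    lrf: float = 0.01          # final lr = lrf * lr0 (cosine floor)
    warmup_epochs: int = 3
    batch_size: int = 8
    box_weight: float = 7.5
    cls_weight: float = 0.5
    dfl_weight: float = 1.5
    mask_weight: float = 1.0
    mosaic: bool = True
    mosaic_disable_frac: float = 0.1  # final fraction of epochs without mosaic
    fliplr: bool = True
    flipud: bool = False
    pixel_shift: bool = True
    shift_frac: float = 0.1
    dropout_rate: float = 0.0  # probability of coarse cutout patches
    topk: int = 10
    align_alpha: float = 0.5
    align_beta: float = 6.0
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1 or self.patience < 0 or self.batch_size < 1:
            raise ValueError("invalid epochs/patience/batch_size")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass
class LossBreakdown:
    box: float = 0.0
    cls: float = 0.0
    dfl: float = 0.0
    mask: float = 0.0

    def total(self, cfg: TrainConfig) -> float:
        return (cfg.box_weight * self.box + cfg.cls_weight * self.cls
                + cfg.dfl_weight * self.dfl + cfg.mask_weight * self.mask)


# -- target assignment -----------------------------------------------------

def assign_targets(scores: np.ndarray, pred_boxes: np.ndarray,
                   anchors: np.ndarray, gt_boxes: np.ndarray,
                   gt_cls: np.ndarray, topk: int = 10,
                   alpha: float = 0.5, beta: float = 6.0,
                   anchor_strides: np.ndarray | None = None):
    """Task-aligned assignment for one image.

    scores: (A, nc) post-sigmoid class scores; pred_boxes: (A, 4) pixel
    boxes; anchors: (A, 2) cell centres; gt_boxes: (M, 4); gt_cls: (M,).
    Each ground truth claims its top-k cells (among cells whose centre
    lies inside it) by alignment score s^alpha * IoU^beta; a cell claimed
    by several ground truths goes to the one with the highest alignment.

    When ``anchor_strides`` is given, the candidate window of a ground
    truth is dilated to at least one cell per side, so boxes much thinner
    than the anchor grid (stems) still receive candidates.

    Returns (fg_mask (A,), gt_index (A,), target_scores (A, nc)).
    """
    A = len(anchors)
    nc = scores.shape[1]
    fg = np.zeros(A, dtype=bool)
    gt_idx = np.zeros(A, dtype=int)
    tscores = np.zeros((A, nc))
    M = len(gt_boxes)
    if M == 0:
        return fg, gt_idx, tscores
    ious = box_iou_matrix(gt_boxes, pred_boxes)          # (M, A)
    if anchor_strides is None:
        inside = ((anchors[None, :, 0] >= gt_boxes[:, None, 0])
                  & (anchors[None, :, 0] < gt_boxes[:, None, 2])
                  & (anchors[None, :, 1] >= gt_boxes[:, None, 1])
                  & (anchors[None, :, 1] < gt_boxes[:, None, 3]))
    else:
        cx = (gt_boxes[:, None, 0] + gt_boxes[:, None, 2]) / 2
        cy = (gt_boxes[:, None, 1] + gt_boxes[:, None, 3]) / 2
        hw = np.maximum((gt_boxes[:, None, 2] - gt_boxes[:, None, 0]) / 2,
                        anchor_strides[None, :] / 2)
        hh = np.maximum((gt_boxes[:, None, 3] - gt_boxes[:, None, 1]) / 2,
                        anchor_strides[None, :] / 2)
        inside = ((np.abs(anchors[None, :, 0] - cx) <= hw)
                  & (np.abs(anchors[None, :, 1] - cy) <= hh))
    align = (scores[:, gt_cls].T ** alpha) * (ious ** beta)
    align = np.where(inside, align, 0.0)
    cand = np.zeros_like(inside)
    k = min(topk, A)
    top = np.argpartition(-align, k - 1, axis=1)[:, :k]
    rows = np.repeat(np.arange(M), k)
    cand[rows, top.ravel()] = True
    cand &= align > 0
    # resolve conflicts: the ground truth with the highest alignment wins
    owner = np.where(cand, align, -1.0).argmax(axis=0)
    any_cand = cand.any(axis=0)
    fg = any_cand
    gt_idx = np.where(fg, owner, 0)
    # normalised soft targets per the task-aligned recipe
    claimed = np.zeros_like(align)
    claimed[owner[fg], np.flatnonzero(fg)] = align[owner[fg], np.flatnonzero(fg)]
    amax = claimed.max(axis=1, keepdims=True)
    imax = np.where(claimed > 0, ious, 0.0).max(axis=1, keepdims=True)
    norm = np.where(amax > 0, claimed / np.maximum(amax, 1e-9) * imax, 0.0)
    pos = np.flatnonzero(fg)
    tscores[pos, gt_cls[gt_idx[pos]]] = norm[gt_idx[pos], pos]
    return fg, gt_idx, tscores


# -- losses ----------------------------------------------------------------

def ciou_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    """1 - CIoU per row; pred (P, 4) Tensor, target (P, 4) array, xyxy."""
    eps = 1e-7
    tx0, ty0, tx1, ty1 = target[:, 0], target[:, 1], target[:, 2], target[:, 3]
    px0, py0, px1, py1 = pred[:, 0], pred[:, 1], pred[:, 2], pred[:, 3]
    iw = ad.maximum(ad.minimum(px1, tx1) - ad.maximum(px0, tx0), 0.0)
    ih = ad.maximum(ad.minimum(py1, ty1) - ad.maximum(py0, ty0), 0.0)
    inter = ad.mul(iw, ih)
    pw, ph = px1 - px0, py1 - py0
    area_t = (tx1 - tx0) * (ty1 - ty0)
    union = ad.add(ad.mul(pw, ph), area_t) - inter
    iou_t = inter / (union + eps)
    # enclosing-box diagonal and centre distance
    cw = ad.maximum(px1, tx1) - ad.minimum(px0, tx0)
    ch = ad.maximum(py1, ty1) - ad.minimum(py0, ty0)
    c2 = ad.mul(cw, cw) + ad.mul(ch, ch) + eps
    dx = (px0 + px1 - tx0 - tx1) * 0.5
    dy = (py0 + py1 - ty0 - ty1) * 0.5
    rho2 = ad.mul(dx, dx) + ad.mul(dy, dy)
    tw, th = tx1 - tx0, ty1 - ty0
    v = ad.power(ad.arctan(tw / np.maximum(th, eps)) - ad.arctan(pw / (ph + eps)), 2.0)
    v = ad.mul(v, 4.0 / np.pi ** 2)
    with ad.no_grad():
        alpha = v.data / (1.0 - iou_t.data + v.data + eps)
    return 1.0 - iou_t + rho2 / c2 + ad.mul(v, alpha)


def dfl_loss(pos_logits: Tensor, target_dist: np.ndarray, reg_max: int) -> Tensor:
    """Distribution focal loss: cross-entropy against the two bins
    bracketing each true distance; (P, 4*reg_max) logits, (P, 4) targets
    in bin units."""
    t = np.clip(target_dist, 0, reg_max - 1)
    lo = np.minimum(np.floor(t).astype(int), reg_max - 2)
    hi = lo + 1
    w_hi = t - lo   # 1.0 exactly when the target sits on the last bin
    w_lo = 1.0 - w_hi
    logp = ad.log(ad.softmax(reshape4(pos_logits, reg_max), axis=-1) + 1e-12)
    P = t.shape[0]
    ii = np.repeat(np.arange(P), 4)
    jj = np.tile(np.arange(4), P)
    nll_lo = -ad.getitem(logp, (ii, jj, lo.ravel()))
    nll_hi = -ad.getitem(logp, (ii, jj, hi.ravel()))
    per = ad.mul(nll_lo, w_lo.ravel()) + ad.mul(nll_hi, w_hi.ravel())
    return reshape4(per, None)


def reshape4(t: Tensor, reg_max):
    if reg_max is None:
        return ad.reshape(t, (-1, 4))
    return ad.reshape(t, (t.shape[0], 4, reg_max))


def _flatten_scale_maps(maps: list[Tensor]) -> Tensor:
    """Per-scale (B, C, h, w) -> anchor-major (B, A, C)."""
    parts = []
    for m in maps:
        B, C = m.shape[0], m.shape[1]
        parts.append(ad.transpose(ad.reshape(m, (B, C, -1)), (0, 2, 1)))
    return ad.concat(parts, axis=1)


def batch_assignment(preds: RawPredictions, targets: list[dict],
                     spec: ModelSpec, cfg: TrainConfig):
    """Task-aligned assignment for a whole batch, computed from the raw
    prediction maps without recording gradients.

    Returns (target_scores (B, A, nc), positives [(image, anchor, gt)]),
    the pair accepted by ``compute_losses(..., assignment=...)``.
    """
    from .postprocess import dist_to_boxes, expected_distances, flatten_predictions
    S = spec.input_size
    anchors, strides = make_anchors(S, spec.strides)
    A = len(anchors)
    B = preds.cls[0].shape[0]
    nc = preds.cls[0].shape[1]
    tscores_all = np.zeros((B, A, nc), dtype=np.float32)
    pos_entries = []
    for b in range(B):
        box_l, cls_l, _, _ = flatten_predictions(preds, b)
        boxes = dist_to_boxes(expected_distances(box_l, spec.reg_max),
                              anchors, strides)
        fg, gi, ts = assign_targets(expit(cls_l), boxes, anchors,
                                    targets[b]["boxes"], targets[b]["cls"],
                                    cfg.topk, cfg.align_alpha, cfg.align_beta,
                                    anchor_strides=strides)
        tscores_all[b] = ts
        for a_i in np.flatnonzero(fg):
            pos_entries.append((b, int(a_i), int(gi[a_i])))
    return tscores_all, pos_entries


def compute_losses(preds: RawPredictions, targets: list[dict], spec: ModelSpec,
                   cfg: TrainConfig, assignment=None):
    """Batch loss. ``targets[b]`` holds 'boxes' (M,4) px, 'cls' (M,),
    'masks' (M, hp, wp) proto-resolution ground-truth masks.

    ``assignment`` may carry a precomputed (target_scores, positives)
    pair (as produced internally) to evaluate the loss under a frozen
    assignment; by default the task-aligned assignment is recomputed
    from the current predictions.

    Returns (total loss Tensor, LossBreakdown of unweighted components).
    """
    S = spec.input_size
    rm = spec.reg_max
    anchors, strides = make_anchors(S, spec.strides)
    A = len(anchors)
    box_l = _flatten_scale_maps(preds.box)    # (B, A, 4*rm)
    cls_l = _flatten_scale_maps(preds.cls)    # (B, A, nc)
    coef_l = _flatten_scale_maps(preds.coef)  # (B, A, nm)
    B = box_l.shape[0]
    nc = cls_l.shape[2]

    # differentiable decoded boxes for the whole batch
    dist = ad.matmul(ad.softmax(ad.reshape(box_l, (B, A, 4, rm)), axis=-1),
                     np.arange(rm, dtype=np.float32).reshape(rm, 1))
    dist = ad.reshape(dist, (B, A, 4))
    sgrid = strides.astype(np.float32)[None, :, None]
    d_px = ad.mul(dist, sgrid)
    ax = anchors.astype(np.float32)
    pred_boxes = ad.concat([
        ad.reshape(ax[None, :, 0] - d_px[:, :, 0], (B, A, 1)),
        ad.reshape(ax[None, :, 1] - d_px[:, :, 1], (B, A, 1)),
        ad.reshape(ax[None, :, 0] + d_px[:, :, 2], (B, A, 1)),
        ad.reshape(ax[None, :, 1] + d_px[:, :, 3], (B, A, 1))], axis=2)

    if assignment is None:
        tscores_all = np.zeros((B, A, nc), dtype=np.float32)
        pos_entries = []  # (b, anchor_idx, gt_idx)
        scores_np = expit(cls_l.data)
        boxes_np = pred_boxes.data.astype(np.float64)
        for b in range(B):
            gtb = targets[b]["boxes"]
            gtc = targets[b]["cls"]
            fg, gi, ts = assign_targets(scores_np[b], boxes_np[b], anchors, gtb,
                                        gtc, cfg.topk, cfg.align_alpha,
                                        cfg.align_beta, anchor_strides=strides)
            tscores_all[b] = ts
            for a_i in np.flatnonzero(fg):
                pos_entries.append((b, int(a_i), int(gi[a_i])))
    else:
        tscores_all, pos_entries = assignment

    ts_sum = max(float(tscores_all.sum()), 1.0)
    cls_loss = ad.tsum(ad.bce_with_logits(cls_l, tscores_all)) / ts_sum

    if not pos_entries:
        zero = ad.astensor(np.zeros(()))
        total = ad.mul(cls_loss, cfg.cls_weight)
        return total, LossBreakdown(0.0, float(cls_loss.data), 0.0, 0.0)

    pb = np.array([e[0] for e in pos_entries])
    pa = np.array([e[1] for e in pos_entries])
    pg = np.array([e[2] for e in pos_entries])
    tgt_boxes = np.stack([targets[b]["boxes"][g] for b, g in zip(pb, pg)])
    weights = tscores_all[pb, pa].sum(axis=1).astype(np.float32)

    pos_boxes = ad.getitem(pred_boxes, (pb, pa))
    box_per = ciou_loss(pos_boxes, tgt_boxes)
    box_loss = ad.tsum(ad.mul(box_per, weights)) / ts_sum

    # DFL targets: side distances from the anchor in bin units
    strd = strides[pa][:, None]
    tdist = np.stack([anchors[pa, 0] - tgt_boxes[:, 0],
                      anchors[pa, 1] - tgt_boxes[:, 1],
                      tgt_boxes[:, 2] - anchors[pa, 0],
                      tgt_boxes[:, 3] - anchors[pa, 1]], axis=1) / strd
    pos_box_logits = ad.getitem(box_l, (pb, pa))
    dfl_per = dfl_loss(pos_box_logits, tdist, rm)
    dfl_loss_t = ad.tsum(ad.mul(ad.tmean(dfl_per, axis=1),
                                weights)) / ts_sum

    # mask loss: assembled prototype masks vs proto-resolution gt masks,
    # cropped to the gt box, normalised by box area
    protos = preds.protos
    hp, wp = protos.shape[2], protos.shape[3]
    nm = protos.shape[1]
    scale = hp / S
    mask_terms = []
    n_mask = 0
    for b in range(B):
        sel = pb == b
        if not sel.any():
            continue
        a_idx = pa[sel]
        g_idx = pg[sel]
        coefs = ad.getitem(coef_l, (np.full(a_idx.shape, b), a_idx))   # (P, nm)
        proto_flat = ad.reshape(protos[b], (nm, hp * wp))
        mlogits = ad.matmul(coefs, proto_flat)                          # (P, hp*wp)
        gt_masks = targets[b]["masks"][g_idx].reshape(len(g_idx), hp * wp)
        bce = ad.bce_with_logits(mlogits, gt_masks.astype(np.float32))
        gb = targets[b]["boxes"][g_idx] * scale
        crop = np.zeros((len(g_idx), hp, wp), dtype=np.float32)
        areas = np.ones(len(g_idx), dtype=np.float32)
        for i, (x0, y0, x1, y1) in enumerate(gb):
            ix0, iy0 = max(int(x0), 0), max(int(y0), 0)
            ix1, iy1 = min(int(np.ceil(x1)), wp), min(int(np.ceil(y1)), hp)
            crop[i, iy0:iy1, ix0:ix1] = 1.0
            areas[i] = max((iy1 - iy0) * (ix1 - ix0), 1)
        per_inst = ad.tsum(ad.mul(bce, crop.reshape(len(g_idx), -1)), axis=1)
        mask_terms.append(ad.tsum(per_inst / areas))
        n_mask += len(g_idx)
    if mask_terms:
        mask_loss = mask_terms[0]
        for t in mask_terms[1:]:
            mask_loss = ad.add(mask_loss, t)
        mask_loss = mask_loss / max(n_mask, 1)
    else:
        mask_loss = ad.astensor(np.zeros(()))

    total = (ad.mul(box_loss, cfg.box_weight) + ad.mul(cls_loss, cfg.cls_weight)
             + ad.mul(dfl_loss_t, cfg.dfl_weight) + ad.mul(mask_loss, cfg.mask_weight))
    breakdown = LossBreakdown(float(box_loss.data), float(cls_loss.data),
                              float(dfl_loss_t.data), float(mask_loss.data))
    return total, breakdown


# -- augmentations ---------------------------------------------------------

def _clip_instances(instances: list[InstanceAnnotation],
                    transform, frame: tuple[float, float, float, float]):
    """Apply an (x, y) -> (x, y) transform to normalised polygons and clip
    them to ``frame``; degenerate results are dropped."""
    out = []
    clip = shapely_box(*frame)
    for inst in instances:
        poly = transform(inst.polygon.copy())
        try:
            geom = Polygon(poly).buffer(0).intersection(clip)
        except Exception:
            continue
        if geom.is_empty:
            continue
        if geom.geom_type == "MultiPolygon":
            geom = max(geom.geoms, key=lambda g: g.area)
        if geom.geom_type != "Polygon" or geom.area < 1e-6:
            continue
        coords = np.asarray(geom.exterior.coords)[:-1]
        if len(coords) < 3:
            continue
        out.append(InstanceAnnotation(inst.class_id, np.clip(coords, 0, 1)))
    return out


def flip_horizontal(sample: ImageSample) -> ImageSample:
    def t(p):
        p[:, 0] = 1.0 - p[:, 0]
        return p
    return ImageSample(sample.image[:, ::-1].copy(),
                       _clip_instances(sample.instances, t, (0, 0, 1, 1)),
                       sample.source_id)


def flip_vertical(sample: ImageSample) -> ImageSample:
    def t(p):
        p[:, 1] = 1.0 - p[:, 1]
        return p
    return ImageSample(sample.image[::-1].copy(),
                       _clip_instances(sample.instances, t, (0, 0, 1, 1)),
                       sample.source_id)


def pixel_shift(sample: ImageSample, dx: int, dy: int,
                fill: int = 114) -> ImageSample:
    """Translate raster by (dx, dy) pixels with border fill; polygons
    follow and are clipped to the frame."""
    H, W = sample.height, sample.width
    canvas = np.full_like(sample.image, fill)
    sx0, sx1 = max(0, -dx), min(W, W - dx)
    sy0, sy1 = max(0, -dy), min(H, H - dy)
    if sx1 > sx0 and sy1 > sy0:
        canvas[sy0 + dy:sy1 + dy, sx0 + dx:sx1 + dx] = sample.image[sy0:sy1, sx0:sx1]

    def t(p):
        p[:, 0] += dx / W
        p[:, 1] += dy / H
        return p
    return ImageSample(canvas, _clip_instances(sample.instances, t, (0, 0, 1, 1)),
                       sample.source_id)


def mosaic(samples: list[ImageSample], rng: np.random.Generator,
           out_size: int | None = None) -> ImageSample:
    """Stitch 4 samples into one canvas around a random centre."""
    assert len(samples) == 4
    size = out_size or samples[0].height
    cx = rng.integers(size // 4, 3 * size // 4)
    cy = rng.integers(size // 4, 3 * size // 4)
    canvas = np.full((size, size, 3), 114, dtype=np.uint8)
    quads = [(0, 0, cx, cy), (cx, 0, size, cy), (0, cy, cx, size),
             (cx, cy, size, size)]
    instances = []
    for s, (x0, y0, x1, y1) in zip(samples, quads):
        w, h = x1 - x0, y1 - y0
        if w < 2 or h < 2:
            continue
        canvas[y0:y1, x0:x1] = bilinear_resize(s.image, h, w)

        def t(p, x0=x0, y0=y0, w=w, h=h):
            p[:, 0] = (x0 + p[:, 0] * w) / size
            p[:, 1] = (y0 + p[:, 1] * h) / size
            return p
        instances.extend(_clip_instances(
            s.instances, t, (x0 / size, y0 / size, x1 / size, y1 / size)))
    return ImageSample(canvas, instances, samples[0].source_id + "+mosaic")


def cutout(sample: ImageSample, rng: np.random.Generator,
           n_patches: int = 3, max_frac: float = 0.15) -> ImageSample:
    """Coarse dropout: grey patches pasted over the raster (labels kept)."""
    img = sample.image.copy()
    H, W = sample.height, sample.width
    for _ in range(n_patches):
        ph = int(rng.uniform(0.05, max_frac) * H)
        pw = int(rng.uniform(0.05, max_frac) * W)
        y = rng.integers(0, max(H - ph, 1))
        x = rng.integers(0, max(W - pw, 1))
        img[y:y + ph, x:x + pw] = rng.integers(0, 255, size=3)
    return ImageSample(img, list(sample.instances), sample.source_id)


def augment(sample: ImageSample, cfg: TrainConfig, rng: np.random.Generator,
            pool: list[ImageSample] | None = None,
            allow_mosaic: bool = True) -> ImageSample:
    """One randomised label-consistent augmentation pass."""
    s = sample
    if cfg.mosaic and allow_mosaic and pool and len(pool) >= 4 and rng.uniform() < 0.5:
        others = [pool[i] for i in rng.integers(0, len(pool), size=3)]
        s = mosaic([s] + others, rng)
    if cfg.fliplr and rng.uniform() < 0.5:
        s = flip_horizontal(s)
    if cfg.flipud and rng.uniform() < 0.5:
        s = flip_vertical(s)
    if cfg.pixel_shift and rng.uniform() < 0.5:
        dx = int(rng.integers(-cfg.shift_frac * s.width, cfg.shift_frac * s.width + 1))
        dy = int(rng.integers(-cfg.shift_frac * s.height, cfg.shift_frac * s.height + 1))
        s = pixel_shift(s, dx, dy)
    if cfg.dropout_rate > 0 and rng.uniform() < cfg.dropout_rate:
        s = cutout(s, rng)
    return s


# -- batching --------------------------------------------------------------

def sample_to_training_arrays(sample: ImageSample, spec: ModelSpec) -> tuple:
    """Resize to the model input and build target arrays (image tensor
    input, boxes px, classes, proto-resolution masks)."""
    S = spec.input_size
    s = resize_to_square(sample, S)
    x = s.image.astype(np.float32).transpose(2, 0, 1) / 255.0
    hp = S // spec.strides[0]
    boxes, cls, masks = [], [], []
    for inst in s.instances:
        x0, y0, x1, y1 = inst.bbox
        boxes.append([x0 * S, y0 * S, x1 * S, y1 * S])
        cls.append(inst.class_id)
        # rasterise 4x oversampled then pool, so instances thinner than a
        # prototype cell (stems) still produce non-empty mask targets
        fine = polygon_to_mask(inst.polygon, 4 * hp, 4 * hp)
        masks.append(fine.reshape(hp, 4, hp, 4).mean(axis=(1, 3)) >= 0.125)
    return x, {"boxes": np.array(boxes, dtype=np.float64).reshape(-1, 4),
               "cls": np.array(cls, dtype=int),
               "masks": np.array(masks, dtype=bool).reshape(-1, hp, hp)}


# -- optimiser and loop ----------------------------------------------------

class SGD:
    """SGD with momentum and decoupled-style weight decay on kernels."""

    def __init__(self, params, cfg: TrainConfig):
        self.params = list(params)
        self.cfg = cfg
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self, lr: float) -> None:
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.cfg.weight_decay and p.decay:
                g = g + self.cfg.weight_decay * p.data
            v *= self.cfg.momentum
            v += g
            p.data -= (lr * v).astype(p.data.dtype)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def lr_at(cfg: TrainConfig, epoch: int, step: int, steps_per_epoch: int) -> float:
    """Linear warmup over warmup_epochs, then cosine decay to lrf*lr0."""
    warm = cfg.warmup_epochs * steps_per_epoch
    t = epoch * steps_per_epoch + step
    if warm > 0 and t < warm:
        return cfg.lr0 * (t + 1) / warm
    span = max(cfg.epochs - cfg.warmup_epochs, 1)
    frac = min((epoch - cfg.warmup_epochs) / span, 1.0) if epoch >= cfg.warmup_epochs else 0.0
    return cfg.lr0 * (cfg.lrf + (1 - cfg.lrf) * 0.5 * (1 + np.cos(np.pi * frac)))


class DivergenceError(RuntimeError):
    pass


def train(model: SegmentationModel, train_set: list[ImageSample],
          val_set: list[ImageSample], cfg: TrainConfig,
          eval_map_every: int = 0, verbose: bool = False):
    """Train in place; returns (best_state_dict, curves).

    curves: list of per-epoch dicts (loss components, val loss, lr, and
    validation box mAP@50 when ``eval_map_every`` divides the epoch).
    Early stopping: validation loss not improving for ``patience`` epochs.
    """
    if not train_set:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.seed)
    spec = model.spec
    opt = SGD(model.parameters(), cfg)
    n = len(train_set)
    steps_per_epoch = max(1, int(np.ceil(n / cfg.batch_size)))
    val_arrays = [sample_to_training_arrays(s, spec) for s in val_set]
    curves = []
    best_val = np.inf
    best_state = {k: v.copy() for k, v in model.state_dict().items()}
    stale = 0
    for epoch in range(cfg.epochs):
        t0 = time.time()
        order = rng.permutation(n)
        allow_mosaic = epoch < cfg.epochs * (1 - cfg.mosaic_disable_frac)
        sums = {"box": 0.0, "cls": 0.0, "dfl": 0.0, "mask": 0.0, "total": 0.0}
        for step in range(steps_per_epoch):
            idx = order[step * cfg.batch_size:(step + 1) * cfg.batch_size]
            batch = []
            for i in idx:
                s = augment(train_set[i], cfg, rng, pool=train_set,
                            allow_mosaic=allow_mosaic)
                batch.append(sample_to_training_arrays(s, spec))
            xs = np.stack([b[0] for b in batch])
            targets = [b[1] for b in batch]
            preds = model.forward(xs, training=True)
            total, parts = compute_losses(preds, targets, spec, cfg)
            if not np.isfinite(total.data):
                raise DivergenceError(
                    f"non-finite loss at epoch {epoch} step {step}: {parts}")
            opt.zero_grad()
            total.backward()
            opt.step(lr_at(cfg, epoch, step, steps_per_epoch))
            sums["box"] += parts.box
            sums["cls"] += parts.cls
            sums["dfl"] += parts.dfl
            sums["mask"] += parts.mask
            sums["total"] += parts.total(cfg)
        rec = {f"train_{k}": v / steps_per_epoch for k, v in sums.items()}
        rec["epoch"] = epoch
        rec["lr"] = lr_at(cfg, epoch, steps_per_epoch - 1, steps_per_epoch)
        # validation loss (and optionally box mAP@50) without tape recording
        val_loss = np.nan
        if val_arrays:
            vl = 0.0
            nb = 0
            val_dets = [] if (eval_map_every and (epoch + 1) % eval_map_every == 0) else None
            for k in range(0, len(val_arrays), cfg.batch_size):
                chunk = val_arrays[k:k + cfg.batch_size]
                xs = np.stack([c[0] for c in chunk])
                with ad.no_grad():
                    preds = model.forward(xs, training=False)
                    tot, _ = compute_losses(preds, [c[1] for c in chunk], spec, cfg)
                vl += float(tot.data) * len(chunk)
                nb += len(chunk)
                if val_dets is not None:
                    from .postprocess import decode, nms, Detection
                    for bi in range(len(chunk)):
                        boxes, scores, cids, _, _ = decode(
                            preds, spec.input_size, spec.reg_max, 0.25, bi)
                        ok = (boxes[:, 2] > boxes[:, 0] + 1e-6) & (boxes[:, 3] > boxes[:, 1] + 1e-6)
                        boxes, scores, cids = boxes[ok], scores[ok], cids[ok]
                        keep = nms(boxes, scores, cids, 0.7)
                        val_dets.append([Detection(int(cids[j]), float(scores[j]),
                                                   tuple(boxes[j])) for j in keep])
            val_loss = vl / max(nb, 1)
            rec["val_loss"] = val_loss
            if val_dets is not None:
                from .metrics import evaluate
                gt_resized = [resize_to_square(s, spec.input_size) for s in val_set]
                repo = evaluate(val_dets, gt_resized, modes=("box",))
                rec["val_map50_box"] = repo.box["All"].ap50 if "All" in repo.box else 0.0
        rec["seconds"] = time.time() - t0
        curves.append(rec)
        if verbose:
            print("epoch %3d loss %.3f val %.3f (%.1fs)"
                  % (epoch, rec["train_total"], val_loss, rec["seconds"]), flush=True)
        if val_arrays:
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_state = {k: v.copy() for k, v in model.state_dict().items()}
                stale = 0
            else:
                stale += 1
                if stale > cfg.patience:
                    break
        else:
            best_state = {k: v.copy() for k, v in model.state_dict().items()}
    return best_state, curves


def curves_to_csv(curves: list[dict], path) -> None:
    import csv
    keys = sorted({k for rec in curves for k in rec})
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=keys)
        w.writeheader()
        for rec in curves:
            w.writerow(rec)
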