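"""Independent reference implementations used only by the tests.

Everything here is written as directly as possible — explicit loops over
output positions, per-pixel point-in-polygon tests, exhaustive pairwise
suppression — deliberately sharing no code with the package, so the
package's vectorised implementations can be checked against them.
"""

from __future__ import annotations

import numpy as np


def sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=np.float64)))


def silu(z):
    z = np.asarray(z, dtype=np.float64)
    return z * sigmoid(z)


def relu(z):
    return np.maximum(np.asarray(z, dtype=np.float64), 0.0)


def conv2d_naive(x, w, b=None, stride=1, padding=1):
    """Quadruple-loop dense convolution, float64."""
    x = np.asarray(x, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    B, C, H, W = x.shape
    Co, _, kh, kw = w.shape
    s, p = stride, padding
    Ho = (H + 2 * p - kh) // s + 1
    Wo = (W + 2 * p - kw) // s + 1
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    out = np.zeros((B, Co, Ho, Wo))
    for n in range(B):
        for co in range(Co):
            for i in range(Ho):
                for j in range(Wo):
                    acc = 0.0
                    for c in range(C):
                        for ky in range(kh):
                            for kx in range(kw):
                                acc += w[co, c, ky, kx] * xp[n, c, i * s + ky, j * s + kx]
                    out[n, co, i, j] = acc
    if b is not None:
        out += np.asarray(b, dtype=np.float64).reshape(1, Co, 1, 1)
    return out


def depthwise_naive(x, w, stride=1, padding=1, multiplier=1):
    x = np.asarray(x, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    B, C, H, W = x.shape
    Cm, _, kh, kw = w.shape
    s, p = stride, padding
    Ho = (H + 2 * p - kh) // s + 1
    Wo = (W + 2 * p - kw) // s + 1
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    out = np.zeros((B, Cm, Ho, Wo))
    for n in range(B):
        for cm in range(Cm):
            c = cm // multiplier
            for i in range(Ho):
                for j in range(Wo):
                    acc = 0.0
                    for ky in range(kh):
                        for kx in range(kw):
                            acc += w[cm, 0, ky, kx] * xp[n, c, i * s + ky, j * s + kx]
                    out[n, cm, i, j] = acc
    return out


def maxpool_naive(x, k, stride=1, padding=0):
    x = np.asarray(x, dtype=np.float64)
    B, C, H, W = x.shape
    s, p = stride, padding
    Ho = (H + 2 * p - k) // s + 1
    Wo = (W + 2 * p - k) // s + 1
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
    out = np.zeros((B, C, Ho, Wo))
    for n in range(B):
        for c in range(C):
            for i in range(Ho):
                for j in range(Wo):
                    out[n, c, i, j] = xp[n, c, i * s:i * s + k, j * s:j * s + k].max()
    return out


def batchnorm_eval_naive(x, gamma, beta, rmean, rvar, eps=1e-3):
    x = np.asarray(x, dtype=np.float64)
    C = x.shape[1]
    out = np.zeros_like(x)
    for c in range(C):
        out[:, c] = gamma[c] * (x[:, c] - rmean[c]) / np.sqrt(rvar[c] + eps) + beta[c]
    return out


def gap_naive(x):
    x = np.asarray(x, dtype=np.float64)
    B, C = x.shape[:2]
    out = np.zeros((B, C, 1, 1))
    for n in range(B):
        for c in range(C):
            out[n, c, 0, 0] = x[n, c].mean()
    return out


def conv_block_naive(layer, x):
    """Reference for blocks.Conv in eval mode, reading the layer's params."""
    y = conv2d_naive(x, layer.weight.data,
                     None if layer.bias is None else layer.bias.data,
                     stride=layer.s, padding=layer.p)
    if layer.bn is not None:
        y = batchnorm_eval_naive(y, layer.bn.gamma.data, layer.bn.beta.data,
                                 layer.bn.running_mean, layer.bn.running_var)
    if layer.act == "silu":
        y = silu(y)
    elif layer.act == "relu":
        y = relu(y)
    elif layer.act == "sigmoid":
        y = sigmoid(y)
    return y


def dwconv_block_naive(layer, x):
    y = depthwise_naive(x, layer.weight.data, stride=layer.s, padding=layer.p,
                        multiplier=layer.mult)
    if layer.bn is not None:
        y = batchnorm_eval_naive(y, layer.bn.gamma.data, layer.bn.beta.data,
                                 layer.bn.running_mean, layer.bn.running_var)
    if layer.act == "silu":
        y = silu(y)
    return y


def ghost_module_naive(gm, x):
    x1 = conv_block_naive(gm.primary, x)
    x2 = dwconv_block_naive(gm.cheap, x1)
    return np.concatenate([x1, x2], axis=1)


def se_naive(se, x):
    x = np.asarray(x, dtype=np.float64)
    pooled = gap_naive(x)
    h = relu(conv2d_naive(pooled, se.fc1.weight.data, se.fc1.bias.data,
                          stride=1, padding=0))
    s = sigmoid(conv2d_naive(h, se.fc2.weight.data, se.fc2.bias.data,
                             stride=1, padding=0))
    return x * s


def gam_naive(gam, x):
    x = np.asarray(x, dtype=np.float64)
    pooled = gap_naive(x)
    h = silu(conv2d_naive(pooled, gam.ch_fc1.weight.data, gam.ch_fc1.bias.data,
                          stride=1, padding=0))
    ac = sigmoid(conv2d_naive(h, gam.ch_fc2.weight.data, gam.ch_fc2.bias.data,
                              stride=1, padding=0))
    xc = x * ac
    sp = conv_block_naive(gam.sp_conv1, xc)
    asp = sigmoid(conv2d_naive(sp, gam.sp_conv2.weight.data,
                               gam.sp_conv2.bias.data, stride=1,
                               padding=gam.sp_conv2.p))
    return xc * asp


def ghost_bottleneck_naive(gb, x):
    y = ghost_module_naive(gb.ghost1, x)
    if gb.down is not None:
        y = dwconv_block_naive(gb.down, y)
    if gb.se is not None:
        y = se_naive(gb.se, y)
    y = ghost_module_naive(gb.ghost2, y)
    if gb.short_dw is None:
        short = np.asarray(x, dtype=np.float64)
    else:
        short = conv_block_naive(gb.short_pw, dwconv_block_naive(gb.short_dw, x))
    return y + short


def c2f_naive(block, x):
    y = conv_block_naive(block.cv1, x)
    c = block.c
    parts = [y[:, :c], y[:, c:]]
    for b in block.bottlenecks:
        z = conv_block_naive(b.cv2, conv_block_naive(b.cv1, parts[-1]))
        parts.append(parts[-1] + z if b.add else z)
    return conv_block_naive(block.cv2, np.concatenate(parts, axis=1))


def sppf_naive(block, x):
    y = conv_block_naive(block.cv1, x)
    p = block.k // 2
    y1 = maxpool_naive(y, block.k, 1, p)
    y2 = maxpool_naive(y1, block.k, 1, p)
    y3 = maxpool_naive(y2, block.k, 1, p)
    return conv_block_naive(block.cv2, np.concatenate([y, y1, y2, y3], axis=1))


def point_in_polygon(px, py, poly):
    """Even-odd rule ray crossing test for a single point."""
    inside = False
    n = len(poly)
    for i in range(n):
        x0, y0 = poly[i]
        x1, y1 = poly[(i + 1) % n]
        if (y0 <= py < y1) or (y1 <= py < y0):
            xc = x0 + (py - y0) * (x1 - x0) / (y1 - y0)
            if px < xc:
                inside = not inside
    return inside


def polygon_mask_naive(polygon, height, width):
    """Exhaustive pixel-centre point-in-polygon rasterisation."""
    poly = np.asarray(polygon, dtype=np.float64) * [width, height]
    mask = np.zeros((height, width), dtype=bool)
    for i in range(height):
        for j in range(width):
            mask[i, j] = point_in_polygon(j + 0.5, i + 0.5, poly)
    return mask


def nms_naive(boxes, scores, class_ids, iou_threshold):
    """O(n^2) greedy suppression, classwise, ties by lower index."""
    def iou(a, b):
        ix0, iy0 = max(a[0], b[0]), max(a[1], b[1])
        ix1, iy1 = min(a[2], b[2]), min(a[3], b[3])
        iw, ih = max(ix1 - ix0, 0.0), max(iy1 - iy0, 0.0)
        inter = iw * ih
        ua = (a[2] - a[0]) * (a[3] - a[1]) + (b[2] - b[0]) * (b[3] - b[1]) - inter
        return inter / ua if ua > 0 else 0.0

    n = len(boxes)
    order = sorted(range(n), key=lambda i: (-scores[i], i))
    suppressed = [False] * n
    keep = []
    for i in order:
        if suppressed[i]:
            continue
        keep.append(i)
        for j in order:
            if j == i or suppressed[j] or class_ids[j] != class_ids[i]:
                continue
            if scores[j] < scores[i] or (scores[j] == scores[i] and j > i):
                if iou(boxes[i], boxes[j]) > iou_threshold:
                    suppressed[j] = True
    return sorted(keep)


def average_precision_naive(tp_flags, n_gt):
    """Direct 101-point interpolated AP by definition."""
    tp_flags = list(tp_flags)
    if n_gt == 0:
        return None if not tp_flags else 0.0
    if not tp_flags:
        return 0.0
    tp = fp = 0
    pr = []
    for f in tp_flags:
        tp += bool(f)
        fp += not f
        pr.append((tp / n_gt, tp / (tp + fp)))
    total = 0.0
    for r in np.linspace(0, 1, 101):
        best = 0.0
        for rec, prec in pr:
            if rec >= r - 1e-12:
                best = max(best, max(p for rc, p in pr if rc >= r - 1e-12))
                break
        total += best
    return total / 101


def softmax_expectation_naive(logits, reg_max):
    """Per-side expected bin index by direct summation."""
    logits = np.asarray(logits, dtype=np.float64).reshape(4, reg_max)
    out = np.zeros(4)
    for side in range(4):
        e = np.exp(logits[side] - logits[side].max())
        p = e / e.sum()
        out[side] = sum(b * p[b] for b in range(reg_max))
    return out
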