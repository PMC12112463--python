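"""Independent brute-force reference implementations used only by tests.

Everything here is deliberately naive — explicit Python loops, no shared
code with the package — so agreement between package and oracle is a real
cross-check rather than a tautology.
"""

from __future__ import annotations

import numpy as np


def naive_conv2d(x, w, bias=None, stride=1, padding=0, dilation=1, groups=1):
    """Direct spatial-loop cross-correlation."""
    b, c, h, wd = x.shape
    o, cg, kh, kw = w.shape
    xp = np.zeros((b, c, h + 2 * padding, wd + 2 * padding))
    xp[:, :, padding : padding + h, padding : padding + wd] = x
    ho = (h + 2 * padding - dilation * (kh - 1) - 1) // stride + 1
    wo = (wd + 2 * padding - dilation * (kw - 1) - 1) // stride + 1
    y = np.zeros((b, o, ho, wo))
    og = o // groups
    for bi in range(b):
        for oi in range(o):
            g = oi // og
            for i in range(ho):
                for j in range(wo):
                    acc = 0.0
                    for ci in range(cg):
                        for u in range(kh):
                            for v in range(kw):
                                acc += (
                                    w[oi, ci, u, v]
                                    * xp[bi, g * cg + ci, i * stride + u * dilation, j * stride + v * dilation]
                                )
                    y[bi, oi, i, j] = acc + (bias[oi] if bias is not None else 0.0)
    return y


def naive_maxpool2d(x, k, stride, padding):
    b, c, h, w = x.shape
    xp = np.full((b, c, h + 2 * padding, w + 2 * padding), -np.inf)
    xp[:, :, padding : padding + h, padding : padding + w] = x
    ho = (h + 2 * padding - k) // stride + 1
    wo = (w + 2 * padding - k) // stride + 1
    y = np.zeros((b, c, ho, wo))
    for bi in range(b):
        for ci in range(c):
            for i in range(ho):
                for j in range(wo):
                    y[bi, ci, i, j] = xp[
                        bi, ci, i * stride : i * stride + k, j * stride : j * stride + k
                    ].max()
    return y


def naive_avgpool2d(x, k, stride):
    b, c, h, w = x.shape
    ho = (h - k) // stride + 1
    wo = (w - k) // stride + 1
    y = np.zeros((b, c, ho, wo))
    for bi in range(b):
        for ci in range(c):
            for i in range(ho):
                for j in range(wo):
                    y[bi, ci, i, j] = x[
                        bi, ci, i * stride : i * stride + k, j * stride : j * stride + k
                    ].mean()
    return y


def corner_iou(a, b):
    """IoU from (cx, cy, w, h) tuples via corner arithmetic (independent path)."""
    ax1, ay1, ax2, ay2 = a[0] - a[2] / 2, a[1] - a[3] / 2, a[0] + a[2] / 2, a[1] + a[3] / 2
    bx1, by1, bx2, by2 = b[0] - b[2] / 2, b[1] - b[3] / 2, b[0] + b[2] / 2, b[1] + b[3] / 2
    iw = min(ax2, bx2) - max(ax1, bx1)
    ih = min(ay2, by2) - max(ay1, by1)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    return inter / (a[2] * a[3] + b[2] * b[3] - inter)


def step_integrate_ap(confidences, is_tp, n_gt):
    """AP by explicit step integration over the envelope of the P-R staircase.

    Walks the confidence-sorted detection list, accumulates (recall,
    precision) points, then integrates precision over recall using, at each
    recall level, the maximum precision at that recall or beyond.
    """
    order = sorted(range(len(confidences)), key=lambda i: -confidences[i])
    points = []
    tp = fp = 0
    for i in order:
        if is_tp[i]:
            tp += 1
        else:
            fp += 1
        points.append((tp / n_gt, tp / (tp + fp)))
    ap = 0.0
    prev_r = 0.0
    for k, (r, _) in enumerate(points):
        if r == prev_r:
            continue
        best_p = max(p for rr, p in points[k:])
        ap += (r - prev_r) * best_p
        prev_r = r
    return ap
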