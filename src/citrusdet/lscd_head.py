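"""Detection heads and anchor-free post-processing.

Two heads share the decode/NMS contract:

* ``BaselineDetect`` -- the stock decoupled head of the nano baseline: per
  pyramid level, separate 3x3 conv stacks for box regression (4 * reg_max
  distribution channels) and classification (nc channels).

* ``LSCDHead`` -- the lightweight shared-convolution head: a per-level 1x1
  Conv_GN that unifies channel widths (this layer is *not* shared because
  the levels differ in input width), a shared group-normalized 3x3 trunk,
  shared 1x1 regression/classification projections, and a learnable scalar
  scale per level applied to the regression output so each level can match
  its own box-size regime.

Boxes are decoded anchor-free: each cell predicts four side distances
(left, top, right, bottom) as discrete distributions over ``reg_max`` bins,
decoded by expectation (soft-argmax) in stride units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Parameter, Tensor, concat
from .nn_blocks import ConvBNSiLU, ConvGN, Module, Scale

__all__ = ["BaselineDetect", "LSCDHead", "Detection", "decode_boxes", "nms",
           "box_iou", "STRIDES"]

STRIDES = (8, 16, 32)


@dataclass(frozen=True)
class Detection:
    """A scored class box in pixel coordinates, origin top-left, half-open."""
    class_id: int
    score: float
    box: tuple  # (x1, y1, x2, y2)


def _dfl_proj(reg_max: int) -> Parameter:
    # fixed expectation projection over distribution bins; counted, frozen
    return Parameter(np.arange(reg_max, dtype=np.float32), frozen=True)


class BaselineDetect(Module):
    """Stock decoupled anchor-free head (per-level conv stacks, no sharing)."""

    def __init__(self, nc: int, ch=(64, 128, 256), reg_max: int = 16, rng=None):
        super().__init__()
        self.nc, self.reg_max, self.ch = nc, reg_max, tuple(ch)
        c2 = max(16, ch[0] // 4, reg_max * 4)
        c3 = max(ch[0], min(nc, 100))
        rngs = rng or np.random.default_rng(0)
        self.box_stems = [ConvBNSiLU(c, c2, 3, rng=rngs) for c in ch]
        self.box_mids = [ConvBNSiLU(c2, c2, 3, rng=rngs) for c in ch]
        self.box_outs = [_PlainConv1x1(c2, 4 * reg_max, rngs) for c in ch]
        self.cls_stems = [ConvBNSiLU(c, c3, 3, rng=rngs) for c in ch]
        self.cls_mids = [ConvBNSiLU(c3, c3, 3, rng=rngs) for c in ch]
        self.cls_outs = [_PlainConv1x1(c3, nc, rngs) for c in ch]
        self.dfl = _dfl_proj(reg_max)
        # prior-based head bias: few objects per cell at initialization
        for s, box_o, cls_o in zip(STRIDES, self.box_outs, self.cls_outs):
            box_o.bias.data[:] = 1.0
            cls_o.bias.data[:] = np.log(5.0 / nc / (640.0 / s) ** 2)

    def forward(self, feats):
        out = []
        for i, x in enumerate(feats):
            box = self.box_outs[i](self.box_mids[i](self.box_stems[i](x)))
            cls = self.cls_outs[i](self.cls_mids[i](self.cls_stems[i](x)))
            out.append(concat([box, cls], axis=1))
        return out


class _PlainConv1x1(Module):
    """1x1 conv with bias and no norm/activation (head projections)."""

    def __init__(self, c1, c2, rng):
        super().__init__()
        self.weight = Parameter(
            (rng.standard_normal((c2, c1, 1, 1)) *
             np.sqrt(1.0 / c1)).astype(np.float32))
        self.bias = Parameter(np.zeros(c2, np.float32))

    def forward(self, x):
        return x.conv2d(self.weight, self.bias)


class LSCDHead(Module):
    """Lightweight shared-convolution, group-normalized detection head.

    ``widths`` are the calibrated trunk widths (unify, mid, out); the 3x3
    trunk and the final projections are shared across pyramid levels and so
    contribute their parameters once.
    """

    def __init__(self, nc: int, ch=(64, 128, 256), widths=(65, 55, 64),
                 reg_max: int = 16, rng=None):
        super().__init__()
        rngs = rng or np.random.default_rng(0)
        h1, h2, h3 = widths
        self.nc, self.reg_max, self.ch = nc, reg_max, tuple(ch)
        self.widths = tuple(widths)
        self.unify = [ConvGN(c, h1, 1, rng=rngs) for c in ch]
        self.trunk1 = ConvGN(h1, h2, 3, rng=rngs)
        self.trunk2 = ConvGN(h2, h3, 3, rng=rngs)
        self.reg_out = _PlainConv1x1(h3, 4 * reg_max, rngs)
        self.cls_out = _PlainConv1x1(h3, nc, rngs)
        self.scales = [Scale(1.0) for _ in ch]
        self.dfl = _dfl_proj(reg_max)
        # prior-based bias for the shared projections (middle-level prior)
        self.reg_out.bias.data[:] = 1.0
        self.cls_out.bias.data[:] = np.log(5.0 / nc / (640.0 / 16) ** 2)

    def forward(self, feats):
        if len(feats) != len(self.ch):
            raise ValueError("expected one feature map per pyramid level")
        out = []
        for i, x in enumerate(feats):
            if x.shape[1] != self.ch[i]:
                raise ValueError(
                    f"level {i}: {x.shape[1]} channels, expected {self.ch[i]}")
            y = self.unify[i](x)
            y = self.trunk2(self.trunk1(y))
            box = self.scales[i](self.reg_out(y))
            cls = self.cls_out(y)
            out.append(concat([box, cls], axis=1))
        return out


# ------------------------------------------------------------- postprocessing
def decode_boxes(raw, reg_max: int = 16, conf_threshold: float = 0.25,
                 strides=STRIDES, image_size=None):
    """Decode raw per-level prediction maps into pixel-space detections.

    Per cell, the four side distances are the expectation over the softmax of
    `reg_max` bins (stride units); box corners are (cell center -/+ distance)
    * stride.  Class scores pass through a logistic; cells below
    `conf_threshold` are dropped; boxes are clipped to `image_size` if given.
    """
    if not 0.0 <= conf_threshold <= 1.0:
        raise ValueError("conf_threshold must lie in [0, 1]")
    dets = []
    bins = np.arange(reg_max, dtype=np.float64)
    for level, stride in zip(raw, strides):
        a = np.asarray(level, dtype=np.float64)
        if a.ndim == 4:
            if a.shape[0] != 1:
                raise ValueError("decode_boxes expects a single image")
            a = a[0]
        nch, h, w = a.shape
        nc = nch - 4 * reg_max
        reg = a[:4 * reg_max].reshape(4, reg_max, h, w)
        e = np.exp(reg - reg.max(axis=1, keepdims=True))
        dist = np.tensordot(bins, e / e.sum(axis=1, keepdims=True), axes=(0, 1))
        cls = np.exp(-np.logaddexp(0.0, -a[4 * reg_max:]))  # stable sigmoid
        cy, cx = np.mgrid[0:h, 0:w]
        cx = cx + 0.5
        cy = cy + 0.5
        x1 = (cx - dist[0]) * stride
        y1 = (cy - dist[1]) * stride
        x2 = (cx + dist[2]) * stride
        y2 = (cy + dist[3]) * stride
        if image_size is not None:
            iw, ih = (image_size, image_size) if np.isscalar(image_size) \
                else image_size
            x1, x2 = np.clip(x1, 0, iw), np.clip(x2, 0, iw)
            y1, y2 = np.clip(y1, 0, ih), np.clip(y2, 0, ih)
        best = cls.argmax(axis=0)
        score = cls.max(axis=0)
        keep = score >= conf_threshold
        if conf_threshold >= 1.0:       # logistic scores are strictly < 1
            keep[:] = False
        for yy, xx in zip(*np.nonzero(keep)):
            b = (float(x1[yy, xx]), float(y1[yy, xx]),
                 float(x2[yy, xx]), float(y2[yy, xx]))
            if b[0] < b[2] and b[1] < b[3]:
                dets.append(Detection(int(best[yy, xx]),
                                      float(score[yy, xx]), b))
    return dets


def box_iou(a, b) -> float:
    """Intersection-over-union of two (x1, y1, x2, y2) boxes."""
    ix = max(0.0, min(a[2], b[2]) - max(a[0], b[0]))
    iy = max(0.0, min(a[3], b[3]) - max(a[1], b[1]))
    inter = ix * iy
    if inter == 0.0:
        return 0.0
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    return inter / (area_a + area_b - inter)


def nms(dets, iou_threshold: float = 0.45):
    """Greedy per-class non-maximum suppression.

    Detections are visited in descending score (ties broken by box
    coordinates lexicographically, so the result is independent of input
    order); a box is removed iff its IoU with an already-kept higher-scoring
    box of the same class is strictly greater than `iou_threshold`.
    """
    if not 0.0 < iou_threshold <= 1.0:
        raise ValueError("iou_threshold must lie in (0, 1]")
    kept = []
    by_class = {}
    for d in dets:
        by_class.setdefault(d.class_id, []).append(d)
    for cid in sorted(by_class):
        cand = sorted(by_class[cid], key=lambda d: (-d.score, d.box))
        chosen = []
        for d in cand:
            if all(box_iou(d.box, k.box) <= iou_threshold for k in chosen):
                chosen.append(d)
        kept.extend(chosen)
    return kept
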