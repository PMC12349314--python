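"""Training loop and detection metrics.

The objective is the standard anchor-free YOLO-style composite: binary
cross-entropy classification on task-aligned soft targets, complete-IoU box
regression and a distribution-focal term over the discretized side
distances, weighted 0.5 / 7.5 / 1.5.  Target assignment is task-aligned
(candidates = anchors whose center lies inside a ground-truth box; metric =
score^alpha * IoU^beta with alpha = 0.5, beta = 6.0; top-10 per ground
truth; conflicts resolved toward the higher metric).

Evaluation follows the COCO-style protocol at IoU 0.5: greedy score-ranked
matching, per-class precision/recall, all-point interpolated average
precision (area under the precision envelope over recall) and F1.
"""

from __future__ import annotations

import csv
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .autodiff import Tensor, concat, maximum, minimum
from .lscd_head import Detection, box_iou, decode_boxes, nms
from .model_zoo import DetectionModel, save_checkpoint

__all__ = [
    "HyperParams", "MatchResult", "MetricsReport", "TAL_TOPK", "TAL_ALPHA",
    "TAL_BETA", "compute_loss", "train", "match_detections",
    "precision_recall", "average_precision", "map50", "f1_score",
    "measure_fps", "evaluate", "dataset_from_scenes", "dataset_from_dir",
]

TAL_TOPK, TAL_ALPHA, TAL_BETA = 10, 0.5, 6.0
LOSS_W_CLS, LOSS_W_BOX, LOSS_W_DFL = 0.5, 7.5, 1.5


@dataclass
class HyperParams:
    """Training hyperparameters; the defaults are the reference recipe
    (SGD, initial learning rate 1e-3, momentum 0.937, weight decay 5e-4,
    batch 16, 640 px input)."""
    lr0: float = 0.001
    momentum: float = 0.937
    weight_decay: float = 0.0005
    batch: int = 16
    img: int = 640
    epochs: int = 100
    seed: int = 0
    optimizer: str = "sgd"
    lrf: float = 0.01           # final lr fraction (linear decay)

    def __post_init__(self):
        if min(self.lr0, self.momentum, self.weight_decay, self.batch,
               self.img) <= 0 or self.epochs < 0:
            raise ValueError("hyperparameters must be positive (epochs >= 0)")
        if self.optimizer != "sgd":
            raise ValueError("only sgd is supported")


# --------------------------------------------------------------------- data
def dataset_from_scenes(scenes):
    """[(CHW float32 image in [0,1], (n,5) labels array)] from LabeledImages."""
    out = []
    for s in scenes:
        img = (s.image.astype(np.float32) / 255.0).transpose(2, 0, 1)
        lab = np.array(s.labels, np.float32).reshape(-1, 5)
        out.append((np.ascontiguousarray(img), lab))
    return out


def dataset_from_dir(root, split: str = "train"):
    """Load a dataset written by `synth_orchard.make_dataset`."""
    import yaml
    root = Path(root)
    man = yaml.safe_load((root / "manifest.yaml").read_text())
    out = []
    for stem in man["splits"][split]:
        img = np.asarray(Image.open(root / "images" / f"{stem}.png"),
                         np.float32) / 255.0
        from .synth_orchard import read_yolo_labels
        lab = np.array(read_yolo_labels(root / "labels" / f"{stem}.txt"),
                       np.float32).reshape(-1, 5)
        out.append((np.ascontiguousarray(img.transpose(2, 0, 1)), lab))
    return out


def _anchors(img_size, strides=(8, 16, 32)):
    pts, strs = [], []
    for s in strides:
        n = img_size // s
        cy, cx = np.mgrid[0:n, 0:n]
        pts.append(np.stack([(cx.ravel() + 0.5) * s, (cy.ravel() + 0.5) * s],
                            axis=1))
        strs.append(np.full(n * n, s, np.float32))
    return np.concatenate(pts).astype(np.float32), np.concatenate(strs)


def _iou_matrix(boxes_a, boxes_b):
    """IoU between (n,4) and (m,4) xyxy boxes."""
    x1 = np.maximum(boxes_a[:, None, 0], boxes_b[None, :, 0])
    y1 = np.maximum(boxes_a[:, None, 1], boxes_b[None, :, 1])
    x2 = np.minimum(boxes_a[:, None, 2], boxes_b[None, :, 2])
    y2 = np.minimum(boxes_a[:, None, 3], boxes_b[None, :, 3])
    inter = np.clip(x2 - x1, 0, None) * np.clip(y2 - y1, 0, None)
    area_a = (boxes_a[:, 2] - boxes_a[:, 0]) * (boxes_a[:, 3] - boxes_a[:, 1])
    area_b = (boxes_b[:, 2] - boxes_b[:, 0]) * (boxes_b[:, 3] - boxes_b[:, 1])
    return inter / np.clip(area_a[:, None] + area_b[None] - inter, 1e-9, None)


def _assign(scores, pboxes, anchors, gt_boxes, gt_cls):
    """Task-aligned assignment for one image.

    Returns (fg_mask, assigned_gt_index, target_scores (A, nc))."""
    A, nc = scores.shape
    G = len(gt_boxes)
    t_scores = np.zeros((A, nc), np.float32)
    fg = np.zeros(A, bool)
    agt = np.full(A, -1)
    if G == 0:
        return fg, agt, t_scores
    inside = ((anchors[:, 0][:, None] > gt_boxes[None, :, 0]) &
              (anchors[:, 0][:, None] < gt_boxes[None, :, 2]) &
              (anchors[:, 1][:, None] > gt_boxes[None, :, 1]) &
              (anchors[:, 1][:, None] < gt_boxes[None, :, 3]))
    iou = _iou_matrix(pboxes, gt_boxes)
    metric = (scores[:, gt_cls] ** TAL_ALPHA) * (iou ** TAL_BETA)
    metric = np.where(inside, metric, 0.0)
    mask = np.zeros_like(inside)
    k = min(TAL_TOPK, A)
    top = np.argpartition(-metric, k - 1, axis=0)[:k]
    for g in range(G):
        sel = top[:, g]
        sel = sel[metric[sel, g] > 0]
        mask[sel, g] = True
    # conflicts: anchor serves the gt with the highest metric
    multi = mask.sum(axis=1) > 1
    if multi.any():
        best = np.where(mask[multi], metric[multi], -1.0).argmax(axis=1)
        mask[multi] = False
        mask[np.nonzero(multi)[0], best] = True
    fg = mask.any(axis=1)
    agt[fg] = mask[fg].argmax(axis=1)
    # normalized soft targets (per gt: metric scaled to its best IoU)
    pos_metric = np.where(mask, metric, 0.0)
    pos_iou = np.where(mask, iou, 0.0)
    denom = pos_metric.max(axis=0, keepdims=True) + 1e-9
    norm = pos_metric / denom * pos_iou.max(axis=0, keepdims=True)
    t = norm.max(axis=1)
    t_scores[fg, gt_cls[agt[fg]]] = t[fg]
    return fg, agt, t_scores


def _bce_with_logits(x: Tensor, t: np.ndarray) -> Tensor:
    """Elementwise stable binary cross-entropy with logits."""
    absx = x.relu() + (-x).relu()
    return x.relu() - x * t + ((-absx).exp() + 1.0).log()


def compute_loss(raw, targets, img_size, num_classes, reg_max=16,
                 strides=(8, 16, 32)):
    """Composite detection loss for a batch.

    `raw`: list of per-level Tensors (B, 4*reg_max+nc, H, W); `targets`:
    per-image (n, 5) arrays of (class, cx, cy, w, h) normalized labels.
    Returns (total, parts) with parts = dict(box=..., cls=..., dfl=...)
    as floats.
    """
    if not raw or raw[0].shape[0] == 0:
        raise ValueError("empty batch")
    B = raw[0].shape[0]
    if len(targets) != B:
        raise ValueError("one target array per image required")
    nc = num_classes
    anchors, astr = _anchors(img_size, strides)
    A = len(anchors)
    # flatten levels -> (B, A, .)
    dists, clss = [], []
    for lvl in raw:
        b, ch, h, w = lvl.shape
        flat = lvl.reshape(b, ch, h * w).transpose(0, 2, 1)
        dists.append(flat[:, :, :4 * reg_max])
        clss.append(flat[:, :, 4 * reg_max:])
    pred_dist = concat(dists, axis=1).reshape(B, A, 4, reg_max)
    pred_cls = concat(clss, axis=1)                      # (B, A, nc)
    bins = np.arange(reg_max, dtype=np.float32)
    dist_sm = pred_dist.softmax(axis=3)
    dist_exp = (dist_sm * bins.reshape(1, 1, 1, reg_max)).sum(axis=3)
    # predicted boxes in pixels (autodiff)
    ax = anchors[:, 0][None, :]
    ay = anchors[:, 1][None, :]
    st = astr[None, :]
    px1 = ax - dist_exp[:, :, 0] * st
    py1 = ay - dist_exp[:, :, 1] * st
    px2 = ax + dist_exp[:, :, 2] * st
    py2 = ay + dist_exp[:, :, 3] * st

    t_scores = np.zeros((B, A, nc), np.float32)
    m_b, m_a, m_gt, m_w = [], [], [], []
    gt_boxes_all = []
    sig = np.exp(-np.logaddexp(0.0, -pred_cls.data))
    pbox_np = np.stack([px1.data, py1.data, px2.data, py2.data], axis=2)
    for i, lab in enumerate(targets):
        lab = np.asarray(lab, np.float32).reshape(-1, 5)
        if len(lab) == 0:
            gt_boxes_all.append(np.zeros((0, 4), np.float32))
            continue
        cxy = lab[:, 1:3] * img_size
        wh = lab[:, 3:5] * img_size
        gtb = np.concatenate([cxy - wh / 2, cxy + wh / 2], axis=1)
        gt_boxes_all.append(gtb)
        fg, agt, ts = _assign(sig[i], pbox_np[i], anchors, gtb,
                              lab[:, 0].astype(int))
        t_scores[i] = ts
        idx = np.nonzero(fg)[0]
        m_b.extend([i] * len(idx))
        m_a.extend(idx)
        m_gt.append(gtb[agt[idx]])
        m_w.extend(ts[idx].sum(axis=1))

    tsum = max(float(t_scores.sum()), 1.0)
    cls_loss = _bce_with_logits(pred_cls, t_scores).sum() * (1.0 / tsum)

    if m_b:
        bi = np.array(m_b)
        ai = np.array(m_a)
        gtb = np.concatenate(m_gt, axis=0)
        wts = np.array(m_w, np.float32)
        wsum = max(float(wts.sum()), 1e-9)
        x1, y1 = px1[(bi, ai)], py1[(bi, ai)]
        x2, y2 = px2[(bi, ai)], py2[(bi, ai)]
        ciou = _ciou(x1, y1, x2, y2, gtb)
        box_loss = ((1.0 - ciou) * wts).sum() * (1.0 / wsum)
        # distribution-focal targets: gt side distances in stride units
        s_m = astr[ai]
        d_t = np.stack([(anchors[ai, 0] - gtb[:, 0]) / s_m,
                        (anchors[ai, 1] - gtb[:, 1]) / s_m,
                        (gtb[:, 2] - anchors[ai, 0]) / s_m,
                        (gtb[:, 3] - anchors[ai, 1]) / s_m], axis=1)
        d_t = np.clip(d_t, 0, reg_max - 1 - 1e-2)
        tl = np.floor(d_t).astype(int)
        wr = d_t - tl
        wl = 1.0 - wr
        ls = pred_dist[(bi, ai)].log_softmax(axis=2)     # (M, 4, reg_max)
        mi = np.arange(len(bi))[:, None]
        side = np.arange(4)[None, :]
        dfl = -(ls[(mi, side, tl)] * wl + ls[(mi, side, np.minimum(tl + 1, reg_max - 1))] * wr)
        dfl_loss = (dfl.mean(axis=1) * wts).sum() * (1.0 / wsum)
    else:
        box_loss = Tensor(0.0)
        dfl_loss = Tensor(0.0)

    total = cls_loss * LOSS_W_CLS + box_loss * LOSS_W_BOX + dfl_loss * LOSS_W_DFL
    parts = dict(cls=float(cls_loss.data), box=float(box_loss.data),
                 dfl=float(dfl_loss.data), total=float(total.data))
    return total, parts


def _ciou(x1, y1, x2, y2, gtb):
    """Complete IoU between predicted corner Tensors and (m,4) gt boxes."""
    g1, g2, g3, g4 = (Tensor(gtb[:, i]) for i in range(4))
    iw = minimum(x2, g3) - maximum(x1, g1)
    ih = minimum(y2, g4) - maximum(y1, g2)
    inter = iw.clip(0, np.inf) * ih.clip(0, np.inf)
    area_p = (x2 - x1).clip(0, np.inf) * (y2 - y1).clip(0, np.inf)
    area_g = (g3 - g1) * (g4 - g2)
    union = area_p + area_g - inter + 1e-7
    iou = inter / union
    # enclosing box diagonal and center distance
    cw = maximum(x2, g3) - minimum(x1, g1)
    chh = maximum(y2, g4) - minimum(y1, g2)
    c2 = cw * cw + chh * chh + 1e-7
    rho2 = ((x1 + x2 - g1 - g3) ** 2 + (y1 + y2 - g2 - g4) ** 2) * 0.25
    wp = (x2 - x1).clip(1e-6, np.inf)
    hp = (y2 - y1).clip(1e-6, np.inf)
    wg = g3 - g1
    hg = g4 - g2
    v = (4.0 / np.pi ** 2) * ((wg / hg).atan() - (wp / hp).atan()) ** 2
    alpha = v.data / np.clip(1.0 - iou.data + v.data, 1e-7, None)  # detached
    return iou - rho2 / c2 - v * alpha


# ----------------------------------------------------------------- optimizer
class _SGD:
    def __init__(self, params, hp: HyperParams):
        self.params = [p for p in params if not getattr(p, "frozen", False)]
        self.hp = hp
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.lr = hp.lr0

    def step(self):
        hp = self.hp
        for p, v in zip(self.params, self.v):
            if p.grad is None:
                continue
            g = p.grad
            if hp.weight_decay and p.data.ndim > 1:
                g = g + hp.weight_decay * p.data
            v *= hp.momentum
            v += g
            p.data = p.data - self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def train(model: DetectionModel, dataset, hp: HyperParams, val_dataset=None,
          ckpt_dir=None, quiet: bool = True):
    """Seeded SGD training.  Checkpoints every 10 epochs (when `ckpt_dir`
    is given) and keeps the best weights by validation mAP@.5.  Returns the
    per-epoch history list."""
    if not dataset:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(hp.seed)
    opt = _SGD(model.parameters(), hp)
    nc = model.cfg.num_classes
    history = []
    best = (-1.0, None)
    n = len(dataset)
    for epoch in range(hp.epochs):
        model.train()
        frac = epoch / max(hp.epochs - 1, 1)
        opt.lr = hp.lr0 * (1.0 - (1.0 - hp.lrf) * frac)
        if epoch < 3 and hp.epochs > 5:      # brief linear warmup
            opt.lr *= (epoch + 1) / 3.0
        order = rng.permutation(n)
        tot = dict(cls=0.0, box=0.0, dfl=0.0, total=0.0)
        nb = 0
        for s in range(0, n, hp.batch):
            idx = order[s:s + hp.batch]
            imgs = np.stack([dataset[i][0] for i in idx])
            labs = [dataset[i][1] for i in idx]
            raw = model(Tensor(imgs))
            loss, parts = compute_loss(raw, labs, hp.img, nc,
                                       reg_max=model.cfg.reg_max)
            opt.zero_grad()
            loss.backward()
            opt.step()
            for k in tot:
                tot[k] += parts[k]
            nb += 1
        rec = {k: v / nb for k, v in tot.items()}
        rec.update(epoch=epoch, lr=opt.lr)
        if val_dataset is not None:
            # low threshold: mAP integrates the whole PR curve
            rep = evaluate(model, val_dataset, img_size=hp.img,
                           conf_threshold=0.05)
            rec["val_map50"] = rep.map50
            if rep.map50 > best[0]:
                best = (rep.map50, model.state_dict())
        history.append(rec)
        if not quiet:
            print(f"epoch {epoch}: " +
                  " ".join(f"{k}={v:.4f}" for k, v in rec.items()
                           if k != "epoch"))
        if ckpt_dir is not None and (epoch + 1) % 10 == 0:
            Path(ckpt_dir).mkdir(parents=True, exist_ok=True)
            save_checkpoint(model, Path(ckpt_dir) / f"epoch_{epoch+1}.npz")
    if best[1] is not None:
        model.load_state_dict(best[1])
        if ckpt_dir is not None:
            save_checkpoint(model, Path(ckpt_dir) / "best.npz")
    return history


# ------------------------------------------------------------------- metrics
@dataclass
class MatchResult:
    """Per-class TP/FP/FN counts plus score-ranked TP/FP flag sequences."""
    per_class: dict = field(default_factory=dict)

    def counts(self):
        tp = sum(c["tp"] for c in self.per_class.values())
        fp = sum(c["fp"] for c in self.per_class.values())
        fn = sum(c["fn"] for c in self.per_class.values())
        return tp, fp, fn

    def merge(self, other: "MatchResult"):
        for cid, c in other.per_class.items():
            mine = self.per_class.setdefault(
                cid, dict(tp=0, fp=0, fn=0, flags=[], n_gt=0))
            for k in ("tp", "fp", "fn", "n_gt"):
                mine[k] += c[k]
            mine["flags"].extend(c["flags"])
        return self


@dataclass
class MetricsReport:
    per_class: dict
    precision: float
    recall: float
    map50: float
    f1: float

    def to_json(self) -> str:
        return json.dumps(dict(per_class=self.per_class, P=self.precision,
                               R=self.recall, mAP50=self.map50, F1=self.f1),
                          indent=2)

    def to_csv(self, path):
        with open(path, "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(["class", "P", "R", "AP50", "F1"])
            for cid, m in sorted(self.per_class.items()):
                wr.writerow([cid, m["P"], m["R"], m["AP50"], m["F1"]])
            wr.writerow(["mean", self.precision, self.recall, self.map50,
                         self.f1])


def match_detections(dets, gts, iou_threshold: float = 0.5) -> MatchResult:
    """Greedy per-class matching by descending score: a detection is a true
    positive iff its best-IoU unmatched same-class ground truth reaches the
    threshold; each ground truth is matched at most once."""
    res = MatchResult()
    classes = {d.class_id for d in dets} | {int(g[0]) for g in gts}
    for cid in sorted(classes):
        ds = sorted([d for d in dets if d.class_id == cid],
                    key=lambda d: (-d.score, d.box))
        gs = [g[1] for g in gts if int(g[0]) == cid]
        used = [False] * len(gs)
        flags = []
        tp = 0
        for d in ds:
            best_iou, best_j = 0.0, -1
            for j, gb in enumerate(gs):
                if used[j]:
                    continue
                i = box_iou(d.box, gb)
                if i > best_iou:
                    best_iou, best_j = i, j
            hit = best_iou >= iou_threshold and best_j >= 0
            if hit:
                used[best_j] = True
                tp += 1
            flags.append((d.score, hit))
        res.per_class[cid] = dict(tp=tp, fp=len(ds) - tp,
                                  fn=len(gs) - tp, flags=flags,
                                  n_gt=len(gs))
    return res


def precision_recall(m: MatchResult):
    """Micro-averaged P = TP/(TP+FP), R = TP/(TP+FN); 0/0 -> 0."""
    tp, fp, fn = m.counts()
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    return p, r


def average_precision(flags, n_gt: int) -> float:
    """All-point interpolated AP: area under the precision envelope over
    recall, from a score-ranked TP/FP flag sequence."""
    if n_gt < 0:
        raise ValueError("n_gt must be >= 0")
    if n_gt == 0 or not flags:
        return 0.0
    ordered = sorted(flags, key=lambda f: -f[0]) \
        if flags and isinstance(flags[0], tuple) else list(flags)
    hits = [(f[1] if isinstance(f, tuple) else bool(f)) for f in ordered]
    tp = np.cumsum(hits)
    fp = np.cumsum([not h for h in hits])
    recall = tp / n_gt
    prec = tp / np.maximum(tp + fp, 1)
    # precision envelope, integrated at recall steps
    r = np.concatenate([[0.0], recall, [recall[-1]]])
    p = np.concatenate([[1.0], prec, [0.0]])
    for i in range(len(p) - 2, -1, -1):
        p[i] = max(p[i], p[i + 1])
    ap = 0.0
    for i in range(1, len(r)):
        ap += (r[i] - r[i - 1]) * p[i]
    return float(ap)


def map50(per_class_ap) -> float:
    """Unweighted mean over classes of AP at IoU 0.5."""
    vals = list(per_class_ap.values()) if isinstance(per_class_ap, dict) \
        else list(per_class_ap)
    return float(np.mean(vals)) if vals else 0.0


def f1_score(p: float, r: float) -> float:
    return 2 * p * r / (p + r) if p + r > 0 else 0.0


def measure_fps(pre_ms: float, infer_ms: float, post_ms: float) -> float:
    """Frames per second at batch size 1: 1000 ms over the summed
    preprocessing, inference and postprocessing times."""
    if min(pre_ms, infer_ms, post_ms) <= 0:
        raise ValueError("stage times must be positive")
    return 1000.0 / (pre_ms + infer_ms + post_ms)


def evaluate(model: DetectionModel, dataset, img_size: int = None,
             conf_threshold: float = 0.25, nms_iou: float = 0.45,
             match_iou: float = 0.5) -> MetricsReport:
    """Run detection over a dataset and compute P/R/AP@.5/F1 per class
    and their means."""
    model.eval()
    merged = MatchResult()
    for img, lab in dataset:
        size = img.shape[-1] if img_size is None else img_size
        raw = model(Tensor(img[None]))
        dets = decode_boxes([r.numpy() for r in raw],
                            reg_max=model.cfg.reg_max,
                            conf_threshold=conf_threshold, image_size=size)
        dets = nms(dets, nms_iou)
        gts = []
        for cls, cx, cy, w, h in lab:
            gts.append((int(cls), ((cx - w / 2) * size, (cy - h / 2) * size,
                                   (cx + w / 2) * size, (cy + h / 2) * size)))
        merged.merge(match_detections(dets, gts, match_iou))
    per_class = {}
    aps = {}
    for cid, c in merged.per_class.items():
        p = c["tp"] / (c["tp"] + c["fp"]) if c["tp"] + c["fp"] else 0.0
        r = c["tp"] / (c["tp"] + c["fn"]) if c["tp"] + c["fn"] else 0.0
        ap = average_precision(c["flags"], c["n_gt"])
        per_class[cid] = dict(P=p, R=r, AP50=ap, F1=f1_score(p, r))
        aps[cid] = ap
    mp, mr = precision_recall(merged)
    return MetricsReport(per_class=per_class, precision=mp, recall=mr,
                         map50=map50(aps), f1=f1_score(mp, mr))
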