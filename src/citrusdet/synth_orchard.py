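"""Synthetic citrus orchard scenes, augmentations and dataset plumbing.

Real orchard imagery for the three phenological classes (flower, green
fruit, orange fruit) is not redistributable, so training and evaluation run
on generated scenes that emulate its statistics: dense clusters, foliage
occlusion, lighting/gamma variation, near-square boxes whose centroids are
biased toward the image center.  Scenes are deterministic under their seed.

Also here: the photometric augmentations (gamma change, luminance
histogram equalization), mixup and mosaic with label bookkeeping, the
7:1:2 dataset split, YOLO-format txt label I/O, and paired tree-level
(visible count, true count) records for the yield regression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image, ImageDraw

__all__ = [
    "CLASSES", "SceneSpec", "LabeledImage", "TreeCountPair", "PackingError",
    "generate_scene", "photometric_augment", "mixup", "mosaic",
    "split_dataset", "write_yolo_labels", "read_yolo_labels",
    "generate_tree_views", "make_dataset", "MIN_VISIBLE_AREA",
]

CLASSES = ("flower", "green_fruit", "orange_fruit")
MIN_VISIBLE_AREA = 8  # px^2; smaller visible remnants get no label


class PackingError(RuntimeError):
    """Raised when the requested object count cannot be placed."""


@dataclass
class SceneSpec:
    width: int = 640
    height: int = 640
    counts: tuple = (4, 6, 6)           # per class: flower, green, orange
    cluster_rate: float = 2.5           # mean objects per cluster
    occlusion_fraction: float = 0.25    # max fraction of an object hidden
    lighting_gamma: float = 1.0
    backlight: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.width < 64 or self.height < 64:
            raise ValueError("canvas must be at least 64x64")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")
        if not 0.0 <= self.occlusion_fraction <= 1.0:
            raise ValueError("occlusion_fraction must lie in [0, 1]")
        if self.lighting_gamma <= 0:
            raise ValueError("lighting_gamma must be positive")


@dataclass
class LabeledImage:
    image: np.ndarray                   # (H, W, 3) uint8
    labels: list = field(default_factory=list)  # (class_id, cx, cy, w, h)

    def __post_init__(self):
        for lb in self.labels:
            if not all(0.0 <= v <= 1.0 for v in lb[1:]):
                raise ValueError(f"label out of [0,1] bounds: {lb}")


@dataclass(frozen=True)
class TreeCountPair:
    tree_id: int
    detect: int                         # visible count, unilateral view
    actual: int                         # true fruit count

    def __post_init__(self):
        if not 0 <= self.detect <= self.actual:
            raise ValueError("need 0 <= detect <= actual")


# ------------------------------------------------------------ scene rendering
def _background(w, h, rng: np.random.Generator) -> Image.Image:
    base = np.zeros((h, w, 3), np.uint8)
    base[..., 0] = 32
    base[..., 1] = 72
    base[..., 2] = 28
    img = Image.fromarray(base)
    draw = ImageDraw.Draw(img)
    for _ in range(int(w * h / 2200)):          # layered foliage blobs
        cx, cy = rng.uniform(0, w), rng.uniform(0, h)
        rx, ry = rng.uniform(8, 42), rng.uniform(8, 42)
        shade = rng.integers(-22, 32)
        col = (int(np.clip(30 + shade // 2, 0, 255)),
               int(np.clip(78 + shade, 0, 255)),
               int(np.clip(26 + shade // 3, 0, 255)))
        draw.ellipse([cx - rx, cy - ry, cx + rx, cy + ry], fill=col)
    return img


def _object_style(cls: int, rng) -> dict:
    if cls == 0:        # flower: white petal cluster, yellow center
        return dict(fill=(238, 240, int(rng.integers(218, 236))),
                    center=(246, 214, 90), petals=True)
    if cls == 1:        # green fruit: hue-offset bright green disc
        g = int(rng.integers(150, 185))
        return dict(fill=(96, g, 52), center=None, petals=False)
    g = int(rng.integers(120, 160))      # orange fruit with highlight
    return dict(fill=(235, g, 30), center=(255, 236, 200), petals=False)


def _draw_object(draw, idmask, oid, cls, cx, cy, rx, ry, rng):
    style = _object_style(cls, rng)
    box = [cx - rx, cy - ry, cx + rx, cy + ry]
    if style["petals"]:
        # five petal lobes around the center plus a core
        for k in range(5):
            ang = 2 * math.pi * k / 5 + rng.uniform(-0.2, 0.2)
            px = cx + 0.45 * rx * math.cos(ang)
            py = cy + 0.45 * ry * math.sin(ang)
            draw.ellipse([px - 0.55 * rx, py - 0.55 * ry,
                          px + 0.55 * rx, py + 0.55 * ry], fill=style["fill"])
        draw.ellipse([cx - 0.3 * rx, cy - 0.3 * ry, cx + 0.3 * rx,
                      cy + 0.3 * ry], fill=style["center"])
    else:
        draw.ellipse(box, fill=style["fill"])
        if style["center"] is not None:
            draw.ellipse([cx - 0.30 * rx, cy - 0.38 * ry,
                          cx + 0.02 * rx, cy - 0.05 * ry],
                         fill=style["center"])
    # rasterize the full extent into the instance mask
    h, w = idmask.shape
    yy, xx = np.mgrid[0:h, 0:w]
    ell = ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0
    idmask[ell] = oid


def _occlude(img_draw, idmask, oid, frac, rng):
    """Cover roughly `frac` of object `oid` with leaf polygons."""
    ys, xs = np.nonzero(idmask == oid)
    if len(xs) == 0 or frac <= 0:
        return
    area0 = len(xs)
    target = int(area0 * frac)
    covered = 0
    tries = 0
    while covered < target and tries < 8:
        tries += 1
        i = rng.integers(0, len(xs))
        lx, ly = float(xs[i]), float(ys[i])
        lr = math.sqrt(target / math.pi) * rng.uniform(0.9, 1.6)
        ang = rng.uniform(0, 2 * math.pi)
        pts = []
        for k in range(5):
            a = ang + 2 * math.pi * k / 5
            rr = lr * (1.25 if k % 2 else 0.7)
            pts.append((lx + rr * math.cos(a), ly + rr * math.sin(a)))
        shade = int(rng.integers(-18, 10))
        img_draw.polygon(pts, fill=(24 + shade // 2,
                                    np.clip(66 + shade, 0, 255), 22))
        small = Image.new("1", (idmask.shape[1], idmask.shape[0]), 0)
        ImageDraw.Draw(small).polygon(pts, fill=1)
        leaf = np.array(small, bool)
        hit = leaf & (idmask == oid)
        covered += int(hit.sum())
        idmask[hit] = 0


def generate_scene(spec: SceneSpec) -> LabeledImage:
    """Render one orchard scene; deterministic under ``spec.seed``.

    Objects are placed in clusters with center-biased cluster positions and
    near-square extents; leaf polygons hide up to ``occlusion_fraction`` of
    each object; every object whose visible area is at least
    ``MIN_VISIBLE_AREA`` px^2 gets exactly one label covering its visible
    extent.
    """
    rng = np.random.default_rng(spec.seed)
    w, h = spec.width, spec.height
    total = sum(spec.counts)
    # crude packing feasibility: mean object area ~ pi*(0.045*min(w,h))^2
    mean_area = math.pi * (0.045 * min(w, h)) ** 2
    if total * mean_area > 0.8 * w * h:
        raise PackingError(
            f"{total} objects cannot be packed into {w}x{h}")
    img = _background(w, h, rng)
    draw = ImageDraw.Draw(img)
    idmask = np.zeros((h, w), np.int32)
    order = []          # (oid, class)
    oid = 0
    for cls, count in enumerate(spec.counts):
        placed = 0
        while placed < count:
            k = min(count - placed,
                    1 + rng.poisson(max(spec.cluster_rate - 1.0, 0.0)))
            # center-biased cluster position
            ccx = np.clip(rng.normal(0.5, 0.16), 0.08, 0.92) * w
            ccy = np.clip(rng.normal(0.5, 0.16), 0.08, 0.92) * h
            for _ in range(k):
                r = rng.uniform(0.028, 0.062) * min(w, h)
                ar = math.exp(rng.uniform(math.log(0.8), math.log(1.25)))
                rx, ry = r * math.sqrt(ar), r / math.sqrt(ar)
                for _ in range(20):     # bounded placement retries
                    cx = ccx + rng.normal(0, 2.2 * r)
                    cy = ccy + rng.normal(0, 2.2 * r)
                    if rx < cx < w - rx and ry < cy < h - ry:
                        break
                else:
                    raise PackingError("could not place object in bounds")
                oid += 1
                _draw_object(draw, idmask, oid, cls, cx, cy, rx, ry, rng)
                order.append((oid, cls))
                placed += 1
    if spec.occlusion_fraction > 0:
        for o, _ in order:
            _occlude(draw, idmask, o, rng.uniform(0, spec.occlusion_fraction),
                     rng)
    out = np.array(img)
    if spec.backlight:
        ramp = np.linspace(0.55, 0.85, h, dtype=np.float32)[:, None, None]
        out = np.clip(out.astype(np.float32) * ramp + 12, 0, 255).astype(np.uint8)
    if spec.lighting_gamma != 1.0:
        out = photometric_augment(out, "gamma", spec.lighting_gamma)
    labels = []
    for o, cls in order:
        ys, xs = np.nonzero(idmask == o)
        if len(xs) < MIN_VISIBLE_AREA:
            continue
        x1, x2 = xs.min(), xs.max() + 1
        y1, y2 = ys.min(), ys.max() + 1
        labels.append((cls, (x1 + x2) / 2 / w, (y1 + y2) / 2 / h,
                       (x2 - x1) / w, (y2 - y1) / h))
    return LabeledImage(out, labels)


# ------------------------------------------------------------- augmentations
def photometric_augment(img: np.ndarray, kind: str, param: float = 1.0
                        ) -> np.ndarray:
    """Gamma change (out = 255*(in/255)**gamma, rounded) or histogram
    equalization of the luminance channel with chroma preserved."""
    img = np.asarray(img, np.uint8)
    if kind == "gamma":
        if param <= 0:
            raise ValueError("gamma must be positive")
        lut = np.rint(255.0 * (np.arange(256) / 255.0) ** param
                      ).astype(np.uint8)
        return lut[img]
    if kind == "equalize":
        ycc = np.array(Image.fromarray(img).convert("YCbCr"))
        y = ycc[..., 0]
        hist = np.bincount(y.ravel(), minlength=256)
        nz = np.nonzero(hist)[0]
        if len(nz) <= 1:        # degenerate histogram: no-op
            return img.copy()
        cdf = hist.cumsum()
        cdf_min = cdf[nz[0]]
        lut = np.rint((cdf - cdf_min) / (cdf[-1] - cdf_min) * 255.0)
        ycc[..., 0] = np.clip(lut, 0, 255).astype(np.uint8)[y]
        return np.array(Image.fromarray(ycc, "YCbCr").convert("RGB"))
    raise ValueError(f"unknown augmentation kind {kind!r}")


def mixup(a: LabeledImage, b: LabeledImage, lam: float) -> LabeledImage:
    """Pixel blend lam*a + (1-lam)*b; label lists are concatenated."""
    if a.image.shape != b.image.shape:
        raise ValueError("mixup requires equally sized images")
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lam must lie in [0, 1]")
    px = np.rint(lam * a.image.astype(np.float64)
                 + (1.0 - lam) * b.image.astype(np.float64)).astype(np.uint8)
    return LabeledImage(px, list(a.labels) + list(b.labels))


def mosaic(quad, canvas_size: int = 640, seed: int = 0) -> LabeledImage:
    """Four images scaled into the quadrants around a random junction point
    in the central half of the canvas; labels are shifted, clipped and
    dropped when their visible area falls below MIN_VISIBLE_AREA."""
    if len(quad) != 4:
        raise ValueError("mosaic needs exactly four images")
    rng = np.random.default_rng(seed)
    s = canvas_size
    jx = int(rng.uniform(0.25, 0.75) * s)
    jy = int(rng.uniform(0.25, 0.75) * s)
    rects = [(0, 0, jx, jy), (jx, 0, s - jx, jy),
             (0, jy, jx, s - jy), (jx, jy, s - jx, s - jy)]
    canvas = np.zeros((s, s, 3), np.uint8)
    labels = []
    for li, (x0, y0, qw, qh) in zip(quad, rects):
        if qw == 0 or qh == 0:
            continue
        ih, iw = li.image.shape[:2]
        resized = np.array(Image.fromarray(li.image).resize(
            (qw, qh), Image.BILINEAR)) if (iw, ih) != (qw, qh) else li.image
        canvas[y0:y0 + qh, x0:x0 + qw] = resized
        for cls, cx, cy, bw, bh in li.labels:
            x1 = x0 + (cx - bw / 2) * qw
            y1 = y0 + (cy - bh / 2) * qh
            x2 = x0 + (cx + bw / 2) * qw
            y2 = y0 + (cy + bh / 2) * qh
            x1, x2 = np.clip([x1, x2], x0, x0 + qw)
            y1, y2 = np.clip([y1, y2], y0, y0 + qh)
            if (x2 - x1) * (y2 - y1) < MIN_VISIBLE_AREA:
                continue
            labels.append((cls, (x1 + x2) / 2 / s, (y1 + y2) / 2 / s,
                           (x2 - x1) / s, (y2 - y1) / s))
    return LabeledImage(canvas, labels)


# ------------------------------------------------------------------ splitting
def split_dataset(item_ids, ratios=(0.7, 0.1, 0.2), seed: int = 0):
    """Seeded shuffle + largest-remainder apportionment into
    (train, val, test); partitions are disjoint and exhaustive."""
    items = list(item_ids)
    if not items:
        raise ValueError("cannot split an empty dataset")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(items))
    n = len(items)
    exact = [r * n for r in ratios]
    sizes = [int(e) for e in exact]
    rem = n - sum(sizes)
    order = sorted(range(len(ratios)), key=lambda i: exact[i] - sizes[i],
                   reverse=True)
    for i in order[:rem]:
        sizes[i] += 1
    out, pos = [], 0
    for sz in sizes:
        out.append([items[j] for j in perm[pos:pos + sz]])
        pos += sz
    return tuple(out)


# ------------------------------------------------------------------ label I/O
def write_yolo_labels(labels, path):
    """One `class cx cy w h` line per object, 6-decimal fixed format."""
    labels = labels.labels if isinstance(labels, LabeledImage) else labels
    with open(path, "w") as fh:
        for cls, cx, cy, w, h in labels:
            fh.write(f"{int(cls)} {cx:.6f} {cy:.6f} {w:.6f} {h:.6f}\n")


def read_yolo_labels(path):
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 fields, "
                                 f"got {len(parts)}")
            try:
                cls = int(parts[0])
                vals = [float(v) for v in parts[1:]]
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: {e}") from None
            out.append((cls, *vals))
    return out


# ------------------------------------------------------------- tree-level data
def generate_tree_views(n_trees: int = 10, alpha: float = 1.44,
                        beta: float = 1.0, sigma: float = 5.0,
                        visibility: float = None, seed: int = 0,
                        actual_range=(50, 140)):
    """Paired (visible count, true count) records for `n_trees` trees.

    The true counts are uniform over `actual_range`; the unilateral visible
    count is the fraction of fruit seen from one side plus counting noise:
    detect = round(visibility*actual + N(0, sigma)), clipped to [0, actual].
    When `visibility` is omitted it is derived from the linear model
    actual = alpha*detect + beta, i.e. detect = (actual - beta)/alpha, so a
    downstream linear fit recovers (alpha, beta) in expectation.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if visibility is not None and not 0.0 < visibility <= 1.0:
        raise ValueError("visibility must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    lo, hi = actual_range
    out = []
    for t in range(n_trees):
        actual = int(rng.integers(lo, hi + 1))
        if visibility is not None:
            mean = visibility * actual
        else:
            mean = (actual - beta) / alpha
        detect = int(round(mean + (rng.normal(0.0, sigma) if sigma > 0 else 0.0)))
        detect = int(np.clip(detect, 0, actual))
        out.append(TreeCountPair(t + 1, detect, actual))
    return out


# ------------------------------------------------------------ dataset on disk
def make_dataset(out_dir, n_images: int, size: int = 640, seed: int = 0,
                 counts_range=((2, 6), (3, 9), (3, 9)),
                 occlusion: float = 0.25, ratios=(0.7, 0.1, 0.2)):
    """Write a complete split dataset (PNG images, YOLO txt labels, YAML
    manifest) under `out_dir`; returns the manifest dict."""
    out = Path(out_dir)
    rng = np.random.default_rng(seed)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "labels").mkdir(parents=True, exist_ok=True)
    ids = []
    for i in range(n_images):
        spec = SceneSpec(
            width=size, height=size,
            counts=tuple(int(rng.integers(lo, hi + 1))
                         for lo, hi in counts_range),
            occlusion_fraction=occlusion,
            lighting_gamma=float(np.exp(rng.uniform(np.log(0.7), np.log(1.4)))),
            backlight=bool(rng.random() < 0.15),
            seed=int(rng.integers(0, 2**31 - 1)))
        scene = generate_scene(spec)
        stem = f"scene_{i:05d}"
        Image.fromarray(scene.image).save(out / "images" / f"{stem}.png")
        write_yolo_labels(scene, out / "labels" / f"{stem}.txt")
        ids.append(stem)
    train, val, test = split_dataset(ids, ratios=ratios, seed=seed)
    manifest = dict(classes=list(CLASSES), size=size, seed=seed,
                    splits=dict(train=train, val=val, test=test))
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh)
    return manifest
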