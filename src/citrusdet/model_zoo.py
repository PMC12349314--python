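"""Assembly of the four detector variants and parameter/FLOP accounting.

Variants (nano scale, strides 8/16/32):

* ``yolov8n``        -- stock baseline: C2f backbone/neck + decoupled head.
* ``rgcspelan_only`` -- every C2f replaced by RGCSPELAN, baseline head kept.
* ``lscd_only``      -- C2f kept, head swapped for the shared LSCD head.
* ``yolov8_rl``      -- both replacements (the lightweight full model).

The RGCSPELAN extraction widths and the LSCD trunk widths are calibrated
and shipped in ``configs/manifest.yaml``; they are the canonical widths of
this implementation and give the reference parameter accounting
(3,157,200 / 2,197,561 / 2,362,518 / 1,553,846 at an 80-class head).

FLOPs are counted for convolution layers only (normalization/activation
excluded), one multiply-accumulate = 2 FLOPs, RepConv in its fused
deploy form.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from .autodiff import Tensor, concat
from .lscd_head import BaselineDetect, LSCDHead
from .nn_blocks import C2f, ConvBNSiLU, Module, RGCSPELAN, SPPF

__all__ = ["ModelConfig", "SummaryReport", "DetectionModel", "VARIANTS",
           "build_model", "count_parameters", "count_flops", "summarize",
           "save_checkpoint", "load_checkpoint", "load_manifest"]

VARIANTS = ("yolov8n", "rgcspelan_only", "lscd_only", "yolov8_rl")

# (c1, c2, n) of the eight aggregation sites: four backbone, four neck
_SITES = ((32, 32, 1), (64, 64, 2), (128, 128, 2), (256, 256, 1),
          (384, 128, 1), (192, 64, 1), (192, 128, 1), (384, 256, 1))


def load_manifest() -> dict:
    """The calibrated channel manifest shipped with the package."""
    text = resources.files("citrusdet").joinpath(
        "configs/manifest.yaml").read_text()
    return yaml.safe_load(text)


@dataclass
class ModelConfig:
    variant: str = "yolov8_rl"
    num_classes: int = 80
    reg_max: int = 16
    input_size: int = 640
    seed: int = 0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(
                f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if self.num_classes < 1:
            raise ValueError("num_classes must be >= 1")
        if self.reg_max < 1:
            raise ValueError("reg_max must be >= 1")
        if self.input_size % 32:
            raise ValueError("input_size must be divisible by 32")


@dataclass
class SummaryReport:
    parameters: int
    gflops: float
    size_bytes: int


class DetectionModel(Module):
    """An assembled variant with named P3/P4/P5 taps and a forward contract:
    on (1, 3, S, S) input the taps have spatial sizes S/8, S/16, S/32."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        manifest = load_manifest()
        rng = np.random.default_rng(cfg.seed)
        use_rg = cfg.variant in ("rgcspelan_only", "yolov8_rl")
        use_lscd = cfg.variant in ("lscd_only", "yolov8_rl")

        def agg(i):
            c1, c2, n = _SITES[i]
            if use_rg:
                m = manifest["rgcspelan_m"][cfg.variant][i]
                return RGCSPELAN(c1, c2, n=n, m=m, rng=rng)
            return C2f(c1, c2, n=n, shortcut=i < 4, rng=rng)

        self.stem0 = ConvBNSiLU(3, 16, 3, 2, rng=rng)
        self.stem1 = ConvBNSiLU(16, 32, 3, 2, rng=rng)
        self.b2 = agg(0)
        self.down3 = ConvBNSiLU(32, 64, 3, 2, rng=rng)
        self.b4 = agg(1)
        self.down5 = ConvBNSiLU(64, 128, 3, 2, rng=rng)
        self.b6 = agg(2)
        self.down7 = ConvBNSiLU(128, 256, 3, 2, rng=rng)
        self.b8 = agg(3)
        self.sppf = SPPF(256, 256, rng=rng)
        self.n12 = agg(4)
        self.n15 = agg(5)
        self.pan16 = ConvBNSiLU(64, 64, 3, 2, rng=rng)
        self.n18 = agg(6)
        self.pan19 = ConvBNSiLU(128, 128, 3, 2, rng=rng)
        self.n21 = agg(7)
        ch = (64, 128, 256)
        if use_lscd:
            self.head = LSCDHead(cfg.num_classes, ch,
                                 widths=tuple(manifest["lscd_widths"]),
                                 reg_max=cfg.reg_max, rng=rng)
        else:
            self.head = BaselineDetect(cfg.num_classes, ch,
                                       reg_max=cfg.reg_max, rng=rng)

    def features(self, x: Tensor):
        """Backbone + neck; returns the P3/P4/P5 taps (strides 8/16/32)."""
        x = self.stem1(self.stem0(x))
        x = self.b2(x)
        x = self.b4(self.down3(x))
        p3_src = x                                  # stride 8
        x = self.b6(self.down5(x))
        p4_src = x                                  # stride 16
        x = self.sppf(self.b8(self.down7(x)))       # stride 32
        p5_src = x
        y = self.n12(concat([p5_src.upsample2x(), p4_src], axis=1))
        p3 = self.n15(concat([y.upsample2x(), p3_src], axis=1))
        p4 = self.n18(concat([self.pan16(p3), y], axis=1))
        p5 = self.n21(concat([self.pan19(p4), p5_src], axis=1))
        return p3, p4, p5

    def forward(self, x: Tensor):
        return self.head(list(self.features(x)))


def build_model(cfg: ModelConfig) -> DetectionModel:
    return DetectionModel(cfg)


def count_parameters(m: DetectionModel) -> int:
    """Exact parameter total (conv kernels + biases + affine norm parameters
    + the frozen DFL projection; running statistics excluded)."""
    return m.num_params()


# ----------------------------------------------------------------- FLOPs walk
def _cf(c1, c2, k, cells):
    return 2 * c1 * c2 * k * k * cells


def _block_flops(block, cells) -> int:
    if isinstance(block, ConvBNSiLU):
        return _cf(block.c1, block.c2, block.k, cells // (block.s * block.s))
    if isinstance(block, C2f):
        c = block.c
        f = _cf(block.cv1.c1, 2 * c, 1, cells)
        for bt in block.m:
            f += _cf(bt.cv1.c1, bt.cv1.c2, 3, cells)
            f += _cf(bt.cv2.c1, bt.cv2.c2, 3, cells)
        return f + _cf(block.cv2.c1, block.cv2.c2, 1, cells)
    if isinstance(block, RGCSPELAN):
        c, m, n = block.c, block.m_width, block.n
        f = _cf(block.stem.c1, 2 * c, 1, cells)
        f += _cf(c, m, 3, cells)                    # first RepConv, fused
        f += (n - 1) * _cf(m, m, 3, cells)
        f += _cf(m, m, 3, cells)                    # tail
        return f + _cf(c + (n + 1) * m, block.proj.c2, 1, cells)
    if isinstance(block, SPPF):
        c_ = block.cv1.c2
        return _cf(block.cv1.c1, c_, 1, cells) + _cf(4 * c_, block.cv2.c2, 1, cells)
    raise TypeError(type(block))


def count_flops(m: DetectionModel, input_hw: int = 640) -> float:
    """Total conv FLOPs (MAC x 2) at the given square input size, in GFLOPs."""
    if input_hw % 32:
        raise ValueError("input_hw must be divisible by 32")
    g = {s: (input_hw // s) ** 2 for s in (2, 4, 8, 16, 32)}
    f = _cf(3, 16, 3, g[2]) + _cf(16, 32, 3, g[4])
    f += _block_flops(m.b2, g[4])
    f += _cf(32, 64, 3, g[8]) + _block_flops(m.b4, g[8])
    f += _cf(64, 128, 3, g[16]) + _block_flops(m.b6, g[16])
    f += _cf(128, 256, 3, g[32]) + _block_flops(m.b8, g[32])
    f += _block_flops(m.sppf, g[32])
    f += _block_flops(m.n12, g[16]) + _block_flops(m.n15, g[8])
    f += _cf(64, 64, 3, g[16]) + _block_flops(m.n18, g[16])
    f += _cf(128, 128, 3, g[32]) + _block_flops(m.n21, g[32])
    head = m.head
    grids = (g[8], g[16], g[32])
    if isinstance(head, LSCDHead):
        h1, h2, h3 = head.widths
        for cells, c in zip(grids, head.ch):
            f += _cf(c, h1, 1, cells)
            f += _cf(h1, h2, 3, cells) + _cf(h2, h3, 3, cells)
            f += _cf(h3, 4 * head.reg_max, 1, cells) + _cf(h3, head.nc, 1, cells)
    else:
        c2 = max(16, head.ch[0] // 4, head.reg_max * 4)
        c3 = max(head.ch[0], min(head.nc, 100))
        for cells, c in zip(grids, head.ch):
            f += _cf(c, c2, 3, cells) + _cf(c2, c2, 3, cells)
            f += _cf(c2, 4 * head.reg_max, 1, cells)
            f += _cf(c, c3, 3, cells) + _cf(c3, c3, 3, cells)
            f += _cf(c3, head.nc, 1, cells)
    return f / 1e9


# ---------------------------------------------------------------- persistence
def save_checkpoint(m: DetectionModel, path, half: bool = False):
    """Serialize weights + config.  `half` stores float16 (deployment size);
    float32 round-trips bit-exactly."""
    sd = m.state_dict()
    if half:
        sd = {k: v.astype(np.float16) if v.dtype == np.float32 else v
              for k, v in sd.items()}
    meta = dict(variant=m.cfg.variant, num_classes=m.cfg.num_classes,
                reg_max=m.cfg.reg_max, input_size=m.cfg.input_size,
                seed=m.cfg.seed)
    np.savez(path, __meta__=np.frombuffer(
        yaml.safe_dump(meta).encode(), dtype=np.uint8), **sd)


def load_checkpoint(path) -> DetectionModel:
    with np.load(path) as z:
        meta = yaml.safe_load(bytes(z["__meta__"]).decode())
        sd = {k: z[k] for k in z.files if k != "__meta__"}
    m = build_model(ModelConfig(**meta))
    m.load_state_dict({k: v.astype(np.float32) if v.dtype == np.float16 else v
                       for k, v in sd.items()})
    return m


def summarize(m: DetectionModel, input_hw: int = 640) -> SummaryReport:
    """Parameters, GFLOPs at `input_hw`, and serialized half-precision size."""
    buf = io.BytesIO()
    save_checkpoint(m, buf, half=True)
    return SummaryReport(parameters=count_parameters(m),
                         gflops=count_flops(m, input_hw),
                         size_bytes=buf.getbuffer().nbytes)
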