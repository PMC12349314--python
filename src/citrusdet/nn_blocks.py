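"""Building blocks of the lightweight citrus detector.

The vocabulary follows the YOLO lineage the detector belongs to:

* ``ConvBNSiLU`` -- the standard conv unit (Conv2d + BatchNorm2d + SiLU),
  usually called CBS.
* ``RepConv`` -- structural re-parameterization: a 3x3 and a 1x1 branch
  (each conv + batch norm) summed during training, algebraically fused into
  one 3x3 convolution for deployment.
* ``RGCSPELAN`` -- an ELAN/CSP-style aggregation block that replaces C2f:
  a 1x1 stem, a channel split into a pass-through half and an extraction
  branch of ``n`` RepConv units at a reduced width, a 3x3 tail conv, ELAN
  concatenation of all intermediate outputs and a 1x1 projection.
* ``ConvGN`` -- conv + group normalization + SiLU, the unit of the shared
  detection head.
* ``Bottleneck`` / ``C2f`` / ``SPPF`` -- the stock blocks of the nano
  baseline, needed for ablation variants.
* ``Scale`` -- a learnable scalar, one per pyramid level in the shared head.

``block_param_count`` gives closed-form trainable-parameter arithmetic for
each block kind; it is the accounting primitive behind model summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Parameter, Tensor, concat

__all__ = [
    "Module", "ConvBNSiLU", "ConvGN", "RepConv", "RGCSPELAN", "Bottleneck",
    "C2f", "SPPF", "Scale", "GroupNormParams", "group_normalize",
    "scale_apply", "repconv_forward", "repconv_fuse", "rgcspelan_forward",
    "default_num_groups", "block_param_count",
]

BN_EPS = 1e-3
BN_MOMENTUM = 0.03
GN_EPS = 1e-5


def default_num_groups(channels: int, preferred: int = 16) -> int:
    """Largest divisor of `channels` not exceeding `preferred` (16 by default,
    reduced when the channel count is small or not divisible by 16)."""
    g = min(preferred, channels)
    while channels % g:
        g -= 1
    return g


# --------------------------------------------------------------------- module
class Module:
    """Tiny module container: tracks sub-modules/parameters by attribute."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kw):
        return self.forward(*args, **kw)

    def _children(self):
        for name, v in vars(self).items():
            if isinstance(v, Module):
                yield name, v
            elif isinstance(v, (list, tuple)):
                for i, m in enumerate(v):
                    if isinstance(m, Module):
                        yield f"{name}.{i}", m

    def named_parameters(self, prefix: str = ""):
        for name, v in vars(self).items():
            if isinstance(v, Parameter):
                yield prefix + name, v
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def num_params(self) -> int:
        """Parameter count as printed in model summaries (includes frozen
        constants such as the DFL projection; excludes running statistics)."""
        return int(sum(p.data.size for p in self.parameters()))

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self, prefix: str = ""):
        out = {}
        for name, p in self.named_parameters(prefix):
            out[name] = p.data
        for name, v in vars(self).items():
            if isinstance(v, np.ndarray):  # running stats buffers
                out[prefix + name] = v
        for name, child in self._children():
            out.update(child.state_dict(prefix + name + "."))
        return out

    def load_state_dict(self, sd: dict, prefix: str = ""):
        for name, p in list(vars(self).items()):
            key = prefix + name
            if isinstance(p, Parameter) and key in sd:
                p.data = np.asarray(sd[key], dtype=np.float32).reshape(p.shape)
            elif isinstance(p, np.ndarray) and key in sd:
                setattr(self, name, np.asarray(sd[key], dtype=p.dtype))
        for name, child in self._children():
            child.load_state_dict(sd, prefix + name + ".")


def _kaiming(rng: np.random.Generator, shape) -> np.ndarray:
    fan_in = int(np.prod(shape[1:]))
    std = np.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * std).astype(np.float32)


class _BatchNorm(Module):
    def __init__(self, c: int):
        super().__init__()
        self.gamma = Parameter(np.ones(c, np.float32))
        self.beta = Parameter(np.zeros(c, np.float32))
        self.running_mean = np.zeros(c, np.float32)
        self.running_var = np.ones(c, np.float32)

    def forward(self, x: Tensor) -> Tensor:
        return x.batch_norm(self.gamma, self.beta, self.running_mean,
                            self.running_var, self.training,
                            momentum=BN_MOMENTUM, eps=BN_EPS)


class ConvBNSiLU(Module):
    """Standard conv unit: k x k conv (no bias), batch norm, SiLU."""

    def __init__(self, c1: int, c2: int, k: int = 1, s: int = 1,
                 act: bool = True, rng: np.random.Generator = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        if k not in (1, 3, 5):
            raise ValueError(f"unsupported kernel {k}")
        self.c1, self.c2, self.k, self.s = c1, c2, k, s
        self.weight = Parameter(_kaiming(rng, (c2, c1, k, k)))
        self.bn = _BatchNorm(c2)
        self.act = act

    def forward(self, x: Tensor) -> Tensor:
        y = x.conv2d(self.weight, stride=self.s, padding=self.k // 2)
        y = self.bn(y)
        return y.silu() if self.act else y


class ConvGN(Module):
    """Conv (no bias) + group normalization + SiLU: the Conv_GN unit of the
    shared detection head.  Group count defaults to 16, reduced to the largest
    divisor of the channel count."""

    def __init__(self, c1: int, c2: int, k: int = 1, s: int = 1,
                 rng: np.random.Generator = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.c1, self.c2, self.k, self.s = c1, c2, k, s
        self.weight = Parameter(_kaiming(rng, (c2, c1, k, k)))
        self.gamma = Parameter(np.ones(c2, np.float32))
        self.beta = Parameter(np.zeros(c2, np.float32))
        self.groups = default_num_groups(c2)

    def forward(self, x: Tensor) -> Tensor:
        y = x.conv2d(self.weight, stride=self.s, padding=self.k // 2)
        y = y.group_norm(self.gamma, self.beta, self.groups, eps=GN_EPS)
        return y.silu()


class RepConv(Module):
    """Re-parameterizable convolution: parallel 3x3 and 1x1 branches (each
    conv + batch norm) summed in training; a single fused 3x3 conv with bias
    in deploy mode.  No identity branch."""

    def __init__(self, c1: int, c2: int, rng: np.random.Generator = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.c1, self.c2 = c1, c2
        self.w3 = Parameter(_kaiming(rng, (c2, c1, 3, 3)))
        self.bn3 = _BatchNorm(c2)
        self.w1 = Parameter(_kaiming(rng, (c2, c1, 1, 1)))
        self.bn1 = _BatchNorm(c2)
        self.fused_w: np.ndarray | None = None
        self.fused_b: np.ndarray | None = None
        self.deploy = False

    def forward(self, x: Tensor) -> Tensor:
        if self.deploy:
            if self.fused_w is None:
                raise RuntimeError("RepConv in deploy mode without fusion")
            y = x.conv2d(Tensor(self.fused_w), Tensor(self.fused_b), padding=1)
            return y.silu()
        y = self.bn3(x.conv2d(self.w3, padding=1)) + \
            self.bn1(x.conv2d(self.w1, padding=0))
        return y.silu()

    @staticmethod
    def _fold(w: np.ndarray, bn: _BatchNorm, eps: float = BN_EPS):
        """Fold batch-norm statistics into the conv kernel and a bias."""
        sigma = np.sqrt(bn.running_var.astype(np.float64) + eps)
        scale = bn.gamma.data.astype(np.float64) / sigma
        wf = w.astype(np.float64) * scale[:, None, None, None]
        bf = bn.beta.data.astype(np.float64) - \
            bn.running_mean.astype(np.float64) * scale
        return wf, bf

    def fuse(self):
        """Fuse both branches into a single 3x3 kernel + bias.  Idempotent;
        only allowed in evaluation mode (running statistics are the fold
        source)."""
        if self.training:
            raise RuntimeError("RepConv fusion requires evaluation mode")
        w3, b3 = self._fold(self.w3.data, self.bn3)
        w1, b1 = self._fold(self.w1.data, self.bn1)
        w1p = np.zeros_like(w3)
        w1p[:, :, 1:2, 1:2] = w1
        self.fused_w = (w3 + w1p).astype(np.float32)
        self.fused_b = (b3 + b1).astype(np.float32)
        self.deploy = True
        return self


class Bottleneck(Module):
    def __init__(self, c1, c2, shortcut=True, e=0.5, rng=None):
        super().__init__()
        c_ = int(c2 * e)
        self.cv1 = ConvBNSiLU(c1, c_, 3, rng=rng)
        self.cv2 = ConvBNSiLU(c_, c2, 3, rng=rng)
        self.add = shortcut and c1 == c2

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class C2f(Module):
    """Stock cross-stage block of the nano baseline."""

    def __init__(self, c1, c2, n=1, shortcut=False, e=0.5, rng=None):
        super().__init__()
        self.c = int(c2 * e)
        self.cv1 = ConvBNSiLU(c1, 2 * self.c, 1, rng=rng)
        self.cv2 = ConvBNSiLU((2 + n) * self.c, c2, 1, rng=rng)
        self.m = [Bottleneck(self.c, self.c, shortcut, e=1.0, rng=rng)
                  for _ in range(n)]

    def forward(self, x):
        y = self.cv1(x)
        c = self.c
        ys = [y[:, 0:c], y[:, c:2 * c]]
        for m in self.m:
            ys.append(m(ys[-1]))
        return self.cv2(concat(ys, axis=1))


class SPPF(Module):
    def __init__(self, c1, c2, k=5, rng=None):
        super().__init__()
        c_ = c1 // 2
        self.cv1 = ConvBNSiLU(c1, c_, 1, rng=rng)
        self.cv2 = ConvBNSiLU(c_ * 4, c2, 1, rng=rng)
        self.k = k

    def forward(self, x):
        y = [self.cv1(x)]
        for _ in range(3):
            y.append(y[-1].maxpool2d(self.k, 1, self.k // 2))
        return self.cv2(concat(y, axis=1))


class RGCSPELAN(Module):
    """ELAN-style aggregation block built on RepConv.

    ``cfg``: input width c1, output width c2, n RepConv units, hidden width
    c (the split half, c2//2 by default) and extraction width m.  The stem is
    a 1x1 conv to 2c, split into a pass-through half and a branch half; the
    branch passes through n RepConv units at width m, then a 3x3 tail conv;
    pass-through, every RepConv output and the tail output are concatenated
    and projected back to c2 by a 1x1 conv.
    """

    def __init__(self, c1: int, c2: int, n: int = 1, m: int = None,
                 e: float = 0.5, s: float = 0.5, rng=None):
        super().__init__()
        if n < 1:
            raise ValueError("RGCSPELAN needs n >= 1")
        c = int(c2 * e)
        if m is None:
            m = int(c * s)
        if c < 1 or m < 1:
            raise ValueError("RGCSPELAN derived widths must be >= 1")
        self.c, self.m_width, self.n = c, m, n
        self.stem = ConvBNSiLU(c1, 2 * c, 1, rng=rng)
        self.reps = [RepConv(c if i == 0 else m, m, rng=rng) for i in range(n)]
        self.tail = ConvBNSiLU(m, m, 3, rng=rng)
        self.proj = ConvBNSiLU(c + (n + 1) * m, c2, 1, rng=rng)

    def forward(self, x):
        y = self.stem(x)
        c = self.c
        ys = [y[:, 0:c]]
        b = y[:, c:2 * c]
        for rep in self.reps:
            b = rep(b)
            ys.append(b)
        ys.append(self.tail(b))
        return self.proj(concat(ys, axis=1))


class Scale(Module):
    """Learnable scalar multiplier (one per pyramid level in the head)."""

    def __init__(self, init: float = 1.0):
        super().__init__()
        self.s = Parameter(np.array([init], np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return x * self.s


# ----------------------------------------------------- functional spec surface
@dataclass
class GroupNormParams:
    num_groups: int
    gamma: np.ndarray
    beta: np.ndarray
    eps: float = GN_EPS

    def __post_init__(self):
        # eps = 0 is tolerated for exact hand checks on non-degenerate inputs
        if self.eps < 0:
            raise ValueError("eps must be non-negative")


def group_normalize(x: np.ndarray, p: GroupNormParams) -> np.ndarray:
    """Group normalization of a (N, C, H, W) activation map:
    gamma * (x - mu_g) / sqrt(sigma_g^2 + eps) + beta, with mu_g/sigma_g^2
    the per-sample within-group mean and variance."""
    x = np.asarray(x, dtype=np.float64)
    n, c, h, w = x.shape
    if c % p.num_groups:
        raise ValueError(
            f"{c} channels not divisible by {p.num_groups} groups")
    t = Tensor(x).group_norm(Parameter(p.gamma), Parameter(p.beta),
                             p.num_groups, eps=p.eps)
    return t.numpy()


def scale_apply(x: np.ndarray, s: float) -> np.ndarray:
    """Elementwise per-level scaling."""
    return np.asarray(x) * s


def repconv_forward(x: np.ndarray, rep: RepConv, mode: str = "train") -> np.ndarray:
    """Run a RepConv in `train` (dual-branch sum) or `deploy` (fused) mode."""
    if mode not in ("train", "deploy"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "deploy" and rep.fused_w is None:
        raise RuntimeError("deploy mode requires fusion first")
    saved = rep.deploy
    rep.deploy = mode == "deploy"
    try:
        return rep(Tensor(np.asarray(x, np.float32))).numpy()
    finally:
        rep.deploy = saved


def repconv_fuse(rep: RepConv) -> RepConv:
    """Fuse both RepConv branches into one 3x3 kernel + bias (idempotent)."""
    return rep.fuse()


def rgcspelan_forward(x: np.ndarray, block: RGCSPELAN) -> np.ndarray:
    """Forward an activation map through an RGCSPELAN block."""
    x = np.asarray(x, np.float32)
    if x.shape[1] != block.stem.c1:
        raise ValueError(
            f"input has {x.shape[1]} channels, block expects {block.stem.c1}")
    return block(Tensor(x)).numpy()


# ------------------------------------------------------------------ accounting
def block_param_count(kind: str, **p) -> int:
    """Closed-form trainable-parameter arithmetic per block kind.

    Counts conv kernels (+ biases where present) and affine norm parameters;
    running statistics are excluded.  Independent of spatial input size.
    """
    kind = kind.lower()
    if kind == "cbs":
        c1, c2, k = p["c1"], p["c2"], p.get("k", 3)
        return c1 * c2 * k * k + 2 * c2
    if kind == "conv_gn":
        c1, c2, k = p["c1"], p["c2"], p.get("k", 1)
        return c1 * c2 * k * k + 2 * c2
    if kind == "repconv":
        c1, c2 = p["c1"], p["c2"]
        return (9 * c1 * c2 + 2 * c2) + (c1 * c2 + 2 * c2)
    if kind == "rgcspelan":
        c1, c2, n, m = p["c1"], p["c2"], p.get("n", 1), p["m"]
        c = p.get("c", c2 // 2)
        t = block_param_count("cbs", c1=c1, c2=2 * c, k=1)
        t += block_param_count("repconv", c1=c, c2=m)
        t += (n - 1) * block_param_count("repconv", c1=m, c2=m)
        t += block_param_count("cbs", c1=m, c2=m, k=3)
        t += block_param_count("cbs", c1=c + (n + 1) * m, c2=c2, k=1)
        return t
    if kind == "c2f":
        c1, c2, n = p["c1"], p["c2"], p.get("n", 1)
        c = int(c2 * p.get("e", 0.5))
        t = block_param_count("cbs", c1=c1, c2=2 * c, k=1)
        t += block_param_count("cbs", c1=(2 + n) * c, c2=c2, k=1)
        t += n * (block_param_count("cbs", c1=c, c2=c, k=3) * 2)
        return t
    if kind == "sppf":
        c1, c2 = p["c1"], p["c2"]
        c_ = c1 // 2
        return block_param_count("cbs", c1=c1, c2=c_, k=1) + \
            block_param_count("cbs", c1=4 * c_, c2=c2, k=1)
    raise ValueError(f"unknown block kind: {kind!r}")
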