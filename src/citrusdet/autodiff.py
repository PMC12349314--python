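"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is the numerical substrate for the detection networks in this package:
a tape-based ``Tensor`` with exactly the operations a small convolutional
detector needs (convolution via im2col + BLAS matmul, pooling, nearest
upsampling, batch/group normalization, the usual elementwise algebra and
reductions).  Arrays are float32 throughout; gradients are accumulated in
float32 as well.

The engine is deliberately small and single-threaded-deterministic: given
identical inputs and parameters, forward and backward are bit-reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "concat", "maximum", "minimum", "stack"]


def _as_f32(x) -> np.ndarray:
    a = np.asarray(x, dtype=np.float32)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # defer numpy binary ops to the Tensor reflected operators
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_f32(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    @staticmethod
    def _wrap(other):
        return other if isinstance(other, Tensor) else Tensor(other)

    @classmethod
    def _make(cls, data, parents, backward):
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        else:
            grad = _as_f32(grad)
        # reachable subgraph + consumer counts, then Kahn-style traversal so
        # every node's gradient is complete before it propagates further
        nodes = {id(self): self}
        pending = {id(self): 0}
        stack = [self]
        while stack:
            node = stack.pop()
            for p in node._parents:
                if not p.requires_grad:
                    continue
                key = id(p)
                if key not in nodes:
                    nodes[key] = p
                    pending[key] = 0
                    stack.append(p)
                pending[key] += 1
        grads = {id(self): grad}
        queue = [self]
        while queue:
            node = queue.pop()
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if pg is None or not parent.requires_grad:
                    continue
                key = id(parent)
                grads[key] = pg if key not in grads else grads[key] + pg
                pending[key] -= 1
                if pending[key] == 0:
                    queue.append(parent)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        o = self._wrap(other)
        return Tensor._make(
            self.data + o.data, (self, o),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, o.shape)))

    __radd__ = __add__

    def __sub__(self, other):
        o = self._wrap(other)
        return Tensor._make(
            self.data - o.data, (self, o),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(-g, o.shape)))

    def __rsub__(self, other):
        return self._wrap(other) - self

    def __mul__(self, other):
        o = self._wrap(other)
        return Tensor._make(
            self.data * o.data, (self, o),
            lambda g: (_unbroadcast(g * o.data, self.shape),
                       _unbroadcast(g * self.data, o.shape)))

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = self._wrap(other)
        return Tensor._make(
            self.data / o.data, (self, o),
            lambda g: (_unbroadcast(g / o.data, self.shape),
                       _unbroadcast(-g * self.data / (o.data * o.data), o.shape)))

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __pow__(self, p: float):
        out = self.data ** p
        return Tensor._make(
            out, (self,), lambda g: (g * p * self.data ** (p - 1),))

    # ------------------------------------------------------------ elementwise
    def exp(self):
        out = np.exp(self.data)
        return Tensor._make(out, (self,), lambda g: (g * out,))

    def log(self):
        return Tensor._make(np.log(self.data), (self,),
                            lambda g: (g / self.data,))

    def sqrt(self):
        out = np.sqrt(self.data)
        return Tensor._make(out, (self,), lambda g: (g / (2.0 * out),))

    def atan(self):
        return Tensor._make(np.arctan(self.data), (self,),
                            lambda g: (g / (1.0 + self.data * self.data),))

    def sigmoid(self):
        out = np.exp(-np.logaddexp(0.0, -self.data)).astype(np.float32)
        return Tensor._make(out, (self,), lambda g: (g * out * (1.0 - out),))

    def silu(self):
        s = np.exp(-np.logaddexp(0.0, -self.data)).astype(np.float32)
        out = self.data * s
        return Tensor._make(out, (self,),
                            lambda g: (g * (s + out * (1.0 - s)),))

    def clip(self, lo, hi):
        out = np.clip(self.data, lo, hi)
        mask = ((self.data >= lo) & (self.data <= hi)).astype(np.float32)
        return Tensor._make(out, (self,), lambda g: (g * mask,))

    def relu(self):
        mask = (self.data > 0).astype(np.float32)
        return Tensor._make(self.data * mask, (self,), lambda g: (g * mask,))

    # -------------------------------------------------------------- reshaping
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        return Tensor._make(self.data.reshape(shape), (self,),
                            lambda g: (g.reshape(old),))

    def transpose(self, *axes):
        inv = np.argsort(axes)
        return Tensor._make(np.transpose(self.data, axes), (self,),
                            lambda g: (np.transpose(g, inv),))

    def __getitem__(self, idx):
        def back(g):
            out = np.zeros_like(self.data)
            np.add.at(out, idx, g)
            return (out,)
        return Tensor._make(self.data[idx], (self,), back)

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def back(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).astype(np.float32),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g2, self.shape).astype(np.float32),)
        return Tensor._make(out, (self,), back)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # --------------------------------------------------------------- softmax
    def log_softmax(self, axis=-1):
        m = self.data.max(axis=axis, keepdims=True)
        z = self.data - m
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        out = z - lse
        sm = np.exp(out)
        return Tensor._make(
            out, (self,),
            lambda g: (g - sm * g.sum(axis=axis, keepdims=True),))

    def softmax(self, axis=-1):
        m = self.data.max(axis=axis, keepdims=True)
        e = np.exp(self.data - m)
        out = e / e.sum(axis=axis, keepdims=True)

        def back(g):
            dot = (g * out).sum(axis=axis, keepdims=True)
            return (out * (g - dot),)
        return Tensor._make(out, (self,), back)

    # ------------------------------------------------------------ convolution
    def conv2d(self, w: "Tensor", b: "Tensor" = None, stride: int = 1,
               padding: int = 0):
        """2-D cross-correlation, NCHW layout, square kernel."""
        x = self.data
        wt = w.data
        oc, ic, kh, kw = wt.shape
        n, c, h, wd = x.shape
        if c != ic:
            raise ValueError(f"conv2d channel mismatch: input {c}, weight {ic}")
        if padding:
            x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        oh = (x.shape[2] - kh) // stride + 1
        ow = (x.shape[3] - kw) // stride + 1
        sN, sC, sH, sW = x.strides
        view = np.lib.stride_tricks.as_strided(
            x, (n, c, kh, kw, oh, ow),
            (sN, sC, sH, sW, sH * stride, sW * stride), writeable=False)
        cols = np.ascontiguousarray(view.reshape(n, c * kh * kw, oh * ow))
        wm = wt.reshape(oc, c * kh * kw)
        out = np.matmul(wm, cols).reshape(n, oc, oh, ow)
        if b is not None:
            out = out + b.data.reshape(1, oc, 1, 1)

        def back(g):
            gm = g.reshape(n, oc, oh * ow)
            gw = np.tensordot(gm, cols, axes=([0, 2], [0, 2]))
            gw = gw.reshape(oc, ic, kh, kw)
            gcols = np.matmul(wm.T, gm)                       # n, c*kh*kw, L
            gcols = gcols.reshape(n, c, kh, kw, oh, ow)
            gx = np.zeros_like(x)
            for i in range(kh):
                for j in range(kw):
                    gx[:, :, i:i + oh * stride:stride,
                       j:j + ow * stride:stride] += gcols[:, :, i, j]
            if padding:
                gx = gx[:, :, padding:-padding, padding:-padding]
            gb = g.sum(axis=(0, 2, 3)) if b is not None else None
            return (np.ascontiguousarray(gx), gw, gb)
        parents = (self, w) if b is None else (self, w, b)
        if b is None:
            return Tensor._make(out, parents, lambda g: back(g)[:2])
        return Tensor._make(out, parents, back)

    # ---------------------------------------------------------------- pooling
    def maxpool2d(self, kernel: int, stride: int = None, padding: int = 0):
        stride = stride or kernel
        x = self.data
        n, c, h, w = x.shape
        if padding:
            x = np.pad(x, ((0, 0), (0, 0), (padding, padding),
                           (padding, padding)), constant_values=-np.inf)
        oh = (x.shape[2] - kernel) // stride + 1
        ow = (x.shape[3] - kernel) // stride + 1
        sN, sC, sH, sW = x.strides
        view = np.lib.stride_tricks.as_strided(
            x, (n, c, oh, ow, kernel, kernel),
            (sN, sC, sH * stride, sW * stride, sH, sW), writeable=False)
        patch = view.reshape(n, c, oh, ow, kernel * kernel)
        idx = patch.argmax(axis=-1)
        out = np.take_along_axis(patch, idx[..., None], axis=-1)[..., 0]

        def back(g):
            gx = np.zeros_like(x)
            ii, jj = np.divmod(idx, kernel)
            nI, cI, oI, wI = np.indices(idx.shape)
            rows = oI * stride + ii
            colsI = wI * stride + jj
            np.add.at(gx, (nI, cI, rows, colsI), g)
            if padding:
                gx = gx[:, :, padding:-padding, padding:-padding]
            return (gx,)
        return Tensor._make(out, (self,), back)

    def upsample2x(self):
        """Nearest-neighbour 2x upsampling."""
        out = self.data.repeat(2, axis=2).repeat(2, axis=3)

        def back(g):
            n, c, h, w = g.shape
            return (g.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5)),)
        return Tensor._make(out, (self,), back)

    # ----------------------------------------------------------- normalization
    def batch_norm(self, gamma: "Tensor", beta: "Tensor", running_mean,
                   running_var, training: bool, momentum: float = 0.03,
                   eps: float = 1e-3):
        """Per-channel batch normalization (NCHW); updates running stats in place."""
        x = self.data
        if training:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            running_mean *= (1 - momentum)
            running_mean += momentum * mu
            running_var *= (1 - momentum)
            running_var += momentum * var * (x.shape[0] * x.shape[2] * x.shape[3]) / \
                max(1, (x.shape[0] * x.shape[2] * x.shape[3] - 1))
        else:
            mu, var = running_mean, running_var
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (x - mu[None, :, None, None]) * inv[None, :, None, None]
        out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

        def back(g):
            ggamma = (g * xhat).sum(axis=(0, 2, 3))
            gbeta = g.sum(axis=(0, 2, 3))
            gx_hat = g * gamma.data[None, :, None, None]
            if training:
                m = x.shape[0] * x.shape[2] * x.shape[3]
                t1 = gx_hat
                t2 = gx_hat.mean(axis=(0, 2, 3), keepdims=True)
                t3 = xhat * (gx_hat * xhat).mean(axis=(0, 2, 3), keepdims=True)
                gx = inv[None, :, None, None] * (t1 - t2 - t3)
                del m
            else:
                gx = gx_hat * inv[None, :, None, None]
            return (gx.astype(np.float32), ggamma, gbeta)
        return Tensor._make(out.astype(np.float32), (self, gamma, beta), back)

    def group_norm(self, gamma: "Tensor", beta: "Tensor", num_groups: int,
                   eps: float = 1e-5):
        """Group normalization: per sample, channels split into `num_groups`
        groups, each normalized by its own mean/variance, then an affine
        per-channel transform gamma * xhat + beta."""
        x = self.data
        n, c, h, w = x.shape
        if c % num_groups:
            raise ValueError(
                f"group_norm: {c} channels not divisible by {num_groups} groups")
        xg = x.reshape(n, num_groups, c // num_groups, h, w)
        mu = xg.mean(axis=(2, 3, 4), keepdims=True)
        var = xg.var(axis=(2, 3, 4), keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = ((xg - mu) * inv).reshape(n, c, h, w)
        out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

        def back(g):
            ggamma = (g * xhat).sum(axis=(0, 2, 3))
            gbeta = g.sum(axis=(0, 2, 3))
            gx_hat = (g * gamma.data[None, :, None, None]).reshape(
                n, num_groups, c // num_groups, h, w)
            xh = xhat.reshape(n, num_groups, c // num_groups, h, w)
            t2 = gx_hat.mean(axis=(2, 3, 4), keepdims=True)
            t3 = xh * (gx_hat * xh).mean(axis=(2, 3, 4), keepdims=True)
            gx = (inv * (gx_hat - t2 - t3)).reshape(n, c, h, w)
            return (gx.astype(np.float32), ggamma, gbeta)
        return Tensor._make(out.astype(np.float32), (self, gamma, beta), back)


class Parameter(Tensor):
    """A trainable tensor.  `frozen` parameters are counted in model summaries
    but excluded from optimizer updates (used for the fixed DFL projection)."""

    __slots__ = ("frozen",)

    def __init__(self, data, frozen: bool = False):
        super().__init__(data, requires_grad=not frozen)
        self.frozen = frozen


def concat(tensors, axis=1):
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    out = np.concatenate(datas, axis=axis)
    offs = np.cumsum([0] + sizes)

    def back(g):
        return tuple(np.take(g, range(offs[i], offs[i + 1]), axis=axis)
                     for i in range(len(datas)))
    return Tensor._make(out, tuple(tensors), back)


def stack(tensors, axis=0):
    out = np.stack([t.data for t in tensors], axis=axis)

    def back(g):
        return tuple(np.take(g, i, axis=axis) for i in range(len(tensors)))
    return Tensor._make(out, tuple(tensors), back)


def maximum(a: Tensor, b: Tensor):
    a, b = Tensor._wrap(a), Tensor._wrap(b)
    mask = (a.data >= b.data).astype(np.float32)
    return Tensor._make(
        np.maximum(a.data, b.data), (a, b),
        lambda g: (_unbroadcast(g * mask, a.shape),
                   _unbroadcast(g * (1.0 - mask), b.shape)))


def minimum(a: Tensor, b: Tensor):
    a, b = Tensor._wrap(a), Tensor._wrap(b)
    mask = (a.data <= b.data).astype(np.float32)
    return Tensor._make(
        np.minimum(a.data, b.data), (a, b),
        lambda g: (_unbroadcast(g * mask, a.shape),
                   _unbroadcast(g * (1.0 - mask), b.shape)))
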