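"""Minimal reverse-mode tensor engine for 3D segmentation networks.

A compact autodiff core over ``numpy.float32`` arrays: enough primitives to
express U-shaped convolutional networks and windowed self-attention blocks,
plus SGD/Adam optimizers.  Everything is deterministic given a seeded
``numpy.random.Generator``; there is no threading or global state.

Conventions
-----------
* Feature maps are ``(B, C, D, H, W)``: batch, channels, slices, rows, cols.
* Convolutions use zero padding ``k // 2`` ("same" at stride 1) and an
  offset-loop im2col, so the only heavy kernel is a BLAS matmul.
* Gradients accumulate additively; ``Tensor.backward`` runs a topological
  sweep from the loss.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "Conv3d",
    "InstanceNorm3d",
    "LayerNorm",
    "Linear",
    "WindowAttention",
    "TransformerBlock",
    "SGD",
    "Adam",
    "leaky_relu",
    "softmax",
    "concat",
    "maxpool2",
    "upsample2",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_bw", "_own")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), bw: Callable | None = None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self._own = False
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._bw = bw if self.requires_grad else None

    # -- graph mechanics ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        # copy-on-write: the first gradient is borrowed (it may be shared
        # with a sibling); a private buffer is made only if a second one
        # arrives
        if self.grad is None:
            self.grad = g
            self._own = False
        elif self._own:
            self.grad += g
        else:
            self.grad = self.grad + g
            self._own = True

    def backward(self) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        self._own = True
        for node in reversed(topo):
            if node._bw is not None:
                node._bw(node.grad)
            if node._parents:
                node.grad = None    # free intermediate gradients eagerly
                node._own = False

    # -- elementwise arithmetic --------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))
        out._bw = bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))
        out._bw = bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(
                    -g * self.data / (other.data ** 2), other.data.shape))
        out._bw = bw
        return out

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))
        out._bw = bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g / self.data)
        out._bw = bw
        return out

    def exp(self):
        out = Tensor(np.exp(self.data), parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * out.data)
        out._bw = bw
        return out

    # -- reductions / reshapes ---------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))
        out._bw = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else (
            np.prod([self.data.shape[a] for a in np.atleast_1d(axis)]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        src = self.data.shape
        out = Tensor(self.data.reshape(shape), parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(src))
        out._bw = bw
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(np.ascontiguousarray(self.data.transpose(axes)), parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g.transpose(tuple(inv)))
        out._bw = bw
        return out

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(np.matmul(self.data, other.data), parents=(self, other))

        def bw(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.data.shape))
        out._bw = bw
        return out

    def roll(self, shift: Sequence[int], axes: Sequence[int]):
        out = Tensor(np.roll(self.data, shift, axis=tuple(axes)), parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(np.roll(g, [-s for s in shift], axis=tuple(axes)))
        out._bw = bw
        return out


# ---------------------------------------------------------------------------
# activations and shape ops
# ---------------------------------------------------------------------------

def leaky_relu(x: Tensor, slope: float = 0.01) -> Tensor:
    mask = (x.data > 0).astype(np.float32)
    factor = mask + slope * (1.0 - mask)
    out = Tensor(x.data * factor, parents=(x,))

    def bw(g):
        if x.requires_grad:
            x._accum(g * factor)
    out._bw = bw
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, parents=(x,))

    def bw(g):
        if x.requires_grad:
            x._accum(y * (g - (g * y).sum(axis=axis, keepdims=True)))
    out._bw = bw
    return out


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]

    def bw(g):
        splits = np.cumsum(sizes[:-1])
        grads = np.split(g, splits, axis=axis)
        for t, g in zip(tensors, grads):
            if t.requires_grad:
                t._accum(g)
    out._bw = bw
    return out


def maxpool2(x: Tensor) -> Tensor:
    """2x downsampling max pool over the three spatial axes of (B,C,D,H,W)."""
    b, c, d, h, w = x.data.shape
    if d % 2 or h % 2 or w % 2:
        raise ValueError(f"maxpool2 needs even spatial dims, got {(d, h, w)}")
    xr = x.data.reshape(b, c, d // 2, 2, h // 2, 2, w // 2, 2)
    xr = xr.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(b, c, d // 2, h // 2, w // 2, 8)
    idx = xr.argmax(axis=-1)
    out = Tensor(np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0],
                 parents=(x,))

    def bw(g):
        if not x.requires_grad:
            return
        scat = np.zeros_like(xr)
        np.put_along_axis(scat, idx[..., None], g[..., None], axis=-1)
        scat = scat.reshape(b, c, d // 2, h // 2, w // 2, 2, 2, 2)
        x._accum(scat.transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(b, c, d, h, w))
    out._bw = bw
    return out


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbor 2x upsampling over the three spatial axes."""
    y = x.data.repeat(2, axis=2).repeat(2, axis=3).repeat(2, axis=4)
    out = Tensor(y, parents=(x,))
    b, c, d, h, w = x.data.shape

    def bw(g):
        if x.requires_grad:
            g = g.reshape(b, c, d, 2, h, 2, w, 2).sum(axis=(3, 5, 7))
            x._accum(g)
    out._bw = bw
    return out


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Module:
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params


class Conv3d(Module):
    """3D convolution with "same" zero padding (stride 1) or strided output."""

    def __init__(self, cin: int, cout: int, k: int | tuple[int, int, int],
                 rng: np.random.Generator, stride: int = 1, bias: bool = True):
        self.k = (k, k, k) if isinstance(k, int) else tuple(k)
        self.stride = stride
        fan_in = cin * int(np.prod(self.k))
        std = math.sqrt(2.0 / fan_in)
        self.w = Tensor(rng.normal(0.0, std, (cout, cin, *self.k)), requires_grad=True)
        self.b = Tensor(np.zeros(cout), requires_grad=True) if bias else None
        self.cin, self.cout = cin, cout

    def _im2col(self, xp: np.ndarray, out_sp: tuple[int, int, int]) -> np.ndarray:
        b = xp.shape[0]
        kd, kh, kw = self.k
        do, ho, wo = out_sp
        s = self.stride
        col = np.empty((b, self.cin, kd * kh * kw, do * ho * wo), dtype=np.float32)
        i = 0
        for dz in range(kd):
            for dy in range(kh):
                for dx in range(kw):
                    patch = xp[:, :, dz:dz + s * do:s, dy:dy + s * ho:s,
                               dx:dx + s * wo:s]
                    col[:, :, i, :] = patch.reshape(b, self.cin, -1)
                    i += 1
        return col.reshape(b, self.cin * kd * kh * kw, do * ho * wo)

    def __call__(self, x: Tensor) -> Tensor:
        b, c, d, h, w = x.data.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        if self.k == (1, 1, 1) and self.stride == 1:
            return self._pointwise(x)
        kd, kh, kw = self.k
        pd, ph, pw = kd // 2, kh // 2, kw // 2
        s = self.stride
        do = (d + 2 * pd - kd) // s + 1
        ho = (h + 2 * ph - kh) // s + 1
        wo = (w + 2 * pw - kw) // s + 1
        xp = np.pad(x.data, ((0, 0), (0, 0), (pd, pd), (ph, ph), (pw, pw)))
        col = self._im2col(xp, (do, ho, wo))
        wmat = self.w.data.reshape(self.cout, -1)
        y = np.matmul(wmat[None], col).reshape(b, self.cout, do, ho, wo)
        if self.b is not None:
            y = y + self.b.data[None, :, None, None, None]
        parents = (x, self.w) if self.b is None else (x, self.w, self.b)
        out = Tensor(y, parents=parents)

        def bw(g):
            g = g.reshape(b, self.cout, -1)
            if self.w.requires_grad:
                dw = np.matmul(g, col.transpose(0, 2, 1)).sum(axis=0)
                self.w._accum(dw.reshape(self.w.data.shape))
            if self.b is not None and self.b.requires_grad:
                self.b._accum(g.sum(axis=(0, 2)))
            if x.requires_grad:
                dcol = np.matmul(wmat.T[None], g)
                dcol = dcol.reshape(b, self.cin, kd * kh * kw, do, ho, wo)
                dxp = np.zeros_like(xp)
                i = 0
                for dz in range(kd):
                    for dy in range(kh):
                        for dx in range(kw):
                            dxp[:, :, dz:dz + s * do:s, dy:dy + s * ho:s,
                                dx:dx + s * wo:s] += dcol[:, :, i]
                            i += 1
                x._accum(dxp[:, :, pd:pd + d, ph:ph + h, pw:pw + w])
        out._bw = bw
        return out

    def _pointwise(self, x: Tensor) -> Tensor:
        """1x1x1 stride-1 path: a plain channel matmul, no im2col copy."""
        b = x.data.shape[0]
        sp = x.data.shape[2:]
        xm = x.data.reshape(b, self.cin, -1)
        wmat = self.w.data.reshape(self.cout, self.cin)
        y = np.matmul(wmat[None], xm).reshape(b, self.cout, *sp)
        if self.b is not None:
            y = y + self.b.data[None, :, None, None, None]
        parents = (x, self.w) if self.b is None else (x, self.w, self.b)
        out = Tensor(y, parents=parents)

        def bw(g):
            g = g.reshape(b, self.cout, -1)
            if self.w.requires_grad:
                dw = np.matmul(g, xm.transpose(0, 2, 1)).sum(axis=0)
                self.w._accum(dw.reshape(self.w.data.shape))
            if self.b is not None and self.b.requires_grad:
                self.b._accum(g.sum(axis=(0, 2)))
            if x.requires_grad:
                x._accum(np.matmul(wmat.T[None], g).reshape(x.data.shape))
        out._bw = bw
        return out


class InstanceNorm3d(Module):
    """Per-sample, per-channel normalization over the spatial axes."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        ax = (2, 3, 4)
        mu = x.data.mean(axis=ax, keepdims=True)
        var = x.data.var(axis=ax, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu) * inv
        gam = self.gamma.data[None, :, None, None, None]
        out = Tensor(xhat * gam + self.beta.data[None, :, None, None, None],
                     parents=(x, self.gamma, self.beta))

        def bw(g):
            if self.gamma.requires_grad:
                self.gamma._accum((g * xhat).sum(axis=(0, 2, 3, 4)))
            if self.beta.requires_grad:
                self.beta._accum(g.sum(axis=(0, 2, 3, 4)))
            if x.requires_grad:
                gg = g * gam
                m1 = gg.mean(axis=ax, keepdims=True)
                m2 = (gg * xhat).mean(axis=ax, keepdims=True)
                x._accum(inv * (gg - m1 - xhat * m2))
        out._bw = bw
        return out


class LayerNorm(Module):
    """Normalization over the last axis (token feature dimension)."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.data.mean(axis=-1, keepdims=True)
        var = x.data.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu) * inv
        out = Tensor(xhat * self.gamma.data + self.beta.data,
                     parents=(x, self.gamma, self.beta))

        def bw(g):
            if self.gamma.requires_grad:
                self.gamma._accum((g * xhat).reshape(-1, xhat.shape[-1]).sum(axis=0))
            if self.beta.requires_grad:
                self.beta._accum(g.reshape(-1, xhat.shape[-1]).sum(axis=0))
            if x.requires_grad:
                gg = g * self.gamma.data
                m1 = gg.mean(axis=-1, keepdims=True)
                m2 = (gg * xhat).mean(axis=-1, keepdims=True)
                x._accum(inv * (gg - m1 - xhat * m2))
        out._bw = bw
        return out


class Linear(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 bias: bool = True):
        std = math.sqrt(2.0 / cin)
        self.w = Tensor(rng.normal(0.0, std, (cin, cout)), requires_grad=True)
        self.b = Tensor(np.zeros(cout), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.w
        if self.b is not None:
            y = y + self.b
        return y


class WindowAttention(Module):
    """Multi-head self-attention inside non-overlapping 3D windows.

    Shifted variants cyclically roll the feature map by half a window before
    partitioning, which lets information cross window boundaries on alternate
    blocks (cyclic cross-boundary attention is accepted rather than masked).
    """

    def __init__(self, dim: int, heads: int, window: tuple[int, int, int],
                 rng: np.random.Generator, shifted: bool = False):
        if dim % heads:
            raise ValueError("dim must be divisible by heads")
        self.dim, self.heads, self.window, self.shifted = dim, heads, tuple(window), shifted
        self.q = Linear(dim, dim, rng)
        self.k = Linear(dim, dim, rng)
        self.v = Linear(dim, dim, rng)
        self.proj = Linear(dim, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        b, c, d, h, w = x.data.shape
        wd, wh, ww = self.window
        if d % wd or h % wh or w % ww:
            raise ValueError(f"spatial dims {(d, h, w)} not divisible by window {self.window}")
        shift = (wd // 2, wh // 2, ww // 2) if self.shifted else None
        if shift:
            x = x.roll([-s for s in shift], axes=(2, 3, 4))
        nd, nh, nw = d // wd, h // wh, w // ww
        t = wd * wh * ww
        # (B,C,D,H,W) -> (B*windows, tokens, C)
        y = x.transpose(0, 2, 3, 4, 1)
        y = y.reshape(b, nd, wd, nh, wh, nw, ww, c)
        y = y.transpose(0, 1, 3, 5, 2, 4, 6, 7).reshape(b * nd * nh * nw, t, c)
        dh = c // self.heads

        def heads_split(z: Tensor) -> Tensor:
            return z.reshape(z.shape[0], t, self.heads, dh).transpose(0, 2, 1, 3)

        q = heads_split(self.q(y)) * (1.0 / math.sqrt(dh))
        k = heads_split(self.k(y))
        v = heads_split(self.v(y))
        attn = softmax(q @ k.transpose(0, 1, 3, 2), axis=-1)
        z = (attn @ v).transpose(0, 2, 1, 3).reshape(b * nd * nh * nw, t, c)
        z = self.proj(z)
        # back to (B,C,D,H,W)
        z = z.reshape(b, nd, nh, nw, wd, wh, ww, c)
        z = z.transpose(0, 1, 4, 2, 5, 3, 6, 7).reshape(b, d, h, w, c)
        z = z.transpose(0, 4, 1, 2, 3)
        if shift:
            z = z.roll(list(shift), axes=(2, 3, 4))
        return z


class TransformerBlock(Module):
    """Pre-norm windowed attention + 2x-expansion MLP, both residual."""

    def __init__(self, dim: int, heads: int, window: tuple[int, int, int],
                 rng: np.random.Generator, shifted: bool = False, mlp_ratio: int = 2):
        self.norm1 = _ChannelLayerNorm(dim)
        self.attn = WindowAttention(dim, heads, window, rng, shifted)
        self.norm2 = _ChannelLayerNorm(dim)
        self.fc1 = Conv3d(dim, dim * mlp_ratio, 1, rng)
        self.fc2 = Conv3d(dim * mlp_ratio, dim, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        return x + self.fc2(leaky_relu(self.fc1(self.norm2(x))))


class _ChannelLayerNorm(Module):
    """LayerNorm over the channel axis of a (B,C,D,H,W) map."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.ln = LayerNorm(dim, eps)

    def parameters(self):
        return self.ln.parameters()

    def __call__(self, x: Tensor) -> Tensor:
        y = x.transpose(0, 2, 3, 4, 1)
        y = self.ln(y)
        return y.transpose(0, 4, 1, 2, 3)


# ---------------------------------------------------------------------------
# optimizers
# ---------------------------------------------------------------------------

class SGD:
    """SGD with Nesterov momentum and decoupled weight decay."""

    def __init__(self, params: list[Tensor], lr: float, momentum: float = 0.99,
                 nesterov: bool = True, weight_decay: float = 0.0):
        self.params = params
        self.lr, self.momentum, self.nesterov = lr, momentum, nesterov
        self.weight_decay = weight_decay
        self.vel = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        for p, v in zip(self.params, self.vel):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            if self.nesterov:
                p.data -= self.lr * (g + self.momentum * v)
            else:
                p.data -= self.lr * v


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)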