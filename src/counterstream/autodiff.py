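"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the counterstream networks need: dense and 2-D
convolutional layers, nearest-neighbour upsampling, elementwise nonlinearities,
broadcasting arithmetic, gather/concat plumbing and numerically fused losses
(softmax cross-entropy, binary cross-entropy with logits).

Weight sharing needs no special handling: a parameter tensor used in several
places of the graph (e.g. the two unfolded bottom-up passes) accumulates the
gradient contributions of every use.
"""

from __future__ import annotations

import numpy as np

# computation dtype; float32 is plenty for these nets and twice as fast.
# Gradient-check tests may rebind to float64 for tighter numerics.
DTYPE = np.float32

__all__ = [
    "Tensor",
    "relu",
    "sigmoid",
    "conv2d",
    "upsample2x",
    "avg_pool2d",
    "concat",
    "take_rows",
    "softmax_cross_entropy",
    "bce_with_logits",
]


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph bookkeeping -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep with unfolding
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out = _node(self.data + other.data, self, other)

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _node(-self.data, self)

        def bw(g):
            if self.requires_grad:
                self._accumulate(-g)

        out._backward = bw
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = _node(self.data * other.data, self, other)

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = _as_tensor(other)
        out = _node(self.data @ other.data, self, other)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        out._backward = bw
        return out

    def reshape(self, *shape):
        out = _node(self.data.reshape(*shape), self)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.shape))

        out._backward = bw
        return out

    def sum(self):
        out = _node(np.array(self.data.sum()), self)

        def bw(g):
            if self.requires_grad:
                self._accumulate(np.broadcast_to(g, self.shape).copy())

        out._backward = bw
        return out

    def mean(self):
        n = self.data.size
        out = _node(np.array(self.data.mean()), self)

        def bw(g):
            if self.requires_grad:
                self._accumulate(np.broadcast_to(g / n, self.shape).copy())

        out._backward = bw
        return out


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data: np.ndarray, *parents: Tensor) -> Tensor:
    out = Tensor(data)
    out._parents = tuple(p for p in parents if isinstance(p, Tensor))
    out.requires_grad = any(p.requires_grad for p in out._parents)
    return out


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward op."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# -- nonlinearities ----------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    out = _node(np.maximum(x.data, 0.0), x)

    def bw(g):
        if x.requires_grad:
            x._accumulate(g * (x.data > 0))

    out._backward = bw
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))
    out = _node(s, x)

    def bw(g):
        if x.requires_grad:
            x._accumulate(g * s * (1.0 - s))

    out._backward = bw
    return out


# -- structural ops ----------------------------------------------------------

def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = _node(np.concatenate([t.data for t in tensors], axis=axis), *tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    out._backward = bw
    return out


def take_rows(x: Tensor, idx) -> Tensor:
    """Gather rows of a 2-D tensor (used to pick per-sample logit segments)."""
    idx = np.asarray(idx)
    out = _node(x.data[idx], x)

    def bw(g):
        if x.requires_grad:
            acc = np.zeros_like(x.data)
            np.add.at(acc, idx, g)
            x._accumulate(acc)

    out._backward = bw
    return out


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling of an NCHW tensor."""
    d = x.data.repeat(2, axis=2).repeat(2, axis=3)
    out = _node(d, x)

    def bw(g):
        if x.requires_grad:
            n, c, h2, w2 = g.shape
            gg = g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))
            x._accumulate(gg)

    out._backward = bw
    return out


def spatial_mean(x: Tensor) -> Tensor:
    """Mean over the spatial axes of an NCHW tensor -> (N, C)."""
    n, c, h, w = x.shape
    out = _node(x.data.mean(axis=(2, 3)), x)

    def bw(g):
        if x.requires_grad:
            gg = np.broadcast_to(g[:, :, None, None] / (h * w), (n, c, h, w))
            x._accumulate(gg.copy())

    out._backward = bw
    return out


def avg_pool2d(x: Tensor, k: int) -> Tensor:
    """Non-overlapping k x k average pooling of an NCHW tensor."""
    n, c, h, w = x.shape
    assert h % k == 0 and w % k == 0, "pooling requires divisible spatial dims"
    d = x.data.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5))
    out = _node(d, x)

    def bw(g):
        if x.requires_grad:
            gg = g[:, :, :, None, :, None] / (k * k)
            gg = np.broadcast_to(gg, (n, c, h // k, k, w // k, k))
            x._accumulate(gg.reshape(n, c, h, w))

    out._backward = bw
    return out


# -- convolution -------------------------------------------------------------

def _windows(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    return win[:, :, ::stride, ::stride, :, :]  # view: n,c,oh,ow,kh,kw


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution, NCHW input, weight (out_c, in_c, kh, kw)."""
    oc, ic, kh, kw = w.shape
    n, _c, h, wdt = x.shape
    win = _windows(x.data, kh, kw, stride, pad)
    oh, ow = win.shape[2], win.shape[3]
    # (n,oh,ow,oc) <- contract (c,kh,kw)
    out_d = np.tensordot(win, w.data, axes=([1, 4, 5], [1, 2, 3]))
    out_d = np.ascontiguousarray(out_d.transpose(0, 3, 1, 2))
    if b is not None:
        out_d += b.data.reshape(1, oc, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    out = _node(out_d, *parents)

    def bw(g):
        if w.requires_grad:
            # (oc, c, kh, kw) <- contract (n, oh, ow)
            w._accumulate(np.tensordot(g, win, axes=([0, 2, 3], [0, 2, 3])))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            # (n,oh,ow,c,kh,kw) <- g (n,oc,oh,ow) x w (oc,c,kh,kw)
            dwin = np.tensordot(g.transpose(0, 2, 3, 1), w.data, axes=(3, 0))
            xp = np.zeros((n, _c, h + 2 * pad, wdt + 2 * pad), dtype=g.dtype)
            for i in range(kh):
                for j in range(kw):
                    xp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += (
                        dwin[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                    )
            x._accumulate(xp[:, :, pad : pad + h, pad : pad + wdt] if pad else xp)

    out._backward = bw
    return out


# -- fused losses ------------------------------------------------------------

def softmax_cross_entropy(logits: Tensor, labels) -> Tensor:
    """Mean cross-entropy of integer labels under softmax(logits); rows x classes."""
    labels = np.asarray(labels, dtype=np.int64)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    nll = -np.log(np.clip(p[np.arange(n), labels], 1e-300, None))
    out = _node(np.array(nll.mean()), logits)

    def bw(g):
        if logits.requires_grad:
            d = p.copy()
            d[np.arange(n), labels] -= 1.0
            logits._accumulate(g * d / n)

    out._backward = bw
    return out


def bce_with_logits(logits: Tensor, targets, pos_weight: float | None = None) -> Tensor:
    """Mean elementwise binary cross-entropy with logits (numerically stable).

    ``pos_weight`` > 1 upweights positive targets (useful for sparse masks)."""
    t = np.asarray(targets, dtype=logits.data.dtype)
    z = logits.data
    # log(1+exp(-|z|)) + max(z,0) - z*t
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    wgt = 1.0 if pos_weight is None else 1.0 + (pos_weight - 1.0) * t
    out = _node(np.array((wgt * loss).mean()), logits)
    n = z.size

    def bw(g):
        if logits.requires_grad:
            s = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
            logits._accumulate(g * wgt * (s - t) / n)

    out._backward = bw
    return out


# -- optimizers ---------------------------------------------------------------

class SGD:
    """SGD with momentum and decoupled weight decay."""

    def __init__(self, params, lr=0.01, momentum=0.9, weight_decay=0.0):
        self.params = list(params)
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self.v):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()


class Adam:
    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
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
            mh = m / (1 - b1**self.t)
            vh = v / (1 - b2**self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
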