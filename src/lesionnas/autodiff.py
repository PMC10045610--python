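"""Reverse-mode automatic differentiation over numpy arrays.

A small tensor/tape engine sufficient for training the detector on a CPU:
elementwise arithmetic, matmul, 2-D convolution expressed as a sum over
sampling taps (which makes the deformable variant a natural extension),
bilinear gathering at fractional positions with gradients flowing to both
the feature map and the positions, 2x2 max pooling, nearest upsampling and
the two detection losses (softmax cross-entropy, smooth L1).

All data is float64.  Gradients are accumulated by a topological sweep over
the recorded graph; every op that creates a Tensor attaches a closure that
pushes gradients to its parents.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concatenate",
    "conv2d",
    "deform_conv2d",
    "bilinear_gather",
    "index_rows",
    "maxpool2",
    "upsample2",
    "softmax_cross_entropy",
    "smooth_l1",
    "softmax",
    "SGD",
]


class Tensor:
    """A numpy array plus an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in _parents
        )
        self.grad = None
        self._parents = tuple(_parents)
        self._backward = _backward

    # -- plumbing ---------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (scalar unless ``grad`` given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient needs a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64).reshape(self.data.shape))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor(out_data, _parents=(self, other), _backward=bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor(-self.data, _parents=(self,), _backward=bw)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(out_data, _parents=(self, other), _backward=bw)

    __rmul__ = __mul__

    def __truediv__(self, scalar):
        return self * (1.0 / float(scalar))

    def __matmul__(self, other):
        other = as_tensor(other)
        a, b = self.data, other.data
        out_data = a @ b

        def bw(g):
            if self.requires_grad:
                self._accumulate(g @ b.T)
            if other.requires_grad:
                other._accumulate(a.T @ g)

        return Tensor(out_data, _parents=(self, other), _backward=bw)

    # -- shape ------------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.reshape(old))

        return Tensor(self.data.reshape(shape), _parents=(self,), _backward=bw)

    def flatten(self):
        return self.reshape(-1)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        return Tensor(self.data.transpose(axes), _parents=(self,), _backward=bw)

    def __getitem__(self, key):
        out_data = self.data[key]

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, key, g)
                self._accumulate(full)

        return Tensor(out_data, _parents=(self,), _backward=bw)

    # -- nonlinearities and reductions ------------------------------------

    def relu(self):
        mask = self.data > 0

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor(self.data * mask, _parents=(self,), _backward=bw)

    def leaky_relu(self, slope: float = 0.01):
        """max(x, slope*x): keeps a gradient path open for negative inputs."""
        factor = np.where(self.data > 0, 1.0, slope)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * factor)

        return Tensor(self.data * factor, _parents=(self,), _backward=bw)

    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * out_data)

        return Tensor(out_data, _parents=(self,), _backward=bw)

    def log(self):
        def bw(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        return Tensor(np.log(self.data), _parents=(self,), _backward=bw)

    def abs(self):
        sign = np.sign(self.data)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * sign)

        return Tensor(np.abs(self.data), _parents=(self,), _backward=bw)

    def sum(self, axis=None):
        out_data = self.data.sum(axis=axis)

        def bw(g):
            if self.requires_grad:
                if axis is None:
                    self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                else:
                    self._accumulate(
                        np.broadcast_to(
                            np.expand_dims(g, axis), self.data.shape
                        ).copy()
                    )

        return Tensor(out_data, _parents=(self,), _backward=bw)

    def mean(self, axis=None):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis) / n


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g.reshape(shape)


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor(out_data, _parents=tuple(tensors), _backward=bw)


# ---------------------------------------------------------------------------
# Convolution as a sum over sampling taps
# ---------------------------------------------------------------------------


def _tap_arrays(taps):
    trs = np.asarray([t[0] for t in taps], dtype=np.int64)
    tcs = np.asarray([t[1] for t in taps], dtype=np.int64)
    return trs, tcs


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, taps, stride: int = 1) -> Tensor:
    """'Same'-padded 2-D convolution of ``x`` [C,H,W] with ``w`` [O,C,K].

    ``taps`` lists the K integer (row, col) displacements of the sampling
    grid; weight k multiplies the input sampled at position p0 + taps[k].
    Zero padding outside the map.  ``stride`` subsamples output positions.
    """
    x, w = as_tensor(x), as_tensor(w)
    if b is not None:
        b = as_tensor(b)
    C, H, W = x.data.shape
    O, Cw, K = w.data.shape
    if Cw != C:
        raise ValueError(f"channel mismatch: map has {C}, weights expect {Cw}")
    if K != len(taps):
        raise ValueError(f"weight tap dim {K} != {len(taps)} taps")
    trs, tcs = _tap_arrays(taps)
    pt, pb = max(0, -trs.min()), max(0, trs.max())
    pl, pr = max(0, -tcs.min()), max(0, tcs.max())
    xpad = np.pad(x.data, ((0, 0), (pt, pb), (pl, pr)))
    Ho, Wo = -(-H // stride), -(-W // stride)
    stacked = np.empty((K, C, Ho, Wo))
    for k in range(K):
        r0, c0 = pt + trs[k], pl + tcs[k]
        stacked[k] = xpad[:, r0 : r0 + stride * Ho : stride, c0 : c0 + stride * Wo : stride]
    out_data = np.einsum("ock,kchw->ohw", w.data, stacked, optimize=True)
    if b is not None:
        out_data = out_data + b.data[:, None, None]

    parents = (x, w) if b is None else (x, w, b)

    def bw(g):
        if w.requires_grad:
            w._accumulate(np.einsum("ohw,kchw->ock", g, stacked, optimize=True))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(1, 2)))
        if x.requires_grad:
            gpad = np.zeros_like(xpad)
            gtap = np.einsum("ohw,ock->kchw", g, w.data, optimize=True)
            for k in range(K):
                r0, c0 = pt + trs[k], pl + tcs[k]
                gpad[:, r0 : r0 + stride * Ho : stride, c0 : c0 + stride * Wo : stride] += gtap[k]
            x._accumulate(gpad[:, pt : pt + H, pl : pl + W])

    return Tensor(out_data, _parents=parents, _backward=bw)


def _bilinear_pieces(pos_r, pos_c, H, W):
    """Corner indices, weights and validity masks for bilinear sampling.

    Positions outside [0, H-1] x [0, W-1] read zero (masked corners).
    """
    r0 = np.floor(pos_r)
    c0 = np.floor(pos_c)
    fr, fc = pos_r - r0, pos_c - c0
    r0, c0 = r0.astype(np.int64), c0.astype(np.int64)
    r1, c1 = r0 + 1, c0 + 1
    corners = []
    for ri, wr in ((r0, 1.0 - fr), (r1, fr)):
        for ci, wc in ((c0, 1.0 - fc), (c1, fc)):
            valid = (ri >= 0) & (ri < H) & (ci >= 0) & (ci < W)
            corners.append(
                (np.clip(ri, 0, H - 1), np.clip(ci, 0, W - 1), wr * wc, valid)
            )
    return corners, fr, fc


def deform_conv2d(x: Tensor, w: Tensor, b: Tensor | None, taps, offsets: Tensor) -> Tensor:
    """Deformable 'same' convolution: tap k samples at p0 + taps[k] + offset.

    ``offsets`` has shape [2K, H, W]; channels 2k and 2k+1 hold the (drow,
    dcol) displacement of tap k at each output position.  Fractional
    positions are resolved bilinearly; reads outside the map are zero.
    Gradients flow to the map, the weights, the bias and the offsets.
    """
    x, w = as_tensor(x), as_tensor(w)
    offsets = as_tensor(offsets)
    if b is not None:
        b = as_tensor(b)
    C, H, W = x.data.shape
    O, Cw, K = w.data.shape
    if Cw != C:
        raise ValueError(f"channel mismatch: map has {C}, weights expect {Cw}")
    if offsets.data.shape != (2 * K, H, W):
        raise ValueError(
            f"offset field shape {offsets.data.shape} != {(2 * K, H, W)}"
        )
    trs, tcs = _tap_arrays(taps)
    rows = np.arange(H)[None, :, None]
    cols = np.arange(W)[None, None, :]
    pos_r = rows + trs[:, None, None] + offsets.data[0::2]  # [K,H,W]
    pos_c = cols + tcs[:, None, None] + offsets.data[1::2]
    corners, _, _ = _bilinear_pieces(pos_r, pos_c, H, W)
    vals = []  # per-corner sampled values [K,C,H,W]
    sampled = np.zeros((K, C, H, W))
    for ri, ci, wt, valid in corners:
        v = x.data[:, ri, ci] * valid[None]  # [C,K,H,W]
        v = np.moveaxis(v, 0, 1)
        vals.append(v)
        sampled += wt[:, None] * v
    out_data = np.einsum("ock,kchw->ohw", w.data, sampled, optimize=True)
    if b is not None:
        out_data = out_data + b.data[:, None, None]

    parents = [x, w, offsets] + ([b] if b is not None else [])

    def bw(g):
        if w.requires_grad:
            w._accumulate(np.einsum("ohw,kchw->ock", g, sampled, optimize=True))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(1, 2)))
        need_x = x.requires_grad
        need_off = offsets.requires_grad
        if not (need_x or need_off):
            return
        gs = np.einsum("ohw,ock->kchw", g, w.data, optimize=True)  # dL/d sampled
        if need_x:
            gx = np.zeros_like(x.data)
            for ri, ci, wt, valid in corners:
                contrib = gs * (wt * valid)[:, None]  # [K,C,H,W]
                idx = (ri[:, None] * W + ci[:, None]) + (
                    np.arange(C)[None, :, None, None] * (H * W)
                )
                np.add.at(gx.reshape(-1), idx.ravel(), contrib.ravel())
            x._accumulate(gx)
        if need_off:
            (v00, v01, v10, v11) = vals
            # derivative of the bilinear combination wrt the row position:
            #   d/dr = (1-fc)(v10-v00) + fc(v11-v01); wrt col analogous.
            wr0 = corners[0][2] + corners[1][2]  # (1-fr)(1-fc)+(1-fr)fc = 1-fr
            wc0 = corners[0][2] + corners[2][2]  # 1-fc
            dr = wc0[:, None] * (v10 - v00) + (1.0 - wc0)[:, None] * (v11 - v01)
            dc = wr0[:, None] * (v01 - v00) + (1.0 - wr0)[:, None] * (v11 - v10)
            goff = np.empty_like(offsets.data)
            goff[0::2] = np.einsum("kchw,kchw->khw", gs, dr)
            goff[1::2] = np.einsum("kchw,kchw->khw", gs, dc)
            offsets._accumulate(goff)

    return Tensor(out_data, _parents=tuple(parents), _backward=bw)


def bilinear_gather(x: Tensor, pos) -> Tensor:
    """Sample ``x`` [C,H,W] at M fractional (row, col) positions -> [C,M].

    ``pos`` may be a constant array or a Tensor [M,2]; in the latter case
    gradients flow into the positions as well as the map.  Out-of-map reads
    contribute zero.
    """
    x = as_tensor(x)
    pos = as_tensor(pos)
    if not np.all(np.isfinite(pos.data)):
        raise ValueError("non-finite sampling position")
    C, H, W = x.data.shape
    pos_r, pos_c = pos.data[:, 0], pos.data[:, 1]
    corners, _, _ = _bilinear_pieces(pos_r, pos_c, H, W)
    vals = []
    out_data = np.zeros((C, pos_r.shape[0]))
    for ri, ci, wt, valid in corners:
        v = x.data[:, ri, ci] * valid[None]  # [C,M]
        vals.append(v)
        out_data += wt[None] * v

    def bw(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            for ri, ci, wt, valid in corners:
                contrib = g * (wt * valid)[None]
                idx = (ri[None] * W + ci[None]) + np.arange(C)[:, None] * (H * W)
                np.add.at(gx.reshape(-1), idx.ravel(), contrib.ravel())
            x._accumulate(gx)
        if pos.requires_grad:
            v00, v01, v10, v11 = vals
            wr0 = corners[0][2] + corners[1][2]  # 1-fr
            wc0 = corners[0][2] + corners[2][2]  # 1-fc
            dr = wc0[None] * (v10 - v00) + (1.0 - wc0)[None] * (v11 - v01)
            dc = wr0[None] * (v01 - v00) + (1.0 - wr0)[None] * (v11 - v10)
            gp = np.stack([(g * dr).sum(axis=0), (g * dc).sum(axis=0)], axis=1)
            pos._accumulate(gp)

    return Tensor(out_data, _parents=(x, pos), _backward=bw)


def index_rows(t: Tensor, idx) -> Tensor:
    """Select rows of ``t`` by an integer index array (with repetition)."""
    t = as_tensor(t)
    idx = np.asarray(idx, dtype=np.int64)
    out_data = t.data[idx]

    def bw(g):
        if t.requires_grad:
            gt = np.zeros_like(t.data)
            np.add.at(gt, idx, g)
            t._accumulate(gt)

    return Tensor(out_data, _parents=(t,), _backward=bw)


def maxpool2(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2; spatial dims must be even."""
    x = as_tensor(x)
    C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError(f"maxpool2 needs even spatial dims, got {H}x{W}")
    win = x.data.reshape(C, H // 2, 2, W // 2, 2).transpose(0, 1, 3, 2, 4)
    win = win.reshape(C, H // 2, W // 2, 4)
    arg = win.argmax(axis=-1)
    out_data = np.take_along_axis(win, arg[..., None], axis=-1)[..., 0]

    def bw(g):
        if x.requires_grad:
            gwin = np.zeros((C, H // 2, W // 2, 4))
            np.put_along_axis(gwin, arg[..., None], g[..., None], axis=-1)
            gx = gwin.reshape(C, H // 2, W // 2, 2, 2).transpose(0, 1, 3, 2, 4)
            x._accumulate(gx.reshape(C, H, W))

    return Tensor(out_data, _parents=(x,), _backward=bw)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling."""
    x = as_tensor(x)
    C, H, W = x.data.shape
    out_data = np.repeat(np.repeat(x.data, 2, axis=1), 2, axis=2)

    def bw(g):
        if x.requires_grad:
            x._accumulate(g.reshape(C, H, 2, W, 2).sum(axis=(2, 4)))

    return Tensor(out_data, _parents=(x,), _backward=bw)


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------


def softmax(logits: Tensor, axis: int = -1) -> Tensor:
    logits = as_tensor(logits)
    z = logits.data - logits.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        if logits.requires_grad:
            dot = (g * p).sum(axis=axis, keepdims=True)
            logits._accumulate(p * (g - dot))

    return Tensor(p, _parents=(logits,), _backward=bw)


def softmax_cross_entropy(logits: Tensor, labels) -> Tensor:
    """Mean cross-entropy of integer ``labels`` under softmax of ``logits`` [N,K]."""
    logits = as_tensor(logits)
    labels = np.asarray(labels, dtype=np.int64)
    n = logits.data.shape[0]
    if n == 0:
        return Tensor(0.0)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1))
    out_data = (logsumexp - z[np.arange(n), labels]).mean()

    def bw(g):
        if logits.requires_grad:
            p = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
            p[np.arange(n), labels] -= 1.0
            logits._accumulate(g * p / n)

    return Tensor(out_data, _parents=(logits,), _backward=bw)


def smooth_l1(pred: Tensor, target, beta: float = 1.0) -> Tensor:
    """Mean smooth-L1 (Huber) loss: quadratic below ``beta``, linear above."""
    pred = as_tensor(pred)
    target = np.asarray(target, dtype=np.float64)
    if pred.data.size == 0:
        return Tensor(0.0)
    d = pred.data - target
    ad = np.abs(d)
    elem = np.where(ad < beta, 0.5 * d * d / beta, ad - 0.5 * beta)
    out_data = elem.mean()

    def bw(g):
        if pred.requires_grad:
            pred._accumulate(g * np.clip(d / beta, -1.0, 1.0) / d.size)

    return Tensor(out_data, _parents=(pred,), _backward=bw)


# ---------------------------------------------------------------------------
# Optimiser
# ---------------------------------------------------------------------------


class SGD:
    """Stochastic gradient descent with momentum and global-norm clipping."""

    def __init__(self, params, lr: float, momentum: float = 0.0,
                 clip_norm: float | None = None):
        self.params = list(params)
        self.lr = float(lr)
        self.momentum = float(momentum)
        self.clip_norm = clip_norm
        self._vel = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        scale = 1.0
        if self.clip_norm is not None:
            sq = sum(
                float((p.grad**2).sum()) for p in self.params if p.grad is not None
            )
            norm = np.sqrt(sq)
            if norm > self.clip_norm:
                scale = self.clip_norm / norm
        for p, v in zip(self.params, self._vel):
            if p.grad is None:
                continue
            v *= self.momentum
            v += scale * p.grad
            p.data -= self.lr * v
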