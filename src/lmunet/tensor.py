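"""Minimal reverse-mode automatic differentiation on numpy arrays.

The segmentation network in this package is small (about half a million
parameters), so a compact tape-based autograd core over numpy is sufficient
to train it on CPU.  A :class:`Tensor` wraps an ``ndarray`` and records the
operations applied to it; :meth:`Tensor.backward` replays the tape in
reverse topological order.

Only the primitives the network needs are provided: elementwise arithmetic
with broadcasting, matmul, reductions, shape surgery, 2-D convolution
(im2col), depthwise causal 1-D convolution, bilinear resampling and the
usual activations.  The selective-scan recurrence lives in
:mod:`lmunet.ssm` as its own primitive.

A process-wide multiply-accumulate (MAC) counter can be armed with
:class:`mac_counter`; convolution, matmul and scan primitives report their
operation counts to it, which is how the network's FLOP accounting works.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = [
    "Tensor",
    "as_tensor",
    "mac_counter",
    "concatenate",
    "stack",
    "conv2d",
    "depthwise_conv1d_causal",
    "bilinear_resize",
]


# ---------------------------------------------------------------------------
# MAC accounting


class mac_counter:
    """Context manager that accumulates multiply-accumulate counts.

    While active, matmul/conv/scan primitives add their MAC counts (batch
    included) to :attr:`total`.  Nesting is not supported.
    """

    _active = None

    def __init__(self):
        self.total = 0

    def __enter__(self):
        mac_counter._active = self
        return self

    def __exit__(self, *exc):
        mac_counter._active = None
        return False

    @staticmethod
    def add(n):
        c = mac_counter._active
        if c is not None:
            c.total += int(n)


# ---------------------------------------------------------------------------
# Tensor


def _float_dtype(dtype):
    dt = np.dtype(dtype)
    return dt if dt in (np.float32, np.float64) else np.dtype(np.float32)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad=False):
        arr = np.asarray(data, dtype=_float_dtype(np.asarray(data).dtype))
        if not arr.flags["C_CONTIGUOUS"]:  # keep 0-d arrays 0-d
            arr = np.ascontiguousarray(arr)
        self.data = arr
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = ()

    # -- construction helpers ------------------------------------------------

    @staticmethod
    def _make(data, prev, backward):
        out = Tensor.__new__(Tensor)
        out.data = data
        out.grad = None
        out.requires_grad = any(p.requires_grad for p in prev)
        if out.requires_grad:
            out._prev = tuple(prev)
            out._backward = backward
        else:
            out._prev = ()
            out._backward = None
        return out

    def _accum(self, g):
        # always copy on first write: g may alias another node's gradient
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    # -- basic introspection -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def item(self):
        return float(self.data)

    def numpy(self):
        return self.data

    def detach(self):
        return Tensor(self.data.copy())

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- backward ------------------------------------------------------------

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        # iterative topological sort (graphs can be thousands of nodes deep)
        topo, stack, visited = [], [(self, False)], set()
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free interior gradients/tape as we go to bound memory
                if node is not self:
                    node._backward = None
                    node._prev = ()
                    node.grad = None

    # -- arithmetic ----------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other, self.dtype)
        data = self.data + other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(data, (self, other), bw)

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other, self.dtype)
        data = self.data * other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(data, (self, other), bw)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other, self.dtype))

    def __rsub__(self, other):
        return as_tensor(other, self.dtype) + (-self)

    def __truediv__(self, other):
        other = as_tensor(other, self.dtype)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return as_tensor(other, self.dtype) * self ** -1.0

    def __pow__(self, p):
        if not isinstance(p, (int, float)):
            raise TypeError("only scalar exponents are supported")
        data = self.data ** p

        def bw(g):
            if self.requires_grad:
                self._accum(g * (p * self.data ** (p - 1)))

        return Tensor._make(data, (self,), bw)

    def __matmul__(self, other):
        other = as_tensor(other, self.dtype)
        data = np.matmul(self.data, other.data)
        mac_counter.add(data.size * self.data.shape[-1])

        def bw(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.data.shape))

        return Tensor._make(data, (self, other), bw)

    # -- elementwise nonlinearities -------------------------------------------

    def exp(self):
        data = np.exp(self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g * data)

        return Tensor._make(data, (self,), bw)

    def log(self):
        data = np.log(self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._make(data, (self,), bw)

    def sigmoid(self):
        data = _sigmoid(self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g * data * (1.0 - data))

        return Tensor._make(data, (self,), bw)

    def tanh(self):
        data = np.tanh(self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g * (1.0 - data * data))

        return Tensor._make(data, (self,), bw)

    def relu(self):
        data = np.maximum(self.data, 0.0)

        def bw(g):
            if self.requires_grad:
                self._accum(g * (self.data > 0))

        return Tensor._make(data, (self,), bw)

    def silu(self):
        s = _sigmoid(self.data)
        data = self.data * s

        def bw(g):
            if self.requires_grad:
                self._accum(g * (s * (1.0 + self.data * (1.0 - s))))

        return Tensor._make(data, (self,), bw)

    def softplus(self):
        data = np.logaddexp(0.0, self.data).astype(self.dtype)

        def bw(g):
            if self.requires_grad:
                self._accum(g * _sigmoid(self.data))

        return Tensor._make(data, (self,), bw)

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        data = self.data.sum(axis=axis, keepdims=keepdims)
        data = np.asarray(data, dtype=self.dtype)
        shape = self.data.shape

        def bw(g):
            if not self.requires_grad:
                return
            gg = g
            if not keepdims and axis is not None:
                gg = np.expand_dims(gg, _norm_axes(axis, len(shape)))
            self._accum(np.broadcast_to(gg, shape))

        return Tensor._make(data, (self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else int(
            np.prod([self.data.shape[a] for a in _norm_axes(axis, self.ndim)])
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis, keepdims=False):
        data = self.data.max(axis=axis, keepdims=True)
        mask = self.data == data  # ties share gradient equally
        counts = mask.sum(axis=axis, keepdims=True)
        out = data if keepdims else np.squeeze(data, axis=axis)

        def bw(g):
            if not self.requires_grad:
                return
            gg = g if keepdims else np.expand_dims(g, axis)
            self._accum((mask * (gg / counts)).astype(self.dtype, copy=False))

        return Tensor._make(np.ascontiguousarray(out), (self,), bw)

    def softmax(self, axis=-1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        data = e / e.sum(axis=axis, keepdims=True)

        def bw(g):
            if self.requires_grad:
                dot = (g * data).sum(axis=axis, keepdims=True)
                self._accum(data * (g - dot))

        return Tensor._make(data, (self,), bw)

    # -- shape surgery ---------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        data = np.ascontiguousarray(self.data.reshape(shape))
        orig = self.data.shape

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))

        return Tensor._make(data, (self,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        data = np.ascontiguousarray(self.data.transpose(axes))
        inv = np.argsort(axes)

        def bw(g):
            if self.requires_grad:
                self._accum(np.ascontiguousarray(g.transpose(inv)))

        return Tensor._make(data, (self,), bw)

    def __getitem__(self, idx):
        data = np.ascontiguousarray(self.data[idx])
        shape = self.data.shape
        parts = idx if isinstance(idx, tuple) else (idx,)
        basic = all(isinstance(p, (slice, int)) for p in parts)

        def bw(g):
            if self.requires_grad:
                full = np.zeros(shape, dtype=self.dtype)
                if basic:  # disjoint target: plain assignment is enough
                    full[idx] = g
                else:
                    np.add.at(full, idx, g)
                self._accum(full)

        return Tensor._make(data, (self,), bw)

    def pad2d(self, pad_h, pad_w, value=0.0):
        """Zero-pad the two trailing (spatial) axes symmetrically."""
        p = [(0, 0)] * (self.ndim - 2) + [(pad_h, pad_h), (pad_w, pad_w)]
        data = np.pad(self.data, p, constant_values=value)
        sl = tuple([slice(None)] * (self.ndim - 2)
                   + [slice(pad_h, data.shape[-2] - pad_h),
                      slice(pad_w, data.shape[-1] - pad_w)])

        def bw(g):
            if self.requires_grad:
                self._accum(np.ascontiguousarray(g[sl]))

        return Tensor._make(data, (self,), bw)


def as_tensor(x, dtype=np.float32):
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=_float_dtype(np.asarray(x).dtype)
                             if isinstance(x, np.ndarray) else dtype))


def _sigmoid(x):
    return expit(x)


def _norm_axes(axis, ndim):
    if isinstance(axis, int):
        axis = (axis,)
    return tuple(a % ndim for a in axis)


def _unbroadcast(g, shape):
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (gs, ss) in enumerate(zip(g.shape, shape)) if ss == 1 and gs != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return np.ascontiguousarray(g)


# ---------------------------------------------------------------------------
# multi-input ops


def concatenate(tensors, axis):
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(int(a), int(b))
                t._accum(np.ascontiguousarray(g[tuple(sl)]))

    return Tensor._make(data, tuple(tensors), bw)


def stack(tensors, axis=0):
    tensors = [as_tensor(t) for t in tensors]
    data = np.stack([t.data for t in tensors], axis=axis)

    def bw(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.ascontiguousarray(np.take(g, i, axis=axis)))

    return Tensor._make(data, tuple(tensors), bw)


# ---------------------------------------------------------------------------
# convolution


def _im2col(x, kh, kw, sh, sw, dh, dw, hout, wout):
    b, c, _, _ = x.shape
    cols = np.empty((b, c, kh, kw, hout, wout), dtype=x.dtype)
    for i in range(kh):
        hi = i * dh
        for j in range(kw):
            wj = j * dw
            cols[:, :, i, j] = x[:, :, hi:hi + sh * hout:sh, wj:wj + sw * wout:sw]
    return cols.reshape(b, c * kh * kw, hout * wout)


def _col2im(cols, xshape, kh, kw, sh, sw, dh, dw, hout, wout):
    b, c, h, w = xshape
    x = np.zeros(xshape, dtype=cols.dtype)
    cols = cols.reshape(b, c, kh, kw, hout, wout)
    for i in range(kh):
        hi = i * dh
        for j in range(kw):
            wj = j * dw
            x[:, :, hi:hi + sh * hout:sh, wj:wj + sw * wout:sw] += cols[:, :, i, j]
    return x


def conv2d(x, weight, bias=None, stride=1, padding=0, dilation=1):
    """2-D cross-correlation, NCHW layout.

    ``weight`` has shape (C_out, C_in, kh, kw).  Counts
    kh*kw*C_in*C_out*H_out*W_out MACs per sample toward the active counter.
    """
    x = as_tensor(x)
    weight = as_tensor(weight)
    sh, sw = (stride, stride) if isinstance(stride, int) else stride
    ph, pw = (padding, padding) if isinstance(padding, int) else padding
    dh, dw = (dilation, dilation) if isinstance(dilation, int) else dilation
    cout, cin, kh, kw = weight.data.shape
    b, c, h, w = x.data.shape
    if c != cin:
        raise ValueError(f"conv2d: input has {c} channels, weight expects {cin}")
    hp, wp = h + 2 * ph, w + 2 * pw
    hout = (hp - (dh * (kh - 1) + 1)) // sh + 1
    wout = (wp - (dw * (kw - 1) + 1)) // sw + 1
    if kh == kw == 1 and sh == sw == 1 and not (ph or pw):
        # pointwise convolution: plain channel matmul, no patch extraction
        out = np.matmul(weight.data.reshape(cout, cin), x.data.reshape(b, cin, h * w))
        out = out.reshape(b, cout, h, w)
        if bias is not None:
            out = out + bias.data.reshape(1, cout, 1, 1)
        mac_counter.add(b * cin * cout * h * w)
        prev = (x, weight) + ((bias,) if bias is not None else ())

        def bw1(g):
            gmat = g.reshape(b, cout, h * w)
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3)))
            if weight.requires_grad:
                gw = np.tensordot(gmat, x.data.reshape(b, cin, h * w), axes=([0, 2], [0, 2]))
                weight._accum(gw.reshape(weight.data.shape))
            if x.requires_grad:
                gx = np.matmul(weight.data.reshape(cout, cin).T, gmat)
                x._accum(gx.reshape(b, cin, h, w))

        return Tensor._make(np.ascontiguousarray(out), prev, bw1)
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if (ph or pw) else x.data
    cols = _im2col(xp, kh, kw, sh, sw, dh, dw, hout, wout)
    wmat = weight.data.reshape(cout, cin * kh * kw)
    out = np.matmul(wmat, cols)  # (b, cout, hout*wout) via broadcasting
    out = out.reshape(b, cout, hout, wout)
    if bias is not None:
        out = out + bias.data.reshape(1, cout, 1, 1)
    mac_counter.add(b * kh * kw * cin * cout * hout * wout)

    prev = (x, weight) + ((bias,) if bias is not None else ())

    def bw(g):
        gmat = g.reshape(b, cout, hout * wout)
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if weight.requires_grad:
            gw = np.tensordot(gmat, cols, axes=([0, 2], [0, 2]))
            weight._accum(gw.reshape(weight.data.shape))
        if x.requires_grad:
            gcols = np.matmul(wmat.T, gmat)
            gx = _col2im(gcols, xp.shape, kh, kw, sh, sw, dh, dw, hout, wout)
            if ph or pw:
                gx = gx[:, :, ph:hp - ph, pw:wp - pw]
            x._accum(np.ascontiguousarray(gx))

    return Tensor._make(np.ascontiguousarray(out), prev, bw)


def depthwise_conv1d_causal(x, weight, bias=None):
    """Causal depthwise 1-D convolution over (B, C, L).

    ``weight`` has shape (C, k); the input is left-padded with k-1 zeros so
    position t only sees positions <= t.
    """
    x = as_tensor(x)
    b, c, length = x.data.shape
    k = weight.data.shape[1]
    xp = np.pad(x.data, ((0, 0), (0, 0), (k - 1, 0)))
    out = np.zeros((b, c, length), dtype=x.dtype)
    for i in range(k):
        out += weight.data[None, :, i:i + 1] * xp[:, :, i:i + length]
    if bias is not None:
        out = out + bias.data.reshape(1, c, 1)
    mac_counter.add(b * c * k * length)
    prev = (x, weight) + ((bias,) if bias is not None else ())

    def bw(g):
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2)))
        if weight.requires_grad:
            gw = np.empty_like(weight.data)
            for i in range(k):
                gw[:, i] = (g * xp[:, :, i:i + length]).sum(axis=(0, 2))
            weight._accum(gw)
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for i in range(k):
                gxp[:, :, i:i + length] += weight.data[None, :, i:i + 1] * g
            x._accum(np.ascontiguousarray(gxp[:, :, k - 1:]))

    return Tensor._make(out, prev, bw)


# ---------------------------------------------------------------------------
# bilinear resampling


def _bilinear_matrix(h_in, h_out, dtype):
    """(h_in, h_out) interpolation matrix, align_corners=False, edge-clamped."""
    scale = h_in / h_out
    centers = (np.arange(h_out) + 0.5) * scale - 0.5
    lo = np.floor(centers).astype(np.int64)
    frac = (centers - lo).astype(dtype)
    hi = np.clip(lo + 1, 0, h_in - 1)
    lo = np.clip(lo, 0, h_in - 1)
    m = np.zeros((h_in, h_out), dtype=dtype)
    cols = np.arange(h_out)
    np.add.at(m, (lo, cols), 1 - frac)
    np.add.at(m, (hi, cols), frac)
    return m


def bilinear_resize(x, size):
    """Resize the trailing two axes of a (B, C, H, W) tensor bilinearly.

    Implemented as two separable interpolation matmuls, so both directions
    (and the transposed backward pass) run through BLAS.
    """
    x = as_tensor(x)
    b, c, h, w = x.data.shape
    hout, wout = size
    if (h, w) == (hout, wout):
        return x
    my = _bilinear_matrix(h, hout, x.dtype)   # (h, hout)
    mx = _bilinear_matrix(w, wout, x.dtype)   # (w, wout)

    def apply(d, a, bmat):
        t = np.tensordot(d, a, axes=([2], [0]))      # (b, c, w, hout)
        t = np.tensordot(t, bmat, axes=([2], [0]))   # (b, c, hout, wout)
        return np.ascontiguousarray(t)

    out = apply(x.data, my, mx)

    def bw(g):
        if x.requires_grad:
            x._accum(apply(g, my.T, mx.T))

    return Tensor._make(out, (x,), bw)
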