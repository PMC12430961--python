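"""Minimal reverse-mode autodiff over numpy arrays.

The engine supports exactly the operations the detection network needs:
broadcast arithmetic, matmul, reductions, reshaping, 2-D convolution with
asymmetric padding, stride-1 max pooling, nearest-neighbour upsampling,
softmax and a handful of pointwise nonlinearities.  Everything is float32
NCHW.  Gradients flow through a tape built eagerly by each operation and
are accumulated by a topological backward pass.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat"]


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
    """A numpy array with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # ---- plumbing -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def numpy(self) -> np.ndarray:
        return self.data

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.asarray(grad, dtype=np.float32))
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # ---- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return self._make(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bw(g):
            a._accum(-g)

        return self._make(-a.data, (a,), bw)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return self._make(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

        return self._make(a.data / b.data, (a, b), bw)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, p: float):
        a = self

        def bw(g):
            a._accum(g * p * np.power(a.data, p - 1))

        return self._make(np.power(a.data, p), (a,), bw)

    def matmul(self, other):
        other = self._wrap(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
                a._accum(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
                b._accum(_unbroadcast(gb, b.data.shape))

        return self._make(np.matmul(a.data, b.data), (a, b), bw)

    __matmul__ = matmul

    # ---- reductions / shaping -------------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.data.shape).copy())

        return self._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[i] for i in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = a.data.shape

        def bw(g):
            a._accum(g.reshape(old))

        return self._make(a.data.reshape(shape), (a,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = np.argsort(axes)

        def bw(g):
            a._accum(g.transpose(inv))

        return self._make(a.data.transpose(axes), (a,), bw)

    def gather_rows(self, index):
        """Select rows along axis 0; scatter-adds gradient back."""
        index = np.asarray(index, dtype=np.int64)
        a = self

        def bw(g):
            full = np.zeros_like(a.data)
            np.add.at(full, index, g)
            a._accum(full)

        return self._make(a.data[index], (a,), bw)

    # ---- pointwise nonlinearities ---------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def bw(g):
            a._accum(g * out_data)

        return self._make(out_data, (a,), bw)

    def log(self):
        a = self

        def bw(g):
            a._accum(g / a.data)

        return self._make(np.log(a.data), (a,), bw)

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)

        def bw(g):
            a._accum(g * 0.5 / out_data)

        return self._make(out_data, (a,), bw)

    def arctan(self):
        a = self

        def bw(g):
            a._accum(g / (1.0 + a.data * a.data))

        return self._make(np.arctan(a.data), (a,), bw)

    def sigmoid(self):
        a = self
        s = 1.0 / (1.0 + np.exp(-np.clip(a.data, -80, 80)))

        def bw(g):
            a._accum(g * s * (1.0 - s))

        return self._make(s, (a,), bw)

    def silu(self):
        a = self
        s = 1.0 / (1.0 + np.exp(-np.clip(a.data, -80, 80)))

        def bw(g):
            a._accum(g * (s + a.data * s * (1.0 - s)))

        return self._make(a.data * s, (a,), bw)

    def relu(self):
        a = self
        mask = a.data > 0

        def bw(g):
            a._accum(g * mask)

        return self._make(a.data * mask, (a,), bw)

    def clip(self, lo: float, hi: float):
        a = self
        mask = (a.data > lo) & (a.data < hi)

        def bw(g):
            a._accum(g * mask)

        return self._make(np.clip(a.data, lo, hi), (a,), bw)

    def maximum(self, other):
        other = self._wrap(other)
        a, b = self, other
        amax = a.data >= b.data

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * amax, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * (~amax), b.data.shape))

        return self._make(np.maximum(a.data, b.data), (a, b), bw)

    def minimum(self, other):
        other = self._wrap(other)
        a, b = self, other
        amin = a.data <= b.data

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * amin, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * (~amin), b.data.shape))

        return self._make(np.minimum(a.data, b.data), (a, b), bw)

    def softmax(self, axis: int = -1):
        a = self
        z = a.data - a.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def bw(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            a._accum(s * (g - dot))

        return self._make(s, (a,), bw)

    # ---- spatial ops (NCHW) ---------------------------------------------
    def conv2d(self, weight: "Tensor", bias=None, stride: int = 1, padding=None):
        """2-D cross-correlation.  `padding` is (top, bottom, left, right);
        defaults to symmetric `(k-1)//2` on each side."""
        a, w = self, weight
        N, C, H, W = a.data.shape
        O, Ci, kh, kw = w.data.shape
        if Ci != C:
            raise ValueError(f"channel mismatch: input {C}, weight expects {Ci}")
        if padding is None:
            padding = ((kh - 1) // 2, (kh - 1) // 2, (kw - 1) // 2, (kw - 1) // 2)
        pt, pb, pl, pr = padding
        xp = np.pad(a.data, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
        Hp, Wp = xp.shape[2], xp.shape[3]
        OH = (Hp - kh) // stride + 1
        OW = (Wp - kw) // stride + 1
        cols = _im2col(xp, kh, kw, stride, OH, OW)  # (N, C*kh*kw, OH*OW)
        wm = w.data.reshape(O, -1)
        y = np.matmul(wm, cols).reshape(N, O, OH, OW)
        if bias is not None:
            y = y + bias.data.reshape(1, O, 1, 1)
        parents = (a, w) + ((bias,) if bias is not None else ())

        def bw(g):
            gr = g.reshape(N, O, OH * OW)
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3)))
            if w.requires_grad:
                gw = np.einsum("nol,nkl->ok", gr, cols, optimize=True)
                w._accum(gw.reshape(w.data.shape))
            if a.requires_grad:
                a._accum(
                    _conv2d_input_grad(g, w.data, (N, C, H, W), stride, (pt, pb, pl, pr))
                )

        return self._make(y, parents, bw)

    def depthwise_conv2d(self, weight: "Tensor", bias=None):
        """Stride-1 depthwise convolution; `weight` has shape (C, kh, kw).
        Symmetric (k-1)//2 padding (odd kernels only)."""
        a, w = self, weight
        N, C, H, W = a.data.shape
        Cw, kh, kw = w.data.shape
        if Cw != C:
            raise ValueError("depthwise channel mismatch")
        pt, pl = (kh - 1) // 2, (kw - 1) // 2
        xp = np.pad(a.data, ((0, 0), (0, 0), (pt, kh - 1 - pt), (pl, kw - 1 - pl)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
        y = np.einsum("nchwij,cij->nchw", win, w.data, optimize=True)
        if bias is not None:
            y = y + bias.data.reshape(1, C, 1, 1)
        parents = (a, w) + ((bias,) if bias is not None else ())

        def bw(g):
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3)))
            if w.requires_grad:
                w._accum(np.einsum("nchwij,nchw->cij", win, g, optimize=True))
            if a.requires_grad:
                gp = np.pad(g, ((0, 0), (0, 0),
                                (kh - 1 - pt, pt), (kw - 1 - pl, pl)))
                gwin = np.lib.stride_tricks.sliding_window_view(
                    gp, (kh, kw), axis=(2, 3))
                wf = w.data[:, ::-1, ::-1]
                a._accum(np.einsum("nchwij,cij->nchw", gwin, wf, optimize=True))

        return self._make(y, parents, bw)

    def maxpool2d_s1(self, kernel: int):
        """Stride-1 max pool with size-preserving asymmetric padding:
        floor((k-1)/2) before, ceil((k-1)/2) after, on both axes."""
        a = self
        k = int(kernel)
        pa, pb = (k - 1) // 2, k - 1 - (k - 1) // 2
        N, C, H, W = a.data.shape
        xp = np.pad(a.data, ((0, 0), (0, 0), (pa, pb), (pa, pb)),
                    constant_values=-np.inf)
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        flat = win.reshape(N, C, H, W, k * k)
        arg = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

        def bw(g):
            gpad = np.zeros_like(xp)
            n, c, h, w = np.indices((N, C, H, W))
            np.add.at(gpad, (n, c, h + arg // k, w + arg % k), g)
            a._accum(gpad[:, :, pa:pa + H, pa:pa + W])

        return self._make(out, (a,), bw)

    def upsample2x(self):
        a = self
        N, C, H, W = a.data.shape
        out = a.data.repeat(2, axis=2).repeat(2, axis=3)

        def bw(g):
            a._accum(g.reshape(N, C, H, 2, W, 2).sum(axis=(3, 5)))

        return self._make(out, (a,), bw)


def _im2col(xp, kh, kw, stride, OH, OW):
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (N, C, OH, OW, kh, kw)
    N, C = xp.shape[0], xp.shape[1]
    return np.ascontiguousarray(
        win.transpose(0, 1, 4, 5, 2, 3)
    ).reshape(N, C * kh * kw, OH * OW)


def _conv2d_input_grad(g, w, in_shape, stride, padding):
    """Input gradient as a full correlation with the flipped kernel."""
    N, C, H, W = in_shape
    O, _, kh, kw = w.shape
    pt, pb, pl, pr = padding
    OH, OW = g.shape[2], g.shape[3]
    if stride > 1:  # zero-stuff
        gs = np.zeros((N, O, (OH - 1) * stride + 1, (OW - 1) * stride + 1),
                      dtype=g.dtype)
        gs[:, :, ::stride, ::stride] = g
    else:
        gs = g
    extra_h = H + pt + pb - kh - (OH - 1) * stride
    extra_w = W + pl + pr - kw - (OW - 1) * stride
    gp = np.pad(gs, ((0, 0), (0, 0),
                     (kh - 1 - pt, kh - 1 - pb + extra_h),
                     (kw - 1 - pl, kw - 1 - pr + extra_w)))
    wf = np.ascontiguousarray(w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
    cols = _im2col(gp, kh, kw, 1, H, W)
    return np.matmul(wf.reshape(C, -1), cols).reshape(N, C, H, W)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tuple(tensors), bw)
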