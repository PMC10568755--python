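"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package trains and runs small convolutional detectors on the CPU, so the
engine implements exactly the operator set those graphs need: broadcasting
elementwise arithmetic, reductions, shape ops, 2-D (grouped) convolution,
max-pooling, neighbourhood unfolding and nearest/bilinear upsampling.
Gradients are accumulated into ``Tensor.grad`` by :meth:`Tensor.backward`
via a topological sort of the recorded tape.
"""
from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager that disables tape recording (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")
    __array_priority__ = 100  # numpy defers binary ops to Tensor

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad):
        grad = np.asarray(grad, dtype=np.float32)
        if self.grad is None:
            self.grad = grad.copy() if grad.base is not None else grad
        else:
            self.grad += grad

    def backward(self, grad=None):
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without grad requires a scalar")
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

    # -- elementwise arithmetic ------------------------------------------
    @staticmethod
    def _as_tensor(x):
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._as_tensor(other)
        out_data = self.data + other.data

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor._make(out_data, (self, other), back)

    __radd__ = __add__

    def __neg__(self):
        def back(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), back)

    def __sub__(self, other):
        return self + (-Tensor._as_tensor(other))

    def __rsub__(self, other):
        return Tensor._as_tensor(other) + (-self)

    def __mul__(self, other):
        other = Tensor._as_tensor(other)
        out_data = self.data * other.data

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(out_data, (self, other), back)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._as_tensor(other)
        out_data = self.data / other.data

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data**2, other.shape))

        return Tensor._make(out_data, (self, other), back)

    def __rtruediv__(self, other):
        return Tensor._as_tensor(other) / self

    def __pow__(self, p: float):
        out_data = self.data**p

        def back(g):
            self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(out_data, (self,), back)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def back(g):
            self._accum(g * 0.5 / np.maximum(out_data, 1e-12))

        return Tensor._make(out_data, (self,), back)

    def exp(self):
        out_data = np.exp(self.data)

        def back(g):
            self._accum(g * out_data)

        return Tensor._make(out_data, (self,), back)

    def log(self):
        def back(g):
            self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), back)

    def abs(self):
        def back(g):
            self._accum(g * np.sign(self.data))

        return Tensor._make(np.abs(self.data), (self,), back)

    def arctan(self):
        def back(g):
            self._accum(g / (1.0 + self.data**2))

        return Tensor._make(np.arctan(self.data), (self,), back)

    def clamp(self, lo=None, hi=None):
        out_data = np.clip(self.data, lo, hi)
        mask = np.ones_like(self.data)
        if lo is not None:
            mask *= self.data >= lo
        if hi is not None:
            mask *= self.data <= hi

        def back(g):
            self._accum(g * mask)

        return Tensor._make(out_data, (self,), back)

    def maximum(self, other):
        other = Tensor._as_tensor(other)
        out_data = np.maximum(self.data, other.data)
        take_self = self.data >= other.data

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * take_self, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * ~take_self, other.shape))

        return Tensor._make(out_data, (self, other), back)

    def minimum(self, other):
        other = Tensor._as_tensor(other)
        out_data = np.minimum(self.data, other.data)
        take_self = self.data <= other.data

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * take_self, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * ~take_self, other.shape))

        return Tensor._make(out_data, (self, other), back)

    # -- activations ------------------------------------------------------
    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def back(g):
            self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), back)

    def silu(self):
        sig = 1.0 / (1.0 + np.exp(-self.data))
        out_data = self.data * sig

        def back(g):
            self._accum(g * (sig * (1.0 + self.data * (1.0 - sig))))

        return Tensor._make(out_data, (self,), back)

    def relu(self):
        mask = self.data > 0

        def back(g):
            self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), back)

    def hsigmoid(self):
        # relu6(x + 3) / 6
        out_data = np.clip(self.data + 3.0, 0.0, 6.0) / 6.0
        mask = ((self.data > -3.0) & (self.data < 3.0)) / 6.0

        def back(g):
            self._accum(g * mask)

        return Tensor._make(out_data, (self,), back)

    def hswish(self):
        hs = np.clip(self.data + 3.0, 0.0, 6.0) / 6.0
        deriv = hs + self.data * (((self.data > -3.0) & (self.data < 3.0)) / 6.0)

        def back(g):
            self._accum(g * deriv)

        return Tensor._make(self.data * hs, (self,), back)

    def softmax(self, axis: int):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def back(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            self._accum(out_data * (g - dot))

        return Tensor._make(out_data, (self,), back)

    # -- reductions & shape ops ------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def back(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape))

        return Tensor._make(out_data, (self,), back)

    def mean(self, axis=None, keepdims=False):
        n = self.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.shape

        def back(g):
            self._accum(g.reshape(orig))

        return Tensor._make(self.data.reshape(shape), (self,), back)

    def transpose(self, axes):
        inv = np.argsort(axes)

        def back(g):
            self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), back)

    def slice_axis(self, axis: int, start: int, stop: int):
        idx = [slice(None)] * self.ndim
        idx[axis] = slice(start, stop)
        idx = tuple(idx)

        def back(g):
            full = np.zeros(self.shape, dtype=np.float32)
            full[idx] = g
            self._accum(full)

        return Tensor._make(self.data[idx], (self,), back)

    def take_rows(self, index: np.ndarray):
        """Gather along axis 0; scatter-add on the way back."""
        index = np.asarray(index)

        def back(g):
            full = np.zeros(self.shape, dtype=np.float32)
            np.add.at(full, index, g)
            self._accum(full)

        return Tensor._make(self.data[index], (self,), back)

    # -- spatial ops (NCHW) ----------------------------------------------
    def conv2d(self, weight: "Tensor", bias=None, stride: int = 1,
               padding: int = 0, groups: int = 1):
        x, w = self.data, weight.data
        B, C, H, W = x.shape
        CO, CIG, KH, KW = w.shape
        G = groups
        assert C == CIG * G and CO % G == 0
        COG = CO // G
        HO = (H + 2 * padding - KH) // stride + 1
        WO = (W + 2 * padding - KW) // stride + 1
        xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding))) \
            if padding else x
        xg = xp.reshape(B, G, CIG, *xp.shape[2:])
        wg = w.reshape(G, COG, CIG, KH, KW)
        out = np.zeros((B, G, COG, HO, WO), dtype=np.float32)
        for ki in range(KH):
            for kj in range(KW):
                xs = xg[:, :, :, ki:ki + stride * HO:stride, kj:kj + stride * WO:stride]
                out += np.einsum("bgihw,goi->bgohw", xs, wg[:, :, :, ki, kj],
                                 optimize=True)
        out = out.reshape(B, CO, HO, WO)
        if bias is not None:
            out = out + bias.data.reshape(1, CO, 1, 1)

        parents = (self, weight) + ((bias,) if bias is not None else ())

        def back(g):
            gg = g.reshape(B, G, COG, HO, WO)
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3)))
            if weight.requires_grad:
                gw = np.zeros_like(wg)
                for ki in range(KH):
                    for kj in range(KW):
                        xs = xg[:, :, :, ki:ki + stride * HO:stride,
                                kj:kj + stride * WO:stride]
                        gw[:, :, :, ki, kj] = np.einsum(
                            "bgihw,bgohw->goi", xs, gg, optimize=True)
                weight._accum(gw.reshape(w.shape))
            if self.requires_grad:
                gxp = np.zeros_like(xg)
                for ki in range(KH):
                    for kj in range(KW):
                        gxp[:, :, :, ki:ki + stride * HO:stride,
                            kj:kj + stride * WO:stride] += np.einsum(
                            "bgohw,goi->bgihw", gg, wg[:, :, :, ki, kj],
                            optimize=True)
                gx = gxp.reshape(xp.shape)
                if padding:
                    gx = gx[:, :, padding:-padding, padding:-padding]
                self._accum(gx)

        return Tensor._make(out, parents, back)

    def maxpool2d(self, k: int, stride: int = 1, padding: int = 0):
        x = self.data
        B, C, H, W = x.shape
        HO = (H + 2 * padding - k) // stride + 1
        WO = (W + 2 * padding - k) // stride + 1
        xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                    constant_values=-np.inf) if padding else x
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::stride, ::stride]          # B,C,HO,WO,k,k
        flat = win.reshape(B, C, HO, WO, k * k)
        arg = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

        def back(g):
            gxp = np.zeros_like(xp)
            ib, ic, ih, iw = np.indices((B, C, HO, WO))
            rh = ih * stride + arg // k
            rw = iw * stride + arg % k
            np.add.at(gxp, (ib, ic, rh, rw), g)
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            self._accum(gxp)

        return Tensor._make(out, (self,), back)

    def upsample_nearest(self, scale: int):
        out_data = self.data.repeat(scale, axis=2).repeat(scale, axis=3)
        B, C, H, W = self.shape

        def back(g):
            gg = g.reshape(B, C, H, scale, W, scale).sum(axis=(3, 5))
            self._accum(gg)

        return Tensor._make(out_data, (self,), back)

    def upsample_bilinear(self, scale: int):
        """Bilinear interpolation with half-pixel centres (align_corners=False)."""
        B, C, H, W = self.shape
        HO, WO = H * scale, W * scale

        def src(n_out, n_in):
            c = (np.arange(n_out) + 0.5) / scale - 0.5
            c = np.clip(c, 0, n_in - 1)
            lo = np.floor(c).astype(int)
            hi = np.minimum(lo + 1, n_in - 1)
            frac = c - lo
            return lo, hi, frac.astype(np.float32)

        y0, y1, fy = src(HO, H)
        x0, x1, fx = src(WO, W)
        x = self.data
        top = x[:, :, y0][:, :, :, x0] * (1 - fx) + x[:, :, y0][:, :, :, x1] * fx
        bot = x[:, :, y1][:, :, :, x0] * (1 - fx) + x[:, :, y1][:, :, :, x1] * fx
        out = top * (1 - fy)[:, None] + bot * fy[:, None]

        def back(g):
            gx = np.zeros_like(x)
            wy = ((1 - fy)[:, None], fy[:, None])
            for ys, wyy in zip((y0, y1), wy):
                for xs, wxx in zip((x0, x1), ((1 - fx), fx)):
                    np.add.at(gx, (slice(None), slice(None), ys[:, None], xs[None, :]),
                              g * wyy * wxx)
            self._accum(gx)

        return Tensor._make(out.astype(np.float32), (self,), back)

    def pad_edge(self, p: int):
        """Replicate-pad the two spatial axes by ``p`` pixels."""
        out_data = np.pad(self.data, ((0, 0), (0, 0), (p, p), (p, p)), mode="edge")

        def back(g):
            core = g[:, :, p:-p, p:-p].copy()
            core[:, :, 0, :] += g[:, :, :p, p:-p].sum(axis=2)
            core[:, :, -1, :] += g[:, :, -p:, p:-p].sum(axis=2)
            core[:, :, :, 0] += g[:, :, p:-p, :p].sum(axis=3)
            core[:, :, :, -1] += g[:, :, p:-p, -p:].sum(axis=3)
            core[:, :, 0, 0] += g[:, :, :p, :p].sum(axis=(2, 3))
            core[:, :, 0, -1] += g[:, :, :p, -p:].sum(axis=(2, 3))
            core[:, :, -1, 0] += g[:, :, -p:, :p].sum(axis=(2, 3))
            core[:, :, -1, -1] += g[:, :, -p:, -p:].sum(axis=(2, 3))
            self._accum(core)

        return Tensor._make(out_data, (self,), back)

    def unfold(self, k: int, padding: int = 0):
        """Extract k x k neighbourhoods: (B,C,H,W) -> (B,C,k*k,H,W)."""
        x = self.data
        B, C, H, W = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding))) \
            if padding else x
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        out = win.reshape(B, C, win.shape[2], win.shape[3], k * k)
        out = np.ascontiguousarray(out.transpose(0, 1, 4, 2, 3))

        def back(g):
            gxp = np.zeros_like(xp)
            HO, WO = g.shape[3], g.shape[4]
            gk = g.reshape(B, C, k, k, HO, WO)
            for ki in range(k):
                for kj in range(k):
                    gxp[:, :, ki:ki + HO, kj:kj + WO] += gk[:, :, ki, kj]
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            self._accum(gxp)

        return Tensor._make(out, (self,), back)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [t for t in tensors if t.shape[axis] > 0]
    if len(tensors) == 1:
        return tensors[0]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]

    def back(g):
        ofs = 0
        for t, s in zip(tensors, sizes):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(ofs, ofs + s)
                t._accum(g[tuple(idx)])
            ofs += s

    return Tensor._make(out_data, tuple(tensors), back)
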