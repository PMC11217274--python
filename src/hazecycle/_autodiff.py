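"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the primitives the dehazing networks need: broadcasted
elementwise arithmetic, activations, reductions, 2-D "valid" cross-correlation
(im2col + BLAS matmul), zero-dilation and padding (from which strided and
transposed convolutions are composed), channel concatenation and cropping,
and per-channel normalisation layers.

All tensors are float32 `numpy` arrays; images follow the NCHW layout.
Gradient correctness of every primitive is checked against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "pad2d", "dilate2d", "crop2d",
           "instance_norm", "batch_norm_train", "batch_norm_eval"]

_F32 = np.float32


def _as_array(x) -> np.ndarray:
    a = np.asarray(x, dtype=_F32)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- graph bookkeeping -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward_fn) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward_fn
        return out

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(_F32, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        # iterative topological sort (graphs are hundreds of nodes deep)
        topo, visited, stack = [], set(), [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
                node._backward = None  # free closures eagerly

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- conveniences ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def __float__(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- elementwise arithmetic -------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data + other.data

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))
        return Tensor._make(out_data, (self, other), back)

    __radd__ = __add__

    def __neg__(self):
        def back(g):
            self._accum(-g)
        return Tensor._make(-self.data, (self,), back)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data * other.data

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))
        return Tensor._make(out_data, (self, other), back)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data / other.data

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data ** 2,
                                          other.data.shape))
        return Tensor._make(out_data, (self, other), back)

    def __rtruediv__(self, other):
        return Tensor(other) / self

    # -- activations & pointwise functions ---------------------------------
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

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def back(g):
            self._accum(g * out_data * (1.0 - out_data))
        return Tensor._make(out_data, (self,), back)

    def tanh(self):
        out_data = np.tanh(self.data)

        def back(g):
            self._accum(g * (1.0 - out_data ** 2))
        return Tensor._make(out_data, (self,), back)

    def relu(self):
        mask = self.data > 0

        def back(g):
            self._accum(g * mask)
        return Tensor._make(self.data * mask, (self,), back)

    def leaky_relu(self, slope: float = 0.2):
        mask = self.data > 0
        scale = np.where(mask, _F32(1.0), _F32(slope))

        def back(g):
            self._accum(g * scale)
        return Tensor._make(self.data * scale, (self,), back)

    def clip(self, lo: float, hi: float):
        """Clamp; gradient passes only where unclipped."""
        mask = (self.data > lo) & (self.data < hi)

        def back(g):
            self._accum(g * mask)
        return Tensor._make(np.clip(self.data, lo, hi), (self,), back)

    # -- reductions --------------------------------------------------------
    def mean(self):
        n = self.data.size

        def back(g):
            self._accum(np.full_like(self.data, g / n))
        return Tensor._make(self.data.mean(dtype=np.float64).astype(_F32),
                            (self,), back)

    def sum(self):
        def back(g):
            self._accum(np.full_like(self.data, g))
        return Tensor._make(self.data.sum(dtype=np.float64).astype(_F32),
                            (self,), back)

    def reshape(self, *shape):
        old = self.data.shape

        def back(g):
            self._accum(g.reshape(old))
        return Tensor._make(self.data.reshape(*shape), (self,), back)


# -- structural ops ---------------------------------------------------------

def concat(tensors, axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def back(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])
    return Tensor._make(out_data, tuple(tensors), back)


def crop2d(x: Tensor, h0: int, h1: int, w0: int, w1: int) -> Tensor:
    """Slice the spatial dims of an NCHW tensor to ``[h0:h1, w0:w1]``."""
    def back(g):
        gx = np.zeros_like(x.data)
        gx[:, :, h0:h1, w0:w1] = g
        x._accum(gx)
    return Tensor._make(x.data[:, :, h0:h1, w0:w1], (x,), back)


def dilate2d(x: Tensor, stride: int) -> Tensor:
    """Insert ``stride - 1`` zeros between spatial elements (NCHW)."""
    if stride == 1:
        return x
    n, c, h, w = x.data.shape
    out_data = np.zeros((n, c, (h - 1) * stride + 1, (w - 1) * stride + 1),
                        dtype=_F32)
    out_data[:, :, ::stride, ::stride] = x.data

    def back(g):
        x._accum(np.ascontiguousarray(g[:, :, ::stride, ::stride]))
    return Tensor._make(out_data, (x,), back)


def pad2d(x: Tensor, pad, mode: str = "zero") -> Tensor:
    """Pad the spatial dims of an NCHW tensor.

    ``pad`` is ``(top, bottom, left, right)``; mode is ``zero`` or
    ``reflect``.  Reflection padding folds its gradient back onto the
    mirrored source pixels.
    """
    pt, pb, pl, pr = pad
    if pt == pb == pl == pr == 0:
        return x
    spec = ((0, 0), (0, 0), (pt, pb), (pl, pr))
    if mode == "zero":
        out_data = np.pad(x.data, spec)

        def back(g):
            h, w = x.data.shape[2:]
            x._accum(np.ascontiguousarray(g[:, :, pt:pt + h, pl:pl + w]))
    elif mode == "reflect":
        out_data = np.pad(x.data, spec, mode="reflect")
        h, w = x.data.shape[2:]
        idx_h = np.pad(np.arange(h), (pt, pb), mode="reflect")
        idx_w = np.pad(np.arange(w), (pl, pr), mode="reflect")

        def back(g):
            gx = np.zeros_like(x.data)
            np.add.at(gx, (slice(None), slice(None),
                           idx_h[:, None], idx_w[None, :]), g)
            x._accum(gx)
    else:
        raise ValueError(f"unknown pad mode {mode!r}")
    return Tensor._make(out_data, (x,), back)


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int):
    """Return (cols, Ho, Wo): cols has shape (N*Ho*Wo, C*kh*kw)."""
    n, c, h, w = x.shape
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]          # (N, C, Ho, Wo, kh, kw)
    ho, wo = win.shape[2], win.shape[3]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)
    return np.ascontiguousarray(cols), ho, wo


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1) -> Tensor:
    """'Valid' cross-correlation of NCHW input with (Cout,Cin,kh,kw) weights.

    Padding is applied by the caller via :func:`pad2d`, which keeps this
    primitive simple and makes transposed convolution a composition of
    :func:`dilate2d`, :func:`pad2d` and :func:`conv2d`.
    """
    n, c, h, wdt = x.data.shape
    co, ci, kh, kw = w.data.shape
    if ci != c:
        raise ValueError(f"channel mismatch: input {c}, kernel {ci}")
    if h < kh or wdt < kw:
        raise ValueError(f"input {h}x{wdt} smaller than kernel {kh}x{kw}")
    cols, ho, wo = _im2col(x.data, kh, kw, stride)
    wm = w.data.reshape(co, -1)
    out = cols @ wm.T                             # (N*Ho*Wo, Co)
    out = out.reshape(n, ho, wo, co).transpose(0, 3, 1, 2)
    if b is not None:
        out = out + b.data.reshape(1, co, 1, 1)
    out = np.ascontiguousarray(out)

    def back(g):
        gy = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, co)
        if b is not None and b.requires_grad:
            b._accum(gy.sum(axis=0))
        if w.requires_grad:
            w._accum((gy.T @ cols).reshape(co, ci, kh, kw))
        if x.requires_grad:
            # grad wrt input: dilate gy by stride, full-pad, correlate with
            # the spatially flipped, channel-transposed kernel.
            gyd = g
            if stride > 1:
                tmp = np.zeros((n, co, (ho - 1) * stride + 1,
                                (wo - 1) * stride + 1), dtype=_F32)
                tmp[:, :, ::stride, ::stride] = g
                gyd = tmp
            gyp = np.pad(gyd, ((0, 0), (0, 0), (kh - 1, kh - 1),
                               (kw - 1, kw - 1)))
            wrot = np.ascontiguousarray(
                w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
            gcols, gh, gw = _im2col(gyp, kh, kw, 1)
            gx_used = (gcols @ wrot.reshape(c, -1).T)
            gx_used = gx_used.reshape(n, gh, gw, c).transpose(0, 3, 1, 2)
            if gh == h and gw == wdt:
                x._accum(np.ascontiguousarray(gx_used))
            else:
                # strided windows may not cover the last input rows/cols
                gx = np.zeros_like(x.data)
                gx[:, :, :gh, :gw] = gx_used
                x._accum(gx)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out, parents, back)


# -- normalisation ----------------------------------------------------------

def _norm_backward(g, xhat, inv_std, gamma, axes):
    """Shared backward for instance/batch norm (reduction over `axes`)."""
    m = 1
    for a in axes:
        m *= xhat.shape[a]
    dxhat = g * gamma.reshape(1, -1, 1, 1)
    mean_d = dxhat.mean(axis=axes, keepdims=True)
    mean_dx = (dxhat * xhat).mean(axis=axes, keepdims=True)
    return inv_std * (dxhat - mean_d - xhat * mean_dx)


def _norm(x: Tensor, gamma: Tensor, beta: Tensor, axes, eps: float) -> Tensor:
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv_std
    out = gamma.data.reshape(1, -1, 1, 1) * xhat + beta.data.reshape(1, -1, 1, 1)

    def back(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            x._accum(_norm_backward(g, xhat, inv_std, gamma.data, axes))
    return Tensor._make(out.astype(_F32), (x, gamma, beta), back)


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor,
                  eps: float = 1e-5) -> Tensor:
    """Per-sample, per-channel normalisation over the spatial dims."""
    return _norm(x, gamma, beta, axes=(2, 3), eps=eps)


def batch_norm_train(x: Tensor, gamma: Tensor, beta: Tensor,
                     running: dict, momentum: float = 0.1,
                     eps: float = 1e-5) -> Tensor:
    """Batch norm in training mode; updates `running` mean/var in place."""
    mu = x.data.mean(axis=(0, 2, 3))
    var = x.data.var(axis=(0, 2, 3))
    running["mean"] = (1 - momentum) * running["mean"] + momentum * mu
    running["var"] = (1 - momentum) * running["var"] + momentum * var
    return _norm(x, gamma, beta, axes=(0, 2, 3), eps=eps)


def batch_norm_eval(x: Tensor, gamma: Tensor, beta: Tensor,
                    running: dict, eps: float = 1e-5) -> Tensor:
    scale = (gamma.data / np.sqrt(running["var"] + eps)).reshape(1, -1, 1, 1)
    shift = (beta.data - gamma.data * running["mean"]
             / np.sqrt(running["var"] + eps)).reshape(1, -1, 1, 1)
    out = x.data * scale + shift

    def back(g):
        if x.requires_grad:
            x._accum(g * scale)
    return Tensor._make(out.astype(_F32), (x,), back)
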