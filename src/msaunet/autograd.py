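"""Minimal reverse-mode automatic differentiation over numpy arrays.

Feature maps are channels-last: ``(batch, height, width, channels)``.
A :class:`Tensor` wraps an ndarray and records the operations applied to
it; calling :meth:`Tensor.backward` on a scalar result accumulates
gradients into every upstream tensor created with ``requires_grad=True``.

The op set is exactly what an encoder--decoder segmentation network
needs: elementwise arithmetic with broadcasting, ``log``/``exp``/
``relu``/``sigmoid``, reductions, channel concatenation, same-padded
(dilated) 2-D convolution, non-overlapping max pooling, bilinear
resizing with half-pixel centers, and batch normalization.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "conv2d",
    "max_pool2d",
    "resize_bilinear",
    "batch_norm",
    "no_grad",
]

_grad_enabled = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum axes that were broadcast from size 1
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # make numpy defer to our reflected operators (ndarray * Tensor etc.)
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, dtype={self.data.dtype}, requires_grad={self.requires_grad})"

    # -- graph construction helpers ------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        out.requires_grad = _grad_enabled and any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray):
        grad = np.asarray(grad, dtype=self.data.dtype)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def backward(self, grad=None):
        """Backpropagate from this tensor (scalar unless ``grad`` given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar tensor")
            grad = np.ones_like(self.data)
        # topological order via iterative DFS
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
                if p.requires_grad and id(p) not in visited:
                    stack.append((p, False))
        self._accumulate(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- elementwise arithmetic ----------------------------------------
    def __add__(self, other):
        other = as_tensor(other, like=self)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor._make(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-as_tensor(other, like=self))

    def __rsub__(self, other):
        return as_tensor(other, like=self) + (-self)

    def __mul__(self, other):
        other = as_tensor(other, like=self)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other, like=self)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / (other.data ** 2), other.shape)
                )

        return Tensor._make(self.data / other.data, (self, other), bwd)

    def __rtruediv__(self, other):
        return as_tensor(other, like=self) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1))

        return Tensor._make(self.data ** exponent, (self,), bwd)

    # -- elementwise nonlinearities ------------------------------------
    def log(self):
        def bwd(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        return Tensor._make(np.log(self.data), (self,), bwd)

    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * out_data)

        return Tensor._make(out_data, (self,), bwd)

    def relu(self):
        mask = self.data > 0

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor._make(self.data * mask, (self,), bwd)

    def sigmoid(self):
        # numerically stable two-sided formulation; the result is kept
        # strictly inside (0, 1) at the working precision so saturated
        # logits cannot round to the closed endpoints
        x = self.data
        out_data = np.empty_like(x)
        pos = x >= 0
        out_data[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out_data[~pos] = ex / (1.0 + ex)
        info = np.finfo(out_data.dtype)
        np.clip(out_data, info.tiny, 1.0 - info.epsneg, out=out_data)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), bwd)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient is passed through inside the interval."""
        inside = (self.data >= lo) & (self.data <= hi)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * inside)

        return Tensor._make(np.clip(self.data, lo, hi), (self,), bwd)

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.shape))

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        orig = self.shape

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.reshape(orig))

        return Tensor._make(self.data.reshape(*shape), (self,), bwd)


def as_tensor(x, like: Tensor | None = None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    dtype = like.data.dtype if like is not None else None
    return Tensor(np.asarray(x, dtype=dtype))


# ----------------------------------------------------------------------
# structural ops
# ----------------------------------------------------------------------

def concat(tensors, axis: int = -1) -> Tensor:
    """Concatenate tensors along ``axis`` (default: channel axis)."""
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        pieces = np.split(g, splits, axis=axis)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t._accumulate(piece)

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tensors, bwd)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           dilation: int = 1) -> Tensor:
    """Same-padded 2-D convolution on NHWC input.

    ``weight`` has shape ``(kh, kw, c_in, c_out)``; ``dilation`` spaces the
    kernel taps so a 3x3 kernel at rate r covers a ``(2r+1)``-pixel span.
    Padding keeps the spatial dimensions unchanged for odd kernels.
    """
    x = as_tensor(x)
    kh, kw, c_in, c_out = weight.shape
    if x.shape[-1] != c_in:
        raise ValueError(
            f"conv2d: input has {x.shape[-1]} channels, weight expects {c_in}"
        )
    b_, h, w, _ = x.shape
    parents = (x, weight) if bias is None else (x, weight, bias)
    w_flat = weight.data.reshape(kh * kw * c_in, c_out)

    if kh == kw == 1:
        # pointwise fast path: a single GEMM, no padding or column buffer
        out = x.data.reshape(-1, c_in) @ w_flat
        if bias is not None:
            out += bias.data

        def bwd1(g):
            g2 = g.reshape(-1, c_out)
            if weight.requires_grad:
                weight._accumulate(
                    (x.data.reshape(-1, c_in).T @ g2).reshape(weight.shape))
            if x.requires_grad:
                x._accumulate((g2 @ w_flat.T).reshape(x.shape))
            if bias is not None and bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 1, 2)))

        return Tensor._make(out.reshape(b_, h, w, c_out), parents, bwd1)

    ph = dilation * (kh - 1) // 2
    pw = dilation * (kw - 1) // 2
    xp = np.pad(x.data, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    # im2col: one contiguous copy per kernel tap into a single buffer,
    # then one GEMM over all taps
    cols = np.empty((b_ * h * w, kh * kw * c_in), dtype=x.data.dtype)
    cols4 = cols.reshape(b_, h, w, kh * kw * c_in)
    for u in range(kh):
        for v in range(kw):
            tap = (u * kw + v) * c_in
            cols4[..., tap:tap + c_in] = xp[:, u * dilation:u * dilation + h,
                                            v * dilation:v * dilation + w, :]
    out = cols @ w_flat
    if bias is not None:
        out += bias.data

    def bwd(g):
        g2 = g.reshape(-1, c_out)
        if weight.requires_grad:
            weight._accumulate((cols.T @ g2).reshape(weight.shape))
        if x.requires_grad:
            gcols = (g2 @ w_flat.T).reshape(b_, h, w, kh * kw * c_in)
            gxp = np.zeros_like(xp)
            for u in range(kh):
                for v in range(kw):
                    tap = (u * kw + v) * c_in
                    gxp[:, u * dilation:u * dilation + h,
                        v * dilation:v * dilation + w, :] += gcols[..., tap:tap + c_in]
            if ph or pw:
                x._accumulate(gxp[:, ph:ph + h, pw:pw + w, :])
            else:
                x._accumulate(gxp)
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 1, 2)))

    return Tensor._make(out.reshape(b_, h, w, c_out), parents, bwd)


def max_pool2d(x: Tensor, k: int) -> Tensor:
    """Max pooling with kernel ``k``, stride ``k``, no padding.

    Spatial dimensions must be divisible by ``k``; ties split the
    gradient evenly (a valid subgradient, and measure-zero on real data).
    """
    x = as_tensor(x)
    b_, h, w, c = x.shape
    if h % k or w % k:
        axis = "height" if h % k else "width"
        raise ValueError(
            f"max_pool2d: {axis} {(h if h % k else w)} not divisible by pool size {k}"
        )
    xr = x.data.reshape(b_, h // k, k, w // k, k, c)
    out = xr.max(axis=(2, 4))

    def bwd(g):
        if not x.requires_grad:
            return
        mask = xr == out[:, :, None, :, None, :]
        counts = mask.sum(axis=(2, 4), keepdims=True)
        gx = mask * (g[:, :, None, :, None, :] / counts)
        x._accumulate(gx.reshape(b_, h, w, c))

    return Tensor._make(out, (x,), bwd)


def _bilinear_matrix(n_out: int, n_in: int, dtype) -> np.ndarray:
    """Row-stochastic interpolation matrix with half-pixel centers.

    Maps a length ``n_in`` signal to length ``n_out``; matches
    align_corners=False resize semantics, so constants map to constants.
    """
    A = np.zeros((n_out, n_in), dtype=dtype)
    scale = n_in / n_out
    for o in range(n_out):
        src = (o + 0.5) * scale - 0.5
        src = min(max(src, 0.0), n_in - 1.0)
        i0 = int(np.floor(src))
        i1 = min(i0 + 1, n_in - 1)
        t = src - i0
        A[o, i0] += 1.0 - t
        A[o, i1] += t
    return A


def resize_bilinear(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Separable bilinear resize of an NHWC tensor (half-pixel centers)."""
    x = as_tensor(x)
    _, h, w, _ = x.shape
    Ah = _bilinear_matrix(out_h, h, x.data.dtype)
    Aw = _bilinear_matrix(out_w, w, x.data.dtype)
    out = np.einsum("oh,bhwc->bowc", Ah, x.data, optimize=True)
    out = np.einsum("pw,bowc->bopc", Aw, out, optimize=True)

    def bwd(g):
        if not x.requires_grad:
            return
        gx = np.einsum("pw,bopc->bowc", Aw, g, optimize=True)
        gx = np.einsum("oh,bowc->bhwc", Ah, gx, optimize=True)
        x._accumulate(gx)

    return Tensor._make(out, (x,), bwd)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               running_mean: np.ndarray, running_var: np.ndarray,
               training: bool, momentum: float = 0.9,
               eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization on NHWC input.

    In training mode, batch statistics over (B, H, W) are used and the
    running buffers are updated in place; in inference mode the running
    buffers are used and the op is a per-channel affine map.
    """
    x = as_tensor(x)
    axes = (0, 1, 2)
    if training:
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        n = x.data.shape[0] * x.data.shape[1] * x.data.shape[2]
        running_mean *= momentum
        running_mean += (1.0 - momentum) * mu
        unbiased = var * (n / max(n - 1, 1))
        running_var *= momentum
        running_var += (1.0 - momentum) * unbiased
    else:
        mu = running_mean.astype(x.data.dtype)
        var = running_var.astype(x.data.dtype)
    inv_std = 1.0 / np.sqrt(var + eps)
    x_hat = (x.data - mu) * inv_std
    out = gamma.data * x_hat + beta.data

    def bwd(g):
        if gamma.requires_grad:
            gamma._accumulate((g * x_hat).sum(axis=axes))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=axes))
        if not x.requires_grad:
            return
        if training:
            n = x.data.shape[0] * x.data.shape[1] * x.data.shape[2]
            gxh = g * gamma.data
            gx = (gxh - gxh.mean(axis=axes)
                  - x_hat * (gxh * x_hat).mean(axis=axes)) * inv_std
            x._accumulate(gx)
        else:
            x._accumulate(g * gamma.data * inv_std)

    return Tensor._make(out, (x, gamma, beta), bwd)
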