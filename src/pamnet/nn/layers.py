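"""Minimal 3D convolutional network layers with explicit backpropagation.

Tensors are numpy arrays of shape (batch, channels, depth, height, width),
float32.  The depth axis carries time for the RF front half of the
reconstruction network and the axial image axis for the back half.

Convolutions use TensorFlow-style ``same`` padding (output = ceil(in/stride),
asymmetric zero padding with the extra sample on the trailing side) or
``valid`` padding.  Stride-1 ``same`` convolutions with odd effective
kernels, and stride-1 transposed convolutions, are evaluated spectrally on
a zero-padded linear-convolution grid (forward and both adjoints); strided
and valid convolutions build patch matrices in slabs along the depth axis
(bounded peak memory) and backpropagate via a kernel-tap loop over strided
views.  The two paths are cross-validated in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter",
    "Layer",
    "Conv3d",
    "ConvTranspose3d",
    "BatchNorm3d",
    "ReLU",
    "MaxNorm",
    "DenseBlock",
]

# cap on elements of a materialized patch matrix (float32) per forward slab
_PATCH_BUDGET = 24_000_000

from scipy import fft as _sfft


def _fft_shape(sizes):
    return tuple(_sfft.next_fast_len(s) for s in sizes)


class Parameter:
    """A trainable tensor with an accumulated gradient."""

    def __init__(self, value: np.ndarray, *, decay: bool = True):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.decay = decay  # eligible for L2 regularization

    @property
    def size(self) -> int:
        return self.value.size

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> list[Parameter]:
        return []

    def output_shape(self, in_shape: tuple[int, ...]) -> tuple[int, ...]:
        """(C, D, H, W) -> (C, D, H, W) without running data through."""
        return in_shape


def _triple(v) -> tuple[int, int, int]:
    if np.isscalar(v):
        return (int(v),) * 3
    t = tuple(int(a) for a in v)
    if len(t) != 3:
        raise ValueError("expected a scalar or length-3 tuple")
    return t


def _same_pad(n: int, k: int, s: int, d: int) -> tuple[int, int, int]:
    ke = (k - 1) * d + 1
    out = -(-n // s)
    pad = max((out - 1) * s + ke - n, 0)
    return pad // 2, pad - pad // 2, out


def _valid_out(n: int, k: int, s: int, d: int) -> int:
    ke = (k - 1) * d + 1
    if n < ke:
        raise ValueError(f"input extent {n} smaller than effective kernel {ke}")
    return (n - ke) // s + 1


def _conv3d_forward(xp, weight, bias, stride, dilation, out_sizes):
    """Correlate a pre-padded input with the kernel via slabbed im2col.

    xp : (B, C, Dp, Hp, Wp) padded input
    weight : (O, C, kd, kh, kw)
    returns (B, O, *out_sizes)
    """
    B, C = xp.shape[:2]
    O = weight.shape[0]
    kd, kh, kw = weight.shape[2:]
    sd, sh, sw = stride
    dd, dh, dw = dilation
    od, oh, ow = out_sizes
    ke = ((kd - 1) * dd + 1, (kh - 1) * dh + 1, (kw - 1) * dw + 1)
    win = np.lib.stride_tricks.sliding_window_view(xp, ke, axis=(2, 3, 4))
    # subsample positions by stride and taps by dilation -> view, no copy
    win = win[:, :, ::sd, ::sh, ::sw, ::dd, ::dh, ::dw]
    win = win[:, :, :od, :oh, :ow]
    wmat = weight.reshape(O, -1).astype(np.float32)
    y = np.empty((B, O, od, oh, ow), dtype=np.float32)
    slab = max(1, _PATCH_BUDGET // max(1, B * oh * ow * C * kd * kh * kw))
    for d0 in range(0, od, slab):
        d1 = min(od, d0 + slab)
        # (B, C, ds, oh, ow, kd, kh, kw) -> (B, ds, oh, ow, C*kd*kh*kw)
        patch = np.ascontiguousarray(win[:, :, d0:d1].transpose(0, 2, 3, 4, 1, 5, 6, 7))
        patch = patch.reshape(B, d1 - d0, oh, ow, -1)
        y[:, :, d0:d1] = np.moveaxis(patch @ wmat.T, -1, 1)
    if bias is not None:
        y += bias.reshape(1, O, 1, 1, 1)
    return y


def _tap_slices(i, j, l, stride, dilation, out_sizes):
    sd, sh, sw = stride
    dd, dh, dw = dilation
    od, oh, ow = out_sizes
    return (
        slice(i * dd, i * dd + (od - 1) * sd + 1, sd),
        slice(j * dh, j * dh + (oh - 1) * sh + 1, sh),
        slice(l * dw, l * dw + (ow - 1) * sw + 1, sw),
    )


def _conv3d_backward(xp, weight, grad, stride, dilation):
    """Gradients of a padded-input correlation.

    Returns (dxp, dweight, dbias); dxp has the padded shape.
    """
    O, C, kd, kh, kw = weight.shape
    out_sizes = grad.shape[2:]
    dxp = np.zeros_like(xp)
    dw = np.zeros_like(weight)
    g2 = grad.reshape(grad.shape[0], O, -1)  # (B, O, P)
    for i in range(kd):
        for j in range(kh):
            for l in range(kw):
                sl = _tap_slices(i, j, l, stride, dilation, out_sizes)
                x_sl = xp[:, :, sl[0], sl[1], sl[2]]
                # dW[o,c] = sum_{b,pos} g[b,o,pos] * x[b,c,pos]
                dw[:, :, i, j, l] = np.einsum(
                    "bop,bcp->oc", g2, x_sl.reshape(x_sl.shape[0], C, -1)
                )
                # dx[b,c,pos] += sum_o g[b,o,pos] * W[o,c]
                tmp = np.tensordot(grad, weight[:, :, i, j, l], axes=([1], [0]))
                dxp[:, :, sl[0], sl[1], sl[2]] += np.moveaxis(tmp, -1, 1)
    db = grad.sum(axis=(0, 2, 3, 4))
    return dxp, dw, db


def _materialize_kernel(weight, dilation):
    """Insert dilation zeros so the kernel acts at unit dilation."""
    if dilation == (1, 1, 1):
        return weight
    O, C, kd, kh, kw = weight.shape
    dd, dh, dw = dilation
    ke = ((kd - 1) * dd + 1, (kh - 1) * dh + 1, (kw - 1) * dw + 1)
    out = np.zeros((O, C, *ke), dtype=weight.dtype)
    out[:, :, ::dd, ::dh, ::dw] = weight
    return out


class _FFTConvPath:
    """Spectral evaluation of stride-1 'same' convolutions (odd effective kernel).

    Used for both the forward correlation and its two adjoints; the padded
    linear-convolution grid makes all three exact (verified against the
    direct path in the test suite).
    """

    @staticmethod
    def applicable(stride, padding, kernel, dilation):
        ke = tuple((k - 1) * d + 1 for k, d in zip(kernel, dilation))
        return stride == (1, 1, 1) and padding == "same" and all(k % 2 == 1 for k in ke)

    @staticmethod
    def forward(x, weight, bias, dilation, cache_out=None):
        B, C = x.shape[:2]
        O = weight.shape[0]
        wd = _materialize_kernel(weight, dilation)
        ke = wd.shape[2:]
        n = x.shape[2:]
        s = _fft_shape([ni + ki - 1 for ni, ki in zip(n, ke)])
        axes = (-3, -2, -1)
        xh = _sfft.rfftn(x, s, axes=axes)
        # correlation = convolution with the flipped kernel
        wh = _sfft.rfftn(wd[:, :, ::-1, ::-1, ::-1], s, axes=axes)
        yh = np.einsum("bcdhw,ocdhw->bodhw", xh, wh)
        y_full = _sfft.irfftn(yh, s, axes=axes)
        off = tuple(k // 2 for k in ke)
        sl = tuple(slice(o, o + ni) for o, ni in zip(off, n))
        y = np.ascontiguousarray(y_full[:, :, sl[0], sl[1], sl[2]]).astype(np.float32)
        if bias is not None:
            y += bias.reshape(1, O, 1, 1, 1)
        if cache_out is not None:
            cache_out["xh"] = xh
            cache_out["s"] = s
            cache_out["n"] = n
        return y

    @staticmethod
    def backward(cache, weight, grad, dilation):
        xh, s, n = cache["xh"], cache["s"], cache["n"]
        wd = _materialize_kernel(weight, dilation)
        ke = wd.shape[2:]
        axes = (-3, -2, -1)
        off = tuple(k // 2 for k in ke)
        # embed grad at the 'same' window offset inside the full grid
        gfull = np.zeros((grad.shape[0], grad.shape[1], *s), dtype=np.float32)
        sl = tuple(slice(o, o + ni) for o, ni in zip(off, n))
        gfull[:, :, sl[0], sl[1], sl[2]] = grad
        gh = _sfft.rfftn(gfull, s, axes=axes)
        # dx[q] = sum_t g[q + off - t] wd[t]  ->  (gfull * wd)[q + 2*off]
        wh_unflipped = _sfft.rfftn(wd, s, axes=axes)
        dxh = np.einsum("bodhw,ocdhw->bcdhw", gh, wh_unflipped)
        dx_full = _sfft.irfftn(dxh, s, axes=axes)
        sl2 = tuple(slice(k - 1, k - 1 + ni) for k, ni in zip(ke, n))
        dx = dx_full[:, :, sl2[0], sl2[1], sl2[2]].astype(np.float32)
        # dwd[t] = sum_{b,p} g[b,p] x[b,p + t - off] = corr(x, gfull)[ke - 1 - t]
        ch = np.einsum("bcdhw,bodhw->ocdhw", np.conj(xh), gh)
        corr = _sfft.irfftn(ch, s, axes=axes)
        dwd = corr[:, :, : ke[0], : ke[1], : ke[2]][:, :, ::-1, ::-1, ::-1]
        dd, dh_, dw_ = dilation
        dw = dwd[:, :, ::dd, ::dh_, ::dw_].astype(np.float32)
        db = grad.sum(axis=(0, 2, 3, 4))
        return np.ascontiguousarray(dx), np.ascontiguousarray(dw), db


class Conv3d(Layer):
    """3D correlation with stride, dilation, and 'same'/'valid' zero padding.

    Stride-1 'same' convolutions with odd effective kernels are evaluated
    spectrally; everything else goes through the direct im2col/tap path."""

    def __init__(self, in_channels, out_channels, kernel, stride=1, dilation=1,
                 padding="same", bias=True, rng=None):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = _triple(kernel)
        self.stride = _triple(stride)
        self.dilation = _triple(dilation)
        if padding not in ("same", "valid"):
            raise ValueError("padding must be 'same' or 'valid'")
        self.padding = padding
        rng = rng or np.random.default_rng()
        fan_in = in_channels * int(np.prod(self.kernel))
        limit = np.sqrt(6.0 / max(fan_in, 1))  # He-style uniform init
        self.weight = Parameter(
            rng.uniform(-limit, limit, size=(out_channels, in_channels, *self.kernel))
        )
        self.bias = Parameter(np.zeros(out_channels), decay=False) if bias else None
        self._cache = None

    def parameters(self) -> list[Parameter]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def _pads_and_out(self, spatial):
        pads, outs = [], []
        for n, k, s, d in zip(spatial, self.kernel, self.stride, self.dilation):
            if self.padding == "same":
                p0, p1, o = _same_pad(n, k, s, d)
            else:
                p0, p1, o = 0, 0, _valid_out(n, k, s, d)
            pads.append((p0, p1))
            outs.append(o)
        return pads, tuple(outs)

    def output_shape(self, in_shape):
        c, *spatial = in_shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {c}")
        _, outs = self._pads_and_out(spatial)
        return (self.out_channels, *outs)

    @property
    def _use_fft(self):
        return _FFTConvPath.applicable(self.stride, self.padding, self.kernel, self.dilation)

    def forward(self, x, training=False):
        if self._use_fft:
            cache = {} if training else None
            y = _FFTConvPath.forward(
                x, self.weight.value,
                self.bias.value if self.bias is not None else None,
                self.dilation, cache_out=cache,
            )
            if training:
                self._cache = ("fft", cache)
            return y
        pads, outs = self._pads_and_out(x.shape[2:])
        xp = np.pad(x, [(0, 0), (0, 0), *pads])
        y = _conv3d_forward(
            xp, self.weight.value,
            self.bias.value if self.bias is not None else None,
            self.stride, self.dilation, outs,
        )
        if training:
            self._cache = ("direct", (xp, pads, x.shape))
        return y

    def backward(self, grad):
        kind, payload = self._cache
        if kind == "fft":
            dx, dw, db = _FFTConvPath.backward(payload, self.weight.value, grad, self.dilation)
            self.weight.grad += dw
            if self.bias is not None:
                self.bias.grad += db
            return dx
        xp, pads, x_shape = payload
        dxp, dw, db = _conv3d_backward(xp, self.weight.value, grad, self.stride, self.dilation)
        self.weight.grad += dw
        if self.bias is not None:
            self.bias.grad += db
        sl = tuple(
            slice(p0, p0 + n) for (p0, _), n in zip(pads, x_shape[2:])
        )
        return dxp[:, :, sl[0], sl[1], sl[2]]


class ConvTranspose3d(Layer):
    """Transposed 3D convolution with an explicit target output size.

    Implemented as zero-interleaving by the stride followed by a full
    correlation with the flipped kernel, then a center crop to the target
    size (the extra trailing sample is cropped from the trailing side).
    """

    def __init__(self, in_channels, out_channels, kernel, stride, out_size, bias=True, rng=None):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = _triple(kernel)
        self.stride = _triple(stride)
        self.out_size = _triple(out_size)
        rng = rng or np.random.default_rng()
        fan_in = in_channels * int(np.prod(self.kernel))
        limit = np.sqrt(6.0 / max(fan_in, 1))
        # weight convention (C_in, C_out, kd, kh, kw), as in the major frameworks
        self.weight = Parameter(
            rng.uniform(-limit, limit, size=(in_channels, out_channels, *self.kernel))
        )
        self.bias = Parameter(np.zeros(out_channels), decay=False) if bias else None
        self._cache = None

    def parameters(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def _geometry(self, spatial):
        stuffed = tuple((n - 1) * s + 1 for n, s in zip(spatial, self.stride))
        full = tuple(m + k - 1 for m, k in zip(stuffed, self.kernel))
        crops = []
        for f, t in zip(full, self.out_size):
            excess = f - t
            if excess < 0:
                raise ValueError(
                    f"target size {t} exceeds full transposed output {f}"
                )
            crops.append((excess // 2, excess - excess // 2))
        return stuffed, full, crops

    def output_shape(self, in_shape):
        c, *spatial = in_shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {c}")
        self._geometry(spatial)
        return (self.out_channels, *self.out_size)

    def _flipped_weight(self):
        # (O, C, taps) kernel for the equivalent forward correlation
        return np.ascontiguousarray(
            self.weight.value[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
        )

    def forward(self, x, training=False):
        if self.stride == (1, 1, 1):
            return self._forward_fft(x, training)
        B, C = x.shape[:2]
        spatial = x.shape[2:]
        stuffed, full, crops = self._geometry(spatial)
        xs = np.zeros((B, C, *stuffed), dtype=np.float32)
        xs[:, :, :: self.stride[0], :: self.stride[1], :: self.stride[2]] = x
        pads = [(k - 1, k - 1) for k in self.kernel]
        xp = np.pad(xs, [(0, 0), (0, 0), *pads])
        y = _conv3d_forward(xp, self._flipped_weight(), None, (1, 1, 1), (1, 1, 1), full)
        sl = tuple(slice(c0, f - c1) for (c0, c1), f in zip(crops, full))
        y = y[:, :, sl[0], sl[1], sl[2]]
        if self.bias is not None:
            y = y + self.bias.value.reshape(1, -1, 1, 1, 1)
        if training:
            self._cache = ("direct", (xp, spatial, stuffed, full, crops))
        return np.ascontiguousarray(y)

    def _forward_fft(self, x, training):
        """Stride-1 case: a full linear convolution with the kernel, spectrally."""
        n = x.shape[2:]
        _, full, crops = self._geometry(n)
        s = _fft_shape(full)
        axes = (-3, -2, -1)
        xh = _sfft.rfftn(x, s, axes=axes)
        wh = _sfft.rfftn(self.weight.value, s, axes=axes)  # (C, O, taps)
        yh = np.einsum("bcdhw,codhw->bodhw", xh, wh)
        y_full = _sfft.irfftn(yh, s, axes=axes)
        sl = tuple(slice(c0, f - c1) for (c0, c1), f in zip(crops, full))
        y = np.ascontiguousarray(y_full[:, :, sl[0], sl[1], sl[2]]).astype(np.float32)
        if self.bias is not None:
            y += self.bias.value.reshape(1, -1, 1, 1, 1)
        if training:
            self._cache = ("fft", (xh, s, n, crops, full))
        return y

    def _backward_fft(self, grad, payload):
        xh, s, n, crops, full = payload
        axes = (-3, -2, -1)
        gfull = np.zeros((grad.shape[0], self.out_channels, *s), dtype=np.float32)
        sl = tuple(slice(c0, f - c1) for (c0, c1), f in zip(crops, full))
        gfull[:, :, sl[0], sl[1], sl[2]] = grad
        gh = _sfft.rfftn(gfull, s, axes=axes)
        wh = _sfft.rfftn(self.weight.value, s, axes=axes)
        dxh = np.einsum("bodhw,codhw->bcdhw", gh, np.conj(wh))
        dx = _sfft.irfftn(dxh, s, axes=axes)[:, :, : n[0], : n[1], : n[2]]
        dwh = np.einsum("bcdhw,bodhw->codhw", np.conj(xh), gh)
        dw = _sfft.irfftn(dwh, s, axes=axes)[:, :, : self.kernel[0], : self.kernel[1], : self.kernel[2]]
        self.weight.grad += dw.astype(np.float32)
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=(0, 2, 3, 4))
        return np.ascontiguousarray(dx.astype(np.float32))

    def backward(self, grad):
        kind, payload = self._cache
        if kind == "fft":
            return self._backward_fft(grad, payload)
        xp, spatial, stuffed, full, crops = payload
        g_full = np.zeros((grad.shape[0], self.out_channels, *full), dtype=np.float32)
        sl = tuple(slice(c0, f - c1) for (c0, c1), f in zip(crops, full))
        g_full[:, :, sl[0], sl[1], sl[2]] = grad
        dxp, dwf, _ = _conv3d_backward(xp, self._flipped_weight(), g_full, (1, 1, 1), (1, 1, 1))
        # map flipped-correlation weight grad back to the transpose layout
        self.weight.grad += dwf[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=(0, 2, 3, 4))
        pads = [(k - 1, k - 1) for k in self.kernel]
        slp = tuple(slice(p0, p0 + m) for (p0, _), m in zip(pads, stuffed))
        dxs = dxp[:, :, slp[0], slp[1], slp[2]]
        return np.ascontiguousarray(
            dxs[:, :, :: self.stride[0], :: self.stride[1], :: self.stride[2]]
        )


class BatchNorm3d(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, channels, eps=1e-5, momentum=0.9):
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(channels), decay=False)
        self.beta = Parameter(np.zeros(channels), decay=False)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache = None

    def parameters(self):
        return [self.gamma, self.beta]

    def forward(self, x, training=False):
        axes = (0, 2, 3, 4)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps).astype(np.float32)
        xhat = (x - mean.reshape(1, -1, 1, 1, 1)) / std.reshape(1, -1, 1, 1, 1)
        if training:
            self._cache = (xhat.astype(np.float32), std)
        return (self.gamma.value.reshape(1, -1, 1, 1, 1) * xhat
                + self.beta.value.reshape(1, -1, 1, 1, 1)).astype(np.float32)

    def backward(self, grad):
        xhat, std = self._cache
        axes = (0, 2, 3, 4)
        n = grad.shape[0] * grad.shape[2] * grad.shape[3] * grad.shape[4]
        dgamma = (grad * xhat).sum(axis=axes)
        dbeta = grad.sum(axis=axes)
        self.gamma.grad += dgamma
        self.beta.grad += dbeta
        g = self.gamma.value.reshape(1, -1, 1, 1, 1)
        mean_g = (dbeta / n).reshape(1, -1, 1, 1, 1)
        mean_gx = (dgamma / n).reshape(1, -1, 1, 1, 1)
        return (g / std.reshape(1, -1, 1, 1, 1)) * (grad - mean_g - xhat * mean_gx)


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x, training=False):
        y = np.maximum(x, 0.0)
        if training:
            self._mask = x > 0
        return y

    def backward(self, grad):
        return grad * self._mask


class MaxNorm(Layer):
    """Divide each sample by its maximum so the peak voxel equals 1.

    Samples whose maximum does not exceed ``eps`` pass through unchanged
    (an all-nonpositive output carries no usable scale).
    """

    def __init__(self, eps=1e-12):
        self.eps = eps
        self._cache = None

    def forward(self, x, training=False):
        B = x.shape[0]
        flat = x.reshape(B, -1)
        idx = np.argmax(flat, axis=1)
        m = flat[np.arange(B), idx]
        active = m > self.eps
        scale = np.where(active, m, 1.0).astype(np.float32)
        y = x / scale.reshape(B, *([1] * (x.ndim - 1)))
        if training:
            self._cache = (x, idx, scale, active)
        return y

    def backward(self, grad):
        x, idx, scale, active = self._cache
        B = x.shape[0]
        s = scale.reshape(B, *([1] * (x.ndim - 1)))
        dx = grad / s
        # contribution through the (sub)gradient of the max itself
        gx = (grad * x).reshape(B, -1).sum(axis=1)
        corr = np.where(active, gx / scale**2, 0.0)
        dflat = dx.reshape(B, -1)
        dflat[np.arange(B), idx] -= corr.astype(np.float32)
        return dflat.reshape(x.shape)


class DenseBlock(Layer):
    """Two equal-width convolutions with batch norm and additive skips.

    x -> conv1 -> BN1 -> (+x) -> ReLU -> conv2 -> BN2 -> (+x) -> ReLU

    Addition (rather than concatenation) requires the channel count to stay
    constant through the block; dilation applies to the time (depth) axis.
    """

    def __init__(self, channels, kernel, dilation, rng=None):
        self.channels = channels
        self.conv1 = Conv3d(channels, channels, kernel, dilation=dilation, rng=rng)
        self.bn1 = BatchNorm3d(channels)
        self.relu1 = ReLU()
        self.conv2 = Conv3d(channels, channels, kernel, dilation=dilation, rng=rng)
        self.bn2 = BatchNorm3d(channels)
        self.relu2 = ReLU()

    def parameters(self):
        return (self.conv1.parameters() + self.bn1.parameters()
                + self.conv2.parameters() + self.bn2.parameters())

    @property
    def convolutions(self):
        return [self.conv1, self.conv2]

    def output_shape(self, in_shape):
        if in_shape[0] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {in_shape[0]}")
        return in_shape

    def forward(self, x, training=False):
        h1 = self.bn1.forward(self.conv1.forward(x, training), training) + x
        a1 = self.relu1.forward(h1, training)
        h2 = self.bn2.forward(self.conv2.forward(a1, training), training) + x
        return self.relu2.forward(h2, training)

    def backward(self, grad):
        g2 = self.relu2.backward(grad)
        dskip2 = g2  # straight-through to the block input
        da1 = self.conv2.backward(self.bn2.backward(g2))
        g1 = self.relu1.backward(da1)
        dskip1 = g1
        dx = self.conv1.backward(self.bn1.backward(g1))
        return dx + dskip1 + dskip2
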