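"""Neural-network primitives with hand-written vector-Jacobian products.

Feature maps are channels-last, (N, H, W, C): pointwise convolutions are
then plain GEMMs on contiguous memory and per-channel broadcasting is
trailing-axis broadcasting.  All convolutions in the segmentation network
have stride 1, so convolution is a sum over kernel offsets of shifted
GEMMs — memory-light compared to a monolithic im2col buffer.  Max pooling
uses a fixed 2x2 window with stride 2 and returns the within-window argmax
indices that max-unpooling consumes.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from .autograd import Tensor

_GELU_C = np.float32(np.sqrt(2.0 / np.pi))
_GELU_A = np.float32(0.044715)


# ---------------------------------------------------------------------------
# convolution (stride 1)
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None,
           padding: int, groups: int = 1) -> Tensor:
    """2-D convolution with stride 1 on (N, H, W, C) maps.

    ``weight`` keeps the conventional (C_out, C_in/groups, kh, kw) shape;
    ``groups`` is either 1 (dense) or the channel count (depthwise).
    """
    n, h, w, cin = x.shape
    cout, cin_g, kh, kw = weight.shape
    if groups == 1 and cin_g != cin:
        raise ValueError(f"weight expects {cin_g} input channels, got {cin}")
    if groups > 1 and (groups != cin or cout != cin or cin_g != 1):
        raise ValueError("grouped convolution is supported only as depthwise")

    p = padding
    xp = np.pad(x.data, ((0, 0), (p, p), (p, p), (0, 0))) if p else x.data
    ho, wo = h + 2 * p - kh + 1, w + 2 * p - kw + 1

    wd = weight.data
    # im2col pays off while the column buffer is small (one big GEMM beats
    # kh*kw small strided ones); above the cutoff fall back to shifted GEMMs
    use_cols = groups == 1 and kh * kw > 1 \
        and n * ho * wo * cin * kh * kw <= 33_000_000
    cols = None
    if groups == 1:
        if kh == 1 and kw == 1 and not p:
            out_data = x.data.reshape(-1, cin) @ wd[:, :, 0, 0].T
            out_data = out_data.reshape(n, ho, wo, cout)
        elif use_cols:
            view = np.lib.stride_tricks.sliding_window_view(
                xp, (kh, kw), axis=(1, 2))         # (N, ho, wo, C, kh, kw)
            cols = np.ascontiguousarray(view).reshape(-1, cin * kh * kw)
            wmat = wd.reshape(cout, cin * kh * kw)
            out_data = (cols @ wmat.T).reshape(n, ho, wo, cout)
        else:
            out_data = np.zeros((n, ho, wo, cout), dtype=np.float32)
            for i in range(kh):
                for j in range(kw):
                    xs = xp[:, i:i + ho, j:j + wo, :]
                    out_data += xs @ wd[:, :, i, j].T
    else:  # depthwise: weight[:, 0, i, j] broadcasts along the channel axis
        out_data = np.zeros((n, ho, wo, cout), dtype=np.float32)
        for i in range(kh):
            for j in range(kw):
                out_data += xp[:, i:i + ho, j:j + wo, :] * wd[:, 0, i, j]
    if bias is not None:
        out_data += bias.data

    def backward(g):
        g = np.ascontiguousarray(g)
        if bias is not None:
            bias._accumulate(g.sum(axis=(0, 1, 2)))
        need_x = x.requires_grad
        gw = np.zeros_like(wd)
        if groups == 1:
            if kh == 1 and kw == 1 and not p:
                gw[:, :, 0, 0] = g.reshape(-1, cout).T @ x.data.reshape(-1, cin)
                weight._accumulate(gw)
                if need_x:
                    gx = g.reshape(-1, cout) @ wd[:, :, 0, 0]
                    x._accumulate(gx.reshape(x.data.shape))
                return
            if cols is not None:
                gmat = g.reshape(-1, cout)
                gw[...] = (gmat.T @ cols).reshape(wd.shape)
                if need_x:
                    gxp = np.zeros_like(xp)
                    gcols = (gmat @ wd.reshape(cout, -1)).reshape(
                        n, ho, wo, cin, kh, kw)
                    for i in range(kh):
                        for j in range(kw):
                            gxp[:, i:i + ho, j:j + wo, :] += \
                                gcols[:, :, :, :, i, j]
                weight._accumulate(gw)
                if need_x:
                    x._accumulate(gxp[:, p:p + h, p:p + w, :] if p else gxp)
                return
            gxp = np.zeros_like(xp) if need_x else None
            for i in range(kh):
                for j in range(kw):
                    xs = xp[:, i:i + ho, j:j + wo, :]
                    gw[:, :, i, j] = np.tensordot(
                        g, xs, axes=([0, 1, 2], [0, 1, 2]))
                    if need_x:
                        gxp[:, i:i + ho, j:j + wo, :] += g @ wd[:, :, i, j]
        else:
            gxp = np.zeros_like(xp) if need_x else None
            for i in range(kh):
                for j in range(kw):
                    xs = xp[:, i:i + ho, j:j + wo, :]
                    gw[:, 0, i, j] = (g * xs).sum(axis=(0, 1, 2))
                    if need_x:
                        gxp[:, i:i + ho, j:j + wo, :] += g * wd[:, 0, i, j]
        weight._accumulate(gw)
        if need_x:
            x._accumulate(gxp[:, p:p + h, p:p + w, :] if p else gxp)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor._result(out_data, parents, backward)


# ---------------------------------------------------------------------------
# batch normalisation
# ---------------------------------------------------------------------------

def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor,
                 running_mean: np.ndarray, running_var: np.ndarray,
                 training: bool, momentum: float = 0.1,
                 eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalisation over (N, H, W).

    In training mode batch statistics are used and the running statistics
    are updated in place as ``running = (1 - momentum) * running +
    momentum * batch`` (running variance uses the unbiased estimate).
    """
    xd = x.data
    m = xd.shape[0] * xd.shape[1] * xd.shape[2]
    if training:
        mu = xd.mean(axis=(0, 1, 2))
        var = xd.var(axis=(0, 1, 2))
        unbiased = var * (m / max(m - 1, 1))
        running_mean *= (1.0 - momentum)
        running_mean += momentum * mu
        running_var *= (1.0 - momentum)
        running_var += momentum * unbiased
    else:
        mu, var = running_mean, running_var
    inv_std = (1.0 / np.sqrt(var + eps)).astype(np.float32)
    xhat = (xd - mu) * inv_std
    out_data = xhat * gamma.data + beta.data

    def backward(g):
        gamma._accumulate((g * xhat).sum(axis=(0, 1, 2)))
        beta._accumulate(g.sum(axis=(0, 1, 2)))
        if not x.requires_grad:
            return
        gxhat = g * gamma.data
        if training:
            # standard batch-norm backward through the batch statistics
            s1 = gxhat.sum(axis=(0, 1, 2))
            s2 = (gxhat * xhat).sum(axis=(0, 1, 2))
            gx = (gxhat - (s1 + xhat * s2) / m) * inv_std
        else:
            gx = gxhat * inv_std
        x._accumulate(gx)

    return Tensor._result(out_data.astype(np.float32, copy=False),
                          (x, gamma, beta), backward)


# ---------------------------------------------------------------------------
# activations
# ---------------------------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    out_data = np.maximum(x.data, 0.0)

    def backward(g):
        x._accumulate(g * (x.data > 0))

    return Tensor._result(out_data, (x,), backward)


def gelu(x: Tensor) -> Tensor:
    """Gaussian error linear unit (tanh approximation)."""
    xd = x.data
    u = _GELU_C * (xd + _GELU_A * xd * xd * xd)
    t = np.tanh(u)
    out_data = 0.5 * xd * (1.0 + t)

    def backward(g):
        du = _GELU_C * (1.0 + 3.0 * _GELU_A * xd * xd)
        grad = 0.5 * (1.0 + t) + 0.5 * xd * (1.0 - t * t) * du
        x._accumulate(g * grad)

    return Tensor._result(out_data, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    # clamp into the open interval: float32 expit saturates to exactly 0/1
    # for |x| > ~17, which would break the strict (0, 1) output contract
    s = expit(x.data).astype(np.float32, copy=False)
    s = np.clip(s, 1e-7, 1.0 - 1e-7)

    def backward(g):
        x._accumulate(g * s * (1.0 - s))

    return Tensor._result(s, (x,), backward)


# ---------------------------------------------------------------------------
# pooling / unpooling
# ---------------------------------------------------------------------------

def _windows(xd: np.ndarray) -> np.ndarray:
    """(N, H, W, C) -> (N, H/2, W/2, 4, C) non-overlapping 2x2 windows."""
    n, h, w, c = xd.shape
    return xd.reshape(n, h // 2, 2, w // 2, 2, c) \
             .transpose(0, 1, 3, 2, 4, 5).reshape(n, h // 2, w // 2, 4, c)


def _unwindow(win: np.ndarray) -> np.ndarray:
    n, ho, wo, _, c = win.shape
    return win.reshape(n, ho, wo, 2, 2, c).transpose(0, 1, 3, 2, 4, 5) \
              .reshape(n, ho * 2, wo * 2, c)


def max_pool2d(x: Tensor) -> tuple[Tensor, np.ndarray]:
    """2x2 max pooling with stride 2 on (N, H, W, C) maps.

    Returns the pooled tensor and an int8 index array of the same shape
    holding, for each output position, the argmax within its 2x2 window
    (row-major: 0=top-left, 1=top-right, 2=bottom-left, 3=bottom-right).
    """
    n, h, w, c = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"max_pool2d requires even spatial dims, got {h}x{w}")
    win = _windows(x.data)
    idx = win.argmax(axis=3)
    out_data = np.take_along_axis(win, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]
    idx8 = idx.astype(np.int8)

    def backward(g):
        gw = np.zeros_like(win)
        np.put_along_axis(gw, idx[:, :, :, None, :], g[:, :, :, None, :], axis=3)
        x._accumulate(_unwindow(gw))

    return Tensor._result(np.ascontiguousarray(out_data), (x,), backward), idx8


def max_unpool2d(x: Tensor, indices: np.ndarray) -> Tensor:
    """Scatter each value to the argmax position recorded by its pool."""
    if indices.shape != x.shape:
        raise ValueError(
            f"indices shape {indices.shape} does not match input {x.shape}")
    idx = indices.astype(np.int64)[:, :, :, None, :]
    win = np.zeros(x.shape[:3] + (4, x.shape[3]), dtype=np.float32)
    np.put_along_axis(win, idx, x.data[:, :, :, None, :], axis=3)
    out_data = _unwindow(win)

    def backward(g):
        gw = _windows(np.ascontiguousarray(g))
        x._accumulate(np.take_along_axis(gw, idx, axis=3)[:, :, :, 0, :])

    return Tensor._result(out_data, (x,), backward)
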