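"""Structured volumetric operations (convolution, padding, pooling, resizing).

All functions take and return :class:`~vangan.nn.tensor.Tensor` objects with
channels-last layout ``(N, D, H, W, C)`` and are differentiable.  The 3-D
convolution uses a shift-and-matmul strategy (one small GEMM per kernel
offset) which avoids materialising im2col buffers and is markedly faster
than window extraction for the small channel counts used here.
"""
from __future__ import annotations

from typing import Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor, _ensure, _node, minimum

__all__ = ["pad3d", "conv3d", "instance_norm", "upsample_nearest3d", "pool1d",
           "max_pool3d", "soft_erode", "soft_dilate", "soft_open"]

SPATIAL_AXES = (1, 2, 3)


def _as_triple(v) -> Tuple[int, int, int]:
    if isinstance(v, (tuple, list)):
        if len(v) != 3:
            raise ValueError("expected a scalar or length-3 sequence")
        return tuple(int(x) for x in v)
    return (int(v),) * 3


def _reflect_indices(n: int, lo: int, hi: int) -> np.ndarray:
    """Source index for each position of an axis reflect-padded by (lo, hi)."""
    idx = np.arange(-lo, n + hi)
    if n == 1:
        return np.zeros_like(idx)
    period = 2 * (n - 1)
    idx = np.abs(idx) % period
    return np.where(idx >= n, period - idx, idx)


def pad3d(x: Tensor, pad: Sequence[Tuple[int, int]], mode: str = "reflect",
          value: float = 0.0) -> Tensor:
    """Pad the three spatial axes of ``x``.

    ``pad`` is ``[(d_lo, d_hi), (h_lo, h_hi), (w_lo, w_hi)]``.
    """
    x = _ensure(x)
    (dl, dh), (hl, hh), (wl, wh) = [(int(a), int(b)) for a, b in pad]
    width = ((0, 0), (dl, dh), (hl, hh), (wl, wh), (0, 0))
    if mode == "reflect":
        data = np.pad(x.data, width, mode="reflect")
    elif mode == "constant":
        data = np.pad(x.data, width, mode="constant", constant_values=value)
    else:
        raise ValueError(f"unsupported padding mode {mode!r}")
    out = _node(data, (x,))
    if out.requires_grad:
        spatial = x.data.shape[1:4]

        def bw(g):
            if mode == "constant":
                return (g[:, dl:dl + spatial[0], hl:hl + spatial[1],
                          wl:wl + spatial[2], :],)
            for axis, (lo, hi) in zip(SPATIAL_AXES,
                                      ((dl, dh), (hl, hh), (wl, wh))):
                if lo == 0 and hi == 0:
                    continue
                n = spatial[axis - 1]
                idx = _reflect_indices(n, lo, hi)
                gm = np.moveaxis(g, axis, 0)
                folded = gm[lo:lo + n].copy()
                # fold the few reflected border rows back onto their sources
                for j in list(range(lo)) + list(range(lo + n, lo + n + hi)):
                    folded[idx[j]] += gm[j]
                g = np.moveaxis(folded, 0, axis)
            return (g,)

        out._backward = bw
    return out


def conv3d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride=1) -> Tensor:
    """Valid 3-D cross-correlation.

    ``x``: (N, D, H, W, C); ``weight``: (kd, kh, kw, C, F); output
    (N, Do, Ho, Wo, F) with ``Do = (D - kd) // sd + 1`` etc.
    """
    x, weight = _ensure(x), _ensure(weight)
    N, D, H, W, C = x.data.shape
    kd, kh, kw, Cw, Fc = weight.data.shape
    if Cw != C:
        raise ValueError(f"channel mismatch: input {C}, weight {Cw}")
    sd, sh, sw = _as_triple(stride)
    Do = (D - kd) // sd + 1
    Ho = (H - kh) // sh + 1
    Wo = (W - kw) // sw + 1
    if min(Do, Ho, Wo) < 1:
        raise ValueError("kernel larger than input")
    xd, wd = x.data, weight.data
    out_data = np.zeros((N, Do, Ho, Wo, Fc), dtype=np.result_type(xd, wd))
    for i in range(kd):
        for j in range(kh):
            for k in range(kw):
                xo = xd[:, i:i + sd * Do:sd, j:j + sh * Ho:sh,
                        k:k + sw * Wo:sw, :]
                out_data += np.matmul(xo, wd[i, j, k])
    if bias is not None:
        out_data += bias.data
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = _node(out_data, parents)
    if out.requires_grad:
        def bw(g):
            gx = None
            if x.requires_grad:
                gx = np.zeros_like(xd, dtype=g.dtype)
                for i in range(kd):
                    for j in range(kh):
                        for k in range(kw):
                            gx[:, i:i + sd * Do:sd, j:j + sh * Ho:sh,
                               k:k + sw * Wo:sw, :] += np.matmul(
                                   g, wd[i, j, k].T)
            gw = None
            if weight.requires_grad:
                gw = np.empty_like(wd, dtype=g.dtype)
                gflat = np.ascontiguousarray(g).reshape(-1, Fc)
                buf = np.empty((N, Do, Ho, Wo, C), dtype=xd.dtype)
                for i in range(kd):
                    for j in range(kh):
                        for k in range(kw):
                            np.copyto(buf, xd[:, i:i + sd * Do:sd,
                                              j:j + sh * Ho:sh,
                                              k:k + sw * Wo:sw, :])
                            gw[i, j, k] = buf.reshape(-1, C).T @ gflat
            if bias is None:
                return (gx, gw)
            gb = g.sum(axis=(0, 1, 2, 3)) if bias.requires_grad else None
            return (gx, gw, gb)

        out._backward = bw
    return out


def instance_norm(x: Tensor, gamma: Tensor | None = None,
                  beta: Tensor | None = None, eps: float = 1e-5) -> Tensor:
    """Fused per-sample, per-channel spatial normalisation.

    A single graph node with a hand-derived backward pass; equivalent to the
    composite mean/variance formulation but with far fewer temporaries.
    """
    x = _ensure(x)
    mu = x.data.mean(axis=(1, 2, 3), keepdims=True)
    xc = x.data - mu
    var = np.mean(xc * xc, axis=(1, 2, 3), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    if gamma is not None:
        data = xhat * gamma.data + beta.data
        parents = (x, gamma, beta)
    else:
        data = xhat
        parents = (x,)
    out = _node(data, parents)
    if out.requires_grad:
        m = float(np.prod(x.data.shape[1:4]))

        def bw(g):
            gy = g * gamma.data if gamma is not None else g
            mean_g = gy.mean(axis=(1, 2, 3), keepdims=True)
            mean_gx = np.mean(gy * xhat, axis=(1, 2, 3), keepdims=True)
            gx = inv * (gy - mean_g - xhat * mean_gx)
            if gamma is None:
                return (gx,)
            gg = (g * xhat).sum(axis=(0, 1, 2, 3)) \
                if gamma.requires_grad else None
            gb = g.sum(axis=(0, 1, 2, 3)) if beta.requires_grad else None
            return (gx, gg, gb)

        out._backward = bw
    return out


def upsample_nearest3d(x: Tensor, factor: int = 2) -> Tensor:
    x = _ensure(x)
    f = int(factor)
    data = x.data.repeat(f, axis=1).repeat(f, axis=2).repeat(f, axis=3)
    out = _node(data, (x,))
    if out.requires_grad:
        N, D, H, W, C = x.data.shape

        def bw(g):
            return (g.reshape(N, D, f, H, f, W, f, C).sum(axis=(2, 4, 6)),)

        out._backward = bw
    return out


def pool1d(x: Tensor, axis: int, size: int = 3, mode: str = "max") -> Tensor:
    """Stride-1 same-size max/min pooling along one spatial axis.

    Out-of-bounds positions are ignored (padded with the identity element
    of the pooling operation), matching padded pooling in the mainstream
    frameworks.
    """
    x = _ensure(x)
    if size % 2 != 1:
        raise ValueError("pool size must be odd")
    p = size // 2
    fill = -np.inf if mode == "max" else np.inf
    xm = np.moveaxis(x.data, axis, -1)
    lead = xm.shape[:-1]
    L = xm.shape[-1]
    padded = np.concatenate([
        np.full(lead + (p,), fill, dtype=xm.dtype), xm,
        np.full(lead + (p,), fill, dtype=xm.dtype)], axis=-1)
    win = sliding_window_view(padded, size, axis=-1)  # lead + (L, size)
    idx = win.argmax(-1) if mode == "max" else win.argmin(-1)
    pooled = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
    out = _node(np.moveaxis(pooled, -1, axis), (x,))
    if out.requires_grad:
        def bw(g):
            gm = np.moveaxis(g, axis, -1)
            M = int(np.prod(lead)) if lead else 1
            gpad = np.zeros((M, L + 2 * p), dtype=g.dtype)
            pos = (np.arange(L)[None, :] + idx.reshape(M, L))
            np.add.at(gpad, (np.repeat(np.arange(M)[:, None], L, axis=1), pos),
                      gm.reshape(M, L))
            core = gpad[:, p:p + L].reshape(lead + (L,))
            return (np.moveaxis(core, -1, axis),)

        out._backward = bw
    return out


def max_pool3d(x: Tensor, size: int = 3) -> Tensor:
    """Cube max pooling (stride 1, same size) as three separable 1-D pools."""
    out = x
    for axis in SPATIAL_AXES:
        out = pool1d(out, axis=axis, size=size, mode="max")
    return out


def soft_erode(x: Tensor) -> Tensor:
    """Differentiable 3-D erosion: min over the three axis-aligned 1-D pools."""
    e = pool1d(x, axis=1, mode="min")
    e = minimum(e, pool1d(x, axis=2, mode="min"))
    return minimum(e, pool1d(x, axis=3, mode="min"))


def soft_dilate(x: Tensor) -> Tensor:
    return max_pool3d(x, size=3)


def soft_open(x: Tensor) -> Tensor:
    return soft_dilate(soft_erode(x))
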