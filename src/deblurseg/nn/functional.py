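"""Structured NN primitives: convolutions, pooling, resampling.

Forward passes are vectorized with ``sliding_window_view``/``einsum``; each
backward pass is hand-derived and checked against finite differences in the
test suite.  Data layout is NCHW.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor

__all__ = [
    "conv2d",
    "deform_conv2d",
    "max_pool2d",
    "bilinear_upsample2x",
    "pixel_shuffle",
    "pixel_unshuffle",
]


def _windows(xp: np.ndarray, kh: int, kw: int, sh: int, sw: int) -> np.ndarray:
    """(N,C,Hp,Wp) -> (N,C,OH,OW,kh,kw) strided windows."""
    w = sliding_window_view(xp, (kh, kw), axis=(2, 3))
    return w[:, :, ::sh, ::sw]


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0, groups: int = 1) -> Tensor:
    """Grouped 2-D convolution (cross-correlation, as is conventional).

    weight: (O, Ci/groups, kh, kw).  groups == Ci gives a depthwise conv.
    """
    N, Ci, H, W = x.data.shape
    O, Cg, kh, kw = weight.data.shape
    if Ci != Cg * groups:
        raise ValueError(f"channel mismatch: input {Ci}, weight expects {Cg * groups}")
    if O % groups:
        raise ValueError("output channels not divisible by groups")
    sh = sw = int(stride)
    p = int(padding)
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    Hp, Wp = xp.shape[2], xp.shape[3]
    OH = (Hp - kh) // sh + 1
    OW = (Wp - kw) // sw + 1
    wins = _windows(xp, kh, kw, sh, sw)                       # N,Ci,OH,OW,kh,kw
    g = groups
    Og = O // g
    K = Cg * kh * kw
    P = OH * OW
    # materialize the im2col buffer once; forward and both backward
    # passes reuse it as plain matmuls
    cols = np.ascontiguousarray(wins.transpose(0, 1, 4, 5, 2, 3)) \
        .reshape(N, g, K, P)
    w2 = weight.data.reshape(g, Og, K)
    out = np.matmul(w2, cols).reshape(N, O, OH, OW)
    if bias is not None:
        out = out + bias.data.reshape(1, O, 1, 1)

    def back_w(go):
        go2 = go.reshape(N, g, Og, P)
        gw = np.matmul(go2, cols.transpose(0, 1, 3, 2)).sum(axis=0)
        return gw.reshape(O, Cg, kh, kw)

    def back_x(go):
        if sh == 1 and sw == 1:
            # full correlation of the padded out-grad with the flipped kernel
            gop = np.pad(go.reshape(N, g, Og, OH, OW),
                         ((0, 0), (0, 0), (0, 0),
                          (kh - 1, kh - 1), (kw - 1, kw - 1)))
            gwins = sliding_window_view(gop, (kh, kw), axis=(3, 4))
            gocols = np.ascontiguousarray(gwins.transpose(0, 1, 2, 5, 6, 3, 4)) \
                .reshape(N, g, Og * kh * kw, Hp * Wp)
            w_flip = weight.data.reshape(g, Og, Cg, kh, kw)[:, :, :, ::-1, ::-1]
            wf2 = np.ascontiguousarray(w_flip.transpose(0, 2, 1, 3, 4)) \
                .reshape(g, Cg, Og * kh * kw)
            gxp = np.matmul(wf2, gocols).reshape(N, Ci, Hp, Wp)
        else:
            go_g = go.reshape(N, g, Og, OH, OW)
            w_g = weight.data.reshape(g, Og, Cg, kh, kw)
            gxp = np.zeros((N, Ci, Hp, Wp))
            gxp_g = gxp.reshape(N, g, Cg, Hp, Wp)
            for i in range(kh):
                for j in range(kw):
                    contrib = np.einsum("goc,ngohw->ngchw", w_g[:, :, :, i, j],
                                        go_g, optimize=True)
                    gxp_g[:, :, :, i:i + sh * OH:sh, j:j + sw * OW:sw] += contrib
        if p:
            return gxp[:, :, p:Hp - p, p:Wp - p]
        return gxp

    parents = [(x, back_x), (weight, back_w)]
    if bias is not None:
        parents.append((bias, lambda go: go.sum(axis=(0, 2, 3))))
    return Tensor._make(out, parents)


def _bilinear_gather(x: np.ndarray, py: np.ndarray, px: np.ndarray):
    """Sample x (N,C,H,W) at continuous positions py/px (N,K,H,W).

    Out-of-image samples contribute zero.  Returns (value, corner cache)
    where value has shape (N,C,K,H,W).
    """
    N, C, H, W = x.shape
    y0 = np.floor(py).astype(np.int64)
    x0 = np.floor(px).astype(np.int64)
    fy = py - y0
    fx = px - x0
    n_idx = np.arange(N)[:, None, None, None]
    xf = x.transpose(0, 2, 3, 1).reshape(N, H * W, C)       # gather-friendly
    val = 0.0
    cache = []
    for dy, wy, dwy in ((0, 1.0 - fy, -1.0), (1, fy, 1.0)):
        for dx, wx, dwx in ((0, 1.0 - fx, -1.0), (1, fx, 1.0)):
            yc = y0 + dy
            xc = x0 + dx
            valid = (yc >= 0) & (yc < H) & (xc >= 0) & (xc < W)
            yv = np.clip(yc, 0, H - 1)
            xv = np.clip(xc, 0, W - 1)
            idx = yv * W + xv                                # (N,K,H,W)
            v = xf[n_idx, idx]                               # (N,K,H,W,C)
            w = (wy * wx) * valid                            # (N,K,H,W)
            val = val + w[..., None] * v
            cache.append((idx, valid, v, wy, wx, dwy, dwx))
    # (N,K,H,W,C) -> (N,C,K,H,W)
    return val.transpose(0, 4, 1, 2, 3), cache, n_idx


def deform_conv2d(x: Tensor, offset: Tensor, mask: Tensor,
                  weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Modulated deformable 3x3 convolution, stride 1, padding 1.

    offset: (N, 18, H, W) — per-tap (dy, dx) displacements, interleaved
    [dy0, dx0, dy1, dx1, ...] in row-major tap order.
    mask:   (N, 9, H, W) — per-tap multiplicative modulation.
    weight: (O, C, 3, 3).  Sampling is bilinear; outside the image the
    sampled value is zero (matching zero padding of a standard conv).
    """
    N, C, H, W = x.data.shape
    O = weight.data.shape[0]
    K = 9
    taps = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)]
    gy, gx = np.mgrid[0:H, 0:W].astype(np.float64)
    off = offset.data.reshape(N, K, 2, H, W)
    py = gy[None, None] + np.array([t[0] for t in taps], dtype=np.float64)[None, :, None, None] \
        + off[:, :, 0]
    px = gx[None, None] + np.array([t[1] for t in taps], dtype=np.float64)[None, :, None, None] \
        + off[:, :, 1]
    sampled, cache, n_idx = _bilinear_gather(x.data, py, px)   # (N,C,K,H,W)
    m = mask.data[:, None]                                      # (N,1,K,H,W)
    sampled_m = sampled * m
    wr = weight.data.reshape(O, C, K)
    out = np.einsum("nckhw,ock->nohw", sampled_m, wr, optimize=True)
    if bias is not None:
        out = out + bias.data.reshape(1, O, 1, 1)

    def back_common(go):
        # gradient wrt the modulated samples
        return np.einsum("ock,nohw->nckhw", wr, go, optimize=True)

    def back_w(go):
        gw = np.einsum("nckhw,nohw->ock", sampled_m, go, optimize=True)
        return gw.reshape(O, C, 3, 3)

    def back_mask(go):
        g_sm = back_common(go)
        return (g_sm * sampled).sum(axis=1)

    def back_x(go):
        g_s = back_common(go) * m                              # (N,C,K,H,W)
        g_s_t = g_s.transpose(0, 2, 3, 4, 1)                   # (N,K,H,W,C)
        gxf = np.zeros((N, H * W, C))
        for idx, valid, _v, wy, wx, _dwy, _dwx in cache:
            w = (wy * wx) * valid
            np.add.at(gxf, (n_idx, idx), w[..., None] * g_s_t)
        return gxf.reshape(N, H, W, C).transpose(0, 3, 1, 2)

    def back_offset(go):
        g_s = back_common(go) * m                              # (N,C,K,H,W)
        dval_dpy = 0.0
        dval_dpx = 0.0
        for _idx, valid, v, wy, wx, dwy, dwx in cache:
            vv = v * valid[..., None]                          # (N,K,H,W,C)
            vv = vv.transpose(0, 4, 1, 2, 3)                   # (N,C,K,H,W)
            dval_dpy = dval_dpy + (dwy * wx)[:, None] * vv
            dval_dpx = dval_dpx + (wy * dwx)[:, None] * vv
        g_py = (g_s * dval_dpy).sum(axis=1)                    # (N,K,H,W)
        g_px = (g_s * dval_dpx).sum(axis=1)
        g_off = np.stack([g_py, g_px], axis=2)                 # (N,K,2,H,W)
        return g_off.reshape(N, 2 * K, H, W)

    parents = [(x, back_x), (offset, back_offset), (mask, back_mask),
               (weight, back_w)]
    if bias is not None:
        parents.append((bias, lambda go: go.sum(axis=(0, 2, 3))))
    return Tensor._make(out, parents)


def max_pool2d(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2.  Requires even spatial dims."""
    N, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError("max_pool2d requires even spatial dimensions")
    win = x.data.reshape(N, C, H // 2, 2, W // 2, 2)
    flat = win.transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H // 2, W // 2, 4)
    arg = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def back(go):
        gflat = np.zeros_like(flat)
        np.put_along_axis(gflat, arg[..., None], go[..., None], axis=-1)
        g = gflat.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return g.reshape(N, C, H, W)

    return Tensor._make(out, [(x, back)])


def _up2x_plan(H: int, W: int):
    """Precompute gather indices/weights for a 2x bilinear upsample
    (half-pixel centers, i.e. align_corners=False)."""
    def axis_plan(n):
        pos = (np.arange(2 * n) + 0.5) / 2.0 - 0.5
        i0 = np.floor(pos).astype(np.int64)
        f = pos - i0
        i0c = np.clip(i0, 0, n - 1)
        i1c = np.clip(i0 + 1, 0, n - 1)
        return i0c, i1c, f
    return axis_plan(H), axis_plan(W)


def bilinear_upsample2x(x: Tensor) -> Tensor:
    """Double spatial dims by bilinear interpolation (half-pixel centers)."""
    N, C, H, W = x.data.shape
    (y0, y1, fy), (x0, x1, fx) = _up2x_plan(H, W)
    d = x.data
    top = d[:, :, y0][:, :, :, x0] * ((1 - fy)[:, None] * (1 - fx)[None, :]) \
        + d[:, :, y0][:, :, :, x1] * ((1 - fy)[:, None] * fx[None, :])
    bot = d[:, :, y1][:, :, :, x0] * (fy[:, None] * (1 - fx)[None, :]) \
        + d[:, :, y1][:, :, :, x1] * (fy[:, None] * fx[None, :])
    out = top + bot

    def back(go):
        g = np.zeros((N, C, H, W))
        for yi, wy in ((y0, 1 - fy), (y1, fy)):
            for xi, wx in ((x0, 1 - fx), (x1, fx)):
                contrib = go * (wy[:, None] * wx[None, :])
                # scatter-add along the two axes successively
                tmp = np.zeros((N, C, H, 2 * W))
                np.add.at(tmp, (slice(None), slice(None), yi), contrib)
                np.add.at(g, (slice(None), slice(None), slice(None), xi), tmp)
        return g

    return Tensor._make(out, [(x, back)])


def pixel_shuffle(x: Tensor, r: int = 2) -> Tensor:
    """(N, r^2*C, H, W) -> (N, C, r*H, r*W) channel-to-space rearrangement."""
    N, RC, H, W = x.data.shape
    if RC % (r * r):
        raise ValueError("channels not divisible by r^2")
    C = RC // (r * r)
    out = x.data.reshape(N, C, r, r, H, W).transpose(0, 1, 4, 2, 5, 3) \
        .reshape(N, C, r * H, r * W)

    def back(go):
        return go.reshape(N, C, H, r, W, r).transpose(0, 1, 3, 5, 2, 4) \
            .reshape(N, RC, H, W)

    return Tensor._make(out, [(x, back)])


def pixel_unshuffle(x: Tensor, r: int = 2) -> Tensor:
    """Exact inverse of :func:`pixel_shuffle`."""
    N, C, RH, RW = x.data.shape
    if RH % r or RW % r:
        raise ValueError("spatial dims not divisible by r")
    H, W = RH // r, RW // r
    out = x.data.reshape(N, C, H, r, W, r).transpose(0, 1, 3, 5, 2, 4) \
        .reshape(N, C * r * r, H, W)

    def back(go):
        return go.reshape(N, C, r, r, H, W).transpose(0, 1, 4, 2, 5, 3) \
            .reshape(N, C, RH, RW)

    return Tensor._make(out, [(x, back)])
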