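"""Structured autodiff ops with hand-derived backward passes.

Each op here would be prohibitively slow if composed from elementwise
primitives, so forward and backward are written directly in vectorised
numpy.  Every backward pass is validated against central finite
differences in ``tests/test_nn.py``.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["unfold", "gather_bilinear", "bilinear_upsample", "selective_scan_op"]


def unfold(x: Tensor, kernel: int, stride: int = 1, padding: int = 0) -> Tensor:
    """im2col: (B, C, H, W) -> (B, C*k*k, Ho*Wo) patch matrix."""
    B, C, H, W = x.shape
    k, s, p = kernel, stride, padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)))
    Hp, Wp = H + 2 * p, W + 2 * p
    Ho = (Hp - k) // s + 1
    Wo = (Wp - k) // s + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    win = win[:, :, ::s, ::s]                       # (B, C, Ho, Wo, k, k)
    out_data = np.ascontiguousarray(
        win.transpose(0, 1, 4, 5, 2, 3)
    ).reshape(B, C * k * k, Ho * Wo)

    def backward(g):
        g = g.reshape(B, C, k, k, Ho, Wo)
        gp = np.zeros((B, C, Hp, Wp), dtype=np.float64)
        for a in range(k):
            for b in range(k):
                gp[:, :, a:a + s * Ho:s, b:b + s * Wo:s] += g[:, :, a, b]
        if p:
            gp = gp[:, :, p:-p, p:-p]
        x._accumulate(gp)

    return Tensor._make(out_data, (x,), backward)


def gather_bilinear(feature: Tensor, coords: Tensor) -> Tensor:
    """Bilinearly sample ``feature`` at fractional ``coords`` (zero padded).

    feature: (B, G, Cg, H, W); coords: (B, G, K, Ho, Wo, 2) as (row, col).
    Returns (B, G, K, Cg, Ho, Wo).  Gradients flow to both the feature map
    (scatter of the corner weights) and the coordinates (corner-difference
    rule of bilinear interpolation).
    """
    B, G, Cg, H, W = feature.shape
    _, _, K, Ho, Wo, _ = coords.shape
    r = coords.data[..., 0]                        # (B, G, K, Ho, Wo)
    c = coords.data[..., 1]
    r0 = np.floor(r).astype(np.int64)
    c0 = np.floor(c).astype(np.int64)
    fr = r - r0
    fc = c - c0

    flat = feature.data.reshape(B, G, Cg, H * W)
    M = K * Ho * Wo

    corner_vals = []
    corner_meta = []
    for dr, dc in ((0, 0), (0, 1), (1, 0), (1, 1)):
        ri = r0 + dr
        ci = c0 + dc
        valid = (ri >= 0) & (ri < H) & (ci >= 0) & (ci < W)
        idx = (np.clip(ri, 0, H - 1) * W + np.clip(ci, 0, W - 1)).reshape(B, G, 1, M)
        vals = np.take_along_axis(flat, idx, axis=3).reshape(B, G, Cg, K, Ho, Wo)
        vals = vals * valid[:, :, None]            # zero padding outside
        wr = (1.0 - fr) if dr == 0 else fr
        wc = (1.0 - fc) if dc == 0 else fc
        corner_vals.append(vals)
        corner_meta.append((idx, valid, wr, wc, dr, dc))

    out_data = np.zeros((B, G, K, Cg, Ho, Wo), dtype=np.float64)
    for vals, (_, _, wr, wc, _, _) in zip(corner_vals, corner_meta):
        out_data += vals.transpose(0, 1, 3, 2, 4, 5) * (wr * wc)[:, :, :, None]

    def backward(g):
        # g: (B, G, K, Cg, Ho, Wo)
        gf = np.zeros((B, G, Cg, H * W), dtype=np.float64)
        gr = np.zeros((B, G, K, Ho, Wo), dtype=np.float64)
        gc = np.zeros((B, G, K, Ho, Wo), dtype=np.float64)
        bi = np.arange(B)[:, None, None, None]
        gi = np.arange(G)[None, :, None, None]
        ci_ = np.arange(Cg)[None, None, :, None]
        for vals, (idx, valid, wr, wc, dr, dc) in zip(corner_vals, corner_meta):
            w = (wr * wc * valid)
            # feature gradient: scatter g * w
            contrib = (g * w[:, :, :, None]).transpose(0, 1, 3, 2, 4, 5)
            contrib = contrib.reshape(B, G, Cg, M)
            np.add.at(gf, (bi, gi, ci_, np.broadcast_to(idx, (B, G, Cg, M))), contrib)
            # coordinate gradient via d(wr*wc)/dr, /dc
            gv = (g * vals.transpose(0, 1, 3, 2, 4, 5)).sum(axis=3)  # (B,G,K,Ho,Wo)
            dwr = -1.0 if dr == 0 else 1.0
            dwc = -1.0 if dc == 0 else 1.0
            gr += gv * dwr * wc * valid
            gc += gv * wr * dwc * valid
        feature._accumulate(gf.reshape(B, G, Cg, H, W))
        coords._accumulate(np.stack([gr, gc], axis=-1))

    return Tensor._make(out_data, (feature, coords), backward)


def bilinear_upsample(x: Tensor, scale: int) -> Tensor:
    """Bilinear x``scale`` upsampling of (B, C, H, W) (align_corners=False)."""
    B, C, H, W = x.shape
    Ho, Wo = H * scale, W * scale
    ro = (np.arange(Ho) + 0.5) / scale - 0.5
    co = (np.arange(Wo) + 0.5) / scale - 0.5
    r0 = np.clip(np.floor(ro).astype(np.int64), 0, H - 1)
    c0 = np.clip(np.floor(co).astype(np.int64), 0, W - 1)
    r1 = np.minimum(r0 + 1, H - 1)
    c1 = np.minimum(c0 + 1, W - 1)
    fr = np.clip(ro - r0, 0.0, 1.0)[:, None]
    fc = np.clip(co - c0, 0.0, 1.0)[None, :]

    corners = [
        (r0, c0, (1 - fr) * (1 - fc)),
        (r0, c1, (1 - fr) * fc),
        (r1, c0, fr * (1 - fc)),
        (r1, c1, fr * fc),
    ]
    out_data = np.zeros((B, C, Ho, Wo), dtype=np.float64)
    for ri, ci, w in corners:
        out_data += x.data[:, :, ri[:, None], ci[None, :]] * w

    def backward(g):
        gflat = np.zeros((B * C, H * W), dtype=np.float64)
        rows = np.arange(B * C)[:, None]
        g2 = g.reshape(B * C, Ho * Wo)
        for ri, ci, w in corners:
            idx = (ri[:, None] * W + ci[None, :]).ravel()[None, :]
            np.add.at(gflat, (rows, idx), g2 * w.ravel()[None, :])
        x._accumulate(gflat.reshape(B, C, H, W))

    return Tensor._make(out_data, (x,), backward)


def selective_scan_op(x: Tensor, delta: Tensor, A: Tensor, Bm: Tensor, Cm: Tensor) -> Tensor:
    """Input-dependent linear state-space recurrence (per channel).

        h_t = exp(delta_t * A) * h_{t-1} + (delta_t * x_t) * B_t
        y_t = <C_t, h_t>

    Shapes: x, delta (B, T, C); A (C, N); Bm, Cm (B, T, N) -> y (B, T, C).
    """
    Bsz, T, C = x.shape
    N = A.shape[1]
    xd, dd, Ad, Bd, Cd = x.data, delta.data, A.data, Bm.data, Cm.data
    hs = np.zeros((T, Bsz, C, N), dtype=np.float64)
    y = np.zeros((Bsz, T, C), dtype=np.float64)
    h = np.zeros((Bsz, C, N), dtype=np.float64)
    for t in range(T):
        a_t = np.exp(dd[:, t, :, None] * Ad[None])          # (B, C, N)
        h = a_t * h + (dd[:, t] * xd[:, t])[:, :, None] * Bd[:, t, None, :]
        hs[t] = h
        y[:, t] = np.einsum("bcn,bn->bc", h, Cd[:, t])

    def backward(g):
        gx = np.zeros_like(xd)
        gd = np.zeros_like(dd)
        gA = np.zeros_like(Ad)
        gB = np.zeros_like(Bd)
        gC = np.zeros_like(Cd)
        gh = np.zeros((Bsz, C, N), dtype=np.float64)
        for t in range(T - 1, -1, -1):
            gC[:, t] = np.einsum("bc,bcn->bn", g[:, t], hs[t])
            gh += g[:, t, :, None] * Cd[:, t, None, :]
            h_prev = hs[t - 1] if t > 0 else np.zeros_like(gh)
            a_t = np.exp(dd[:, t, :, None] * Ad[None])
            ga = gh * h_prev
            # through a_t = exp(delta * A)
            gd[:, t] += np.einsum("bcn,cn->bc", ga * a_t, Ad)
            gA += np.einsum("bcn,bc->cn", ga * a_t, dd[:, t])
            # through the input injection (delta * x) * B
            inj = gh * Bd[:, t, None, :]
            gd[:, t] += inj.sum(axis=2) * xd[:, t]
            gx[:, t] += inj.sum(axis=2) * dd[:, t]
            gB[:, t] += np.einsum("bcn,bc->bn", gh, dd[:, t] * xd[:, t])
            gh = gh * a_t
        x._accumulate(gx)
        delta._accumulate(gd)
        A._accumulate(gA)
        Bm._accumulate(gB)
        Cm._accumulate(gC)

    return Tensor._make(y, (x, delta, A, Bm, Cm), backward)
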