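"""Differentiable spatial operations on (B, C, H, W) arrays.

Convolution is implemented as im2col + grouped batched matmul; its backward
pass is the exact adjoint (col2im scatter).  Pooling and interpolation ops
store the index bookkeeping they need for their adjoints.  A process-global
FLOP audit hook records 2xMAC counts for convolution/linear ops when enabled
(the convention used for the architecture audits: fused conv+norm, elementwise
and pooling ops not counted).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor

__all__ = [
    "conv2d",
    "batch_norm_train",
    "batch_norm_eval",
    "linear",
    "avg_pool2d",
    "max_pool2d",
    "adaptive_avg_pool2d",
    "upsample_nearest2d",
    "resize_bilinear",
    "flop_audit",
]


# ---------------------------------------------------------------------------
# FLOP auditing
# ---------------------------------------------------------------------------
class flop_audit:
    """Context manager accumulating 2xMAC FLOPs of conv/linear ops.

    Only multiply-accumulate work of convolutions and linear layers is
    counted (each MAC as two floating point operations), matching the fused
    conv+norm reporting convention of lightweight-detector papers.
    """

    _active: "flop_audit | None" = None

    def __init__(self):
        self.flops = 0
        self.by_tag: dict[str, int] = {}
        self._tag_stack: list[str] = []

    def __enter__(self):
        flop_audit._active = self
        return self

    def __exit__(self, *exc):
        flop_audit._active = None
        return False

    def push_tag(self, tag: str):
        self._tag_stack.append(tag)

    def pop_tag(self):
        self._tag_stack.pop()

    @classmethod
    def add(cls, macs: int):
        a = cls._active
        if a is not None:
            f = 2 * int(macs)
            a.flops += f
            if a._tag_stack:
                tag = a._tag_stack[-1]
                a.by_tag[tag] = a.by_tag.get(tag, 0) + f


# ---------------------------------------------------------------------------
# Convolution
# ---------------------------------------------------------------------------
def _im2col(x: np.ndarray, kh: int, kw: int, sh: int, sw: int, ph: int, pw: int):
    B, C, H, W = x.shape
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    Ho = (x.shape[2] - kh) // sh + 1
    Wo = (x.shape[3] - kw) // sw + 1
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))[:, :, ::sh, ::sw]
    # (B, C, Ho, Wo, kh, kw) -> (B, C*kh*kw, Ho*Wo), channel-major patch layout
    cols = np.ascontiguousarray(win.transpose(0, 1, 4, 5, 2, 3)).reshape(
        B, C * kh * kw, Ho * Wo
    )
    return cols, Ho, Wo


def _col2im(gcols: np.ndarray, xshape, kh, kw, sh, sw, ph, pw, Ho, Wo):
    B, C, H, W = xshape
    Hp, Wp = H + 2 * ph, W + 2 * pw
    buf = np.zeros((B, C, Hp, Wp), dtype=gcols.dtype)
    g6 = gcols.reshape(B, C, kh, kw, Ho, Wo)
    for i in range(kh):
        hi = i + sh * (Ho - 1) + 1
        for j in range(kw):
            wj = j + sw * (Wo - 1) + 1
            buf[:, :, i:hi:sh, j:wj:sw] += g6[:, :, i, j]
    return buf[:, :, ph:Hp - ph or None, pw:Wp - pw or None]


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride=1, padding=0, groups=1):
    """Grouped 2-D cross-correlation, torch layout: w is (Cout, Cin/g, kh, kw).

    Computed as a sum over the kh*kw kernel positions of batched grouped
    matmuls on shifted input views (BLAS-friendly, no im2col gather); the
    backward pass is the exact adjoint, scattering into the padded gradient
    buffer through the same strided views.
    """
    sh, sw = (stride, stride) if isinstance(stride, int) else stride
    ph, pw = (padding, padding) if isinstance(padding, int) else padding
    B, C, H, W = x.data.shape
    Cout, Cin_g, kh, kw = w.data.shape
    if C % groups or Cout % groups:
        raise ValueError(f"channels ({C}->{Cout}) not divisible by groups={groups}")
    if Cin_g != C // groups:
        raise ValueError("weight shape inconsistent with input channels/groups")

    if ph or pw:
        xp = np.zeros((B, C, H + 2 * ph, W + 2 * pw), dtype=x.data.dtype)
        xp[:, :, ph : ph + H, pw : pw + W] = x.data
    else:
        xp = x.data
    Ho = (H + 2 * ph - kh) // sh + 1
    Wo = (W + 2 * pw - kw) // sw + 1
    L = Ho * Wo
    Cog = Cout // groups
    wg = w.data.reshape(groups, Cog, Cin_g, kh, kw)

    def shifted(i, j):
        view = xp[:, :, i : i + sh * (Ho - 1) + 1 : sh, j : j + sw * (Wo - 1) + 1 : sw]
        return np.ascontiguousarray(view).reshape(B, groups, Cin_g, L)

    out = np.zeros((B, groups, Cog, L), dtype=x.data.dtype)
    for i in range(kh):
        for j in range(kw):
            out += np.matmul(wg[None, :, :, :, i, j], shifted(i, j))
    out = out.reshape(B, Cout, Ho, Wo)
    if b is not None:
        out = out + b.data.reshape(1, Cout, 1, 1)
    flop_audit.add(B * Cout * Cin_g * kh * kw * L)

    parents = (x, w) if b is None else (x, w, b)

    def bw(g):
        gout = np.ascontiguousarray(g).reshape(B, groups, Cog, L)
        if b is not None and b.requires_grad:
            Tensor._accum(b, gout.sum(axis=(0, 3)).reshape(b.data.shape), own=True)
        need_x = x.requires_grad
        need_w = w.requires_grad
        if need_x:
            gxp = np.zeros_like(xp)
        if need_w:
            gw = np.empty_like(wg)
        for i in range(kh):
            for j in range(kw):
                xs = shifted(i, j) if need_w else None
                if need_w:
                    gw[:, :, :, i, j] = np.matmul(gout, xs.transpose(0, 1, 3, 2)).sum(axis=0)
                if need_x:
                    gxs = np.matmul(wg[None, :, :, :, i, j].transpose(0, 1, 3, 2), gout)
                    gxp[:, :, i : i + sh * (Ho - 1) + 1 : sh,
                        j : j + sw * (Wo - 1) + 1 : sw] += gxs.reshape(B, C, Ho, Wo)
        if need_w:
            Tensor._accum(w, gw.reshape(w.data.shape), own=True)
        if need_x:
            gx = gxp[:, :, ph : ph + H, pw : pw + W] if (ph or pw) else gxp
            Tensor._accum(x, np.ascontiguousarray(gx), own=True)

    return Tensor._make(out, parents, bw)


def batch_norm_train(x: Tensor, weight: Tensor, bias: Tensor, eps: float):
    """Fused training-mode batch normalisation over (B, C, H, W).

    Returns ``(out, batch_mean, batch_var)``; the statistics are plain
    arrays for the caller's running-average update.
    """
    mu = x.data.mean(axis=(0, 2, 3), keepdims=True)
    xc = x.data - mu
    var = np.mean(xc * xc, axis=(0, 2, 3), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    C = x.data.shape[1]
    w4 = weight.data.reshape(1, C, 1, 1)
    out = xc * (inv * w4)
    out += bias.data.reshape(1, C, 1, 1)

    def bw(g):
        xn = xc * inv
        if weight.requires_grad:
            Tensor._accum(weight, (g * xn).sum(axis=(0, 2, 3)), own=True)
        if bias.requires_grad:
            Tensor._accum(bias, g.sum(axis=(0, 2, 3)), own=True)
        if x.requires_grad:
            gxn = g * w4
            m1 = gxn.mean(axis=(0, 2, 3), keepdims=True)
            m2 = np.mean(gxn * xn, axis=(0, 2, 3), keepdims=True)
            gxn -= m1 + xn * m2
            gxn *= inv
            Tensor._accum(x, gxn, own=True)

    out_t = Tensor._make(out, (x, weight, bias), bw)
    return out_t, mu.ravel(), var.ravel()


def batch_norm_eval(x: Tensor, weight: Tensor, bias: Tensor,
                    running_mean: np.ndarray, running_var: np.ndarray, eps: float):
    """Inference-mode batch normalisation with frozen statistics."""
    C = x.data.shape[1]
    inv = (1.0 / np.sqrt(running_var + eps)).astype(x.data.dtype)
    scale = weight.data * inv
    shift = bias.data - running_mean * scale
    out = x.data * scale.reshape(1, C, 1, 1) + shift.reshape(1, C, 1, 1)

    def bw(g):
        if weight.requires_grad:
            xn = (x.data - running_mean.reshape(1, C, 1, 1)) * inv.reshape(1, C, 1, 1)
            Tensor._accum(weight, (g * xn).sum(axis=(0, 2, 3)), own=True)
        if bias.requires_grad:
            Tensor._accum(bias, g.sum(axis=(0, 2, 3)), own=True)
        if x.requires_grad:
            Tensor._accum(x, g * scale.reshape(1, C, 1, 1), own=True)

    return Tensor._make(out, (x, weight, bias), bw)


def linear(x: Tensor, w: Tensor, b: Tensor | None = None):
    """x (..., Cin) @ w.T (Cin, Cout) + b."""
    out = x.matmul(Tensor(w.data.T) if not w.requires_grad else _wT(w))
    flop_audit.add(int(np.prod(x.data.shape[:-1])) * w.data.shape[0] * w.data.shape[1])
    if b is not None:
        out = out + b
    return out


def _wT(w: Tensor) -> Tensor:
    return w.transpose((1, 0))


# ---------------------------------------------------------------------------
# Pooling
# ---------------------------------------------------------------------------
def avg_pool2d(x: Tensor, kernel, stride=None, padding=0, count_include_pad=True):
    """Average pooling.

    With ``count_include_pad`` the divisor is the constant ``kh*kw`` (zero
    padding counted); otherwise each window divides by the number of real
    input pixels it covers, so constants are preserved exactly at borders.
    """
    kh, kw = (kernel, kernel) if isinstance(kernel, int) else kernel
    if stride is None:
        stride = (kh, kw)
    sh, sw = (stride, stride) if isinstance(stride, int) else stride
    ph, pw = (padding, padding) if isinstance(padding, int) else padding
    B, C, H, W = x.data.shape
    cols, Ho, Wo = _im2col(x.data, kh, kw, sh, sw, ph, pw)
    sums = cols.reshape(B, C, kh * kw, Ho * Wo).sum(axis=2)
    if count_include_pad:
        divisor = np.full((1, 1, Ho * Wo), float(kh * kw), dtype=x.data.dtype)
    else:
        ones = np.ones((1, 1, H, W), dtype=x.data.dtype)
        cnt, _, _ = _im2col(ones, kh, kw, sh, sw, ph, pw)
        divisor = cnt.reshape(1, 1, kh * kw, Ho * Wo).sum(axis=2)
    out = (sums / divisor).reshape(B, C, Ho, Wo)

    def bw(g):
        gc = np.broadcast_to(
            (g.reshape(B, C, 1, Ho * Wo) / divisor[:, :, None, :]),
            (B, C, kh * kw, Ho * Wo),
        ).reshape(B, C * kh * kw, Ho * Wo)
        Tensor._accum(x, _col2im(gc, x.data.shape, kh, kw, sh, sw, ph, pw, Ho, Wo))

    return Tensor._make(out, (x,), bw)


def max_pool2d(x: Tensor, kernel, stride=None, padding=0):
    kh, kw = (kernel, kernel) if isinstance(kernel, int) else kernel
    if stride is None:
        stride = (kh, kw)
    sh, sw = (stride, stride) if isinstance(stride, int) else stride
    ph, pw = (padding, padding) if isinstance(padding, int) else padding
    B, C, H, W = x.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)), constant_values=-np.inf)
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::sh, ::sw]
    Ho, Wo = win.shape[2], win.shape[3]
    flat = win.reshape(B, C, Ho, Wo, kh * kw)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def bw(g):
        buf = np.zeros_like(xp)
        ii, jj = np.divmod(idx, kw)
        bi, ci, hi, wi = np.indices(idx.shape)
        np.add.at(buf, (bi, ci, hi * sh + ii, wi * sw + jj), g)
        Hp, Wp = xp.shape[2], xp.shape[3]
        Tensor._accum(x, buf[:, :, ph:Hp - ph or None, pw:Wp - pw or None])

    return Tensor._make(np.ascontiguousarray(out), (x,), bw)


def adaptive_avg_pool2d(x: Tensor, out_hw):
    """Adaptive average pooling to an exact (gh, gw) grid.

    Window i along an axis of size H covers [floor(i*H/g), ceil((i+1)*H/g)),
    so windows tile the input exactly and overlap only when g does not
    divide H.
    """
    gh, gw = (out_hw, out_hw) if isinstance(out_hw, int) else out_hw
    B, C, H, W = x.data.shape
    if gh < 1 or gw < 1:
        raise ValueError("adaptive pool output size must be >= 1")
    hb = [(i * H // gh, -(-(i + 1) * H // gh)) for i in range(gh)]
    wb = [(j * W // gw, -(-(j + 1) * W // gw)) for j in range(gw)]
    out = np.empty((B, C, gh, gw), dtype=x.data.dtype)
    for i, (h0, h1) in enumerate(hb):
        for j, (w0, w1) in enumerate(wb):
            out[:, :, i, j] = x.data[:, :, h0:h1, w0:w1].mean(axis=(2, 3))

    def bw(g):
        buf = np.zeros_like(x.data)
        for i, (h0, h1) in enumerate(hb):
            for j, (w0, w1) in enumerate(wb):
                buf[:, :, h0:h1, w0:w1] += (
                    g[:, :, i : i + 1, j : j + 1] / ((h1 - h0) * (w1 - w0))
                )
        Tensor._accum(x, buf)

    return Tensor._make(out, (x,), bw)


def upsample_nearest2d(x: Tensor, scale: int):
    B, C, H, W = x.data.shape
    out = np.repeat(np.repeat(x.data, scale, axis=2), scale, axis=3)

    def bw(g):
        gg = g.reshape(B, C, H, scale, W, scale).sum(axis=(3, 5))
        Tensor._accum(x, gg)

    return Tensor._make(out, (x,), bw)


def _bilinear_matrix(n_out: int, n_in: int, dtype) -> np.ndarray:
    """Row-interpolation matrix, half-pixel centres (align_corners=False)."""
    M = np.zeros((n_out, n_in), dtype=dtype)
    if n_in == 1:
        M[:, 0] = 1.0
        return M
    src = (np.arange(n_out, dtype=np.float64) + 0.5) * n_in / n_out - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    f = src - i0
    for o in range(n_out):
        M[o, i0[o]] += 1.0 - f[o]
        M[o, i1[o]] += f[o]
    return M


def resize_bilinear(x: Tensor, out_hw):
    """Bilinear resize to (Ho, Wo) with half-pixel alignment."""
    Ho, Wo = out_hw
    B, C, H, W = x.data.shape
    R = _bilinear_matrix(Ho, H, x.data.dtype)
    Cm = _bilinear_matrix(Wo, W, x.data.dtype)
    flat = x.data.reshape(B * C, H, W)
    out = np.matmul(np.matmul(R[None], flat), Cm.T[None]).reshape(B, C, Ho, Wo)

    def bw(g):
        gf = g.reshape(B * C, Ho, Wo)
        gx = np.matmul(np.matmul(R.T[None], gf), Cm[None]).reshape(B, C, H, W)
        Tensor._accum(x, gx)

    return Tensor._make(out, (x,), bw)
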