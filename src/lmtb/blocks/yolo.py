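"""Standard YOLO-family building blocks (v11 generation).

These reconstruct the publicly documented nano-scale layout of the YOLO11
detector family: CSP-style bottleneck stages (C3k2), spatial pyramid pooling
(SPPF), the position-sensitive attention stage (C2PSA) and the decoupled
anchor-free detect head with distribution focal regression.  They serve as
the unmodified reference graph against which the lightweight replacement
blocks in this package are audited.
"""

from __future__ import annotations

import math

import numpy as np

from .. import functional as F
from .. import nn
from ..tensor import Tensor


def autopad(k) -> int:
    if isinstance(k, (tuple, list)):
        return tuple(x // 2 for x in k)
    return k // 2


class Conv(nn.Module):
    """Conv2d (no bias) + BatchNorm + SiLU, the standard fused conv unit."""

    def __init__(self, c1, c2, k=1, s=1, p=None, g=1, act=True):
        super().__init__()
        self.conv = nn.Conv2d(c1, c2, k, s, autopad(k) if p is None else p, g, bias=False)
        self.bn = nn.BatchNorm2d(c2)
        self.act = nn.SiLU() if act is True else (act if isinstance(act, nn.Module) else nn.Identity())

    def forward(self, x):
        return self.act(self.bn(self.conv(x)))


class DWConv(Conv):
    """Depthwise convolution (groups = gcd of channel counts)."""

    def __init__(self, c1, c2, k=1, s=1, act=True):
        super().__init__(c1, c2, k, s, g=math.gcd(c1, c2), act=act)


class Bottleneck(nn.Module):
    def __init__(self, c1, c2, shortcut=True, g=1, k=(3, 3), e=0.5):
        super().__init__()
        c_ = int(c2 * e)
        self.cv1 = Conv(c1, c_, k[0], 1)
        self.cv2 = Conv(c_, c2, k[1], 1, g=g)
        self.add = shortcut and c1 == c2

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class C3(nn.Module):
    def __init__(self, c1, c2, n=1, shortcut=True, g=1, e=0.5):
        super().__init__()
        c_ = int(c2 * e)
        self.cv1 = Conv(c1, c_, 1, 1)
        self.cv2 = Conv(c1, c_, 1, 1)
        self.cv3 = Conv(2 * c_, c2, 1)
        self.m = nn.Sequential(
            *(Bottleneck(c_, c_, shortcut, g, k=((1, 1), (3, 3)), e=1.0) for _ in range(n))
        )

    def forward(self, x):
        return self.cv3(Tensor.concat([self.m(self.cv1(x)), self.cv2(x)], axis=1))


class C3k(C3):
    """C3 with a configurable bottleneck kernel (3x3 pairs here)."""

    def __init__(self, c1, c2, n=1, shortcut=True, g=1, e=0.5, k=3):
        super().__init__(c1, c2, n, shortcut, g, e)
        c_ = int(c2 * e)
        self.m = nn.Sequential(
            *(Bottleneck(c_, c_, shortcut, g, k=(k, k), e=1.0) for _ in range(n))
        )


class C2f(nn.Module):
    """Cross-stage-partial bottleneck with split/concat fusion."""

    def __init__(self, c1, c2, n=1, shortcut=False, g=1, e=0.5):
        super().__init__()
        self.c = int(c2 * e)
        self.cv1 = Conv(c1, 2 * self.c, 1, 1)
        self.cv2 = Conv((2 + n) * self.c, c2, 1)
        self.m = nn.ModuleList(
            Bottleneck(self.c, self.c, shortcut, g, k=((3, 3), (3, 3)), e=1.0)
            for _ in range(n)
        )

    def forward(self, x):
        y = self.cv1(x).chunk(2, axis=1)
        ys = [y[0], y[1]]
        for m in self.m:
            ys.append(m(ys[-1]))
        return self.cv2(Tensor.concat(ys, axis=1))


class C3k2(C2f):
    """v11-generation CSP stage: inner blocks are C3k units or bottlenecks."""

    def __init__(self, c1, c2, n=1, c3k=False, e=0.5, g=1, shortcut=True):
        super().__init__(c1, c2, n, shortcut, g, e)
        self.m = nn.ModuleList(
            C3k(self.c, self.c, 2, shortcut, g)
            if c3k
            else Bottleneck(self.c, self.c, shortcut, g)
            for _ in range(n)
        )


class SPPF(nn.Module):
    def __init__(self, c1, c2, k=5):
        super().__init__()
        c_ = c1 // 2
        self.cv1 = Conv(c1, c_, 1, 1)
        self.cv2 = Conv(c_ * 4, c2, 1, 1)
        self.k = k

    def forward(self, x):
        y = [self.cv1(x)]
        for _ in range(3):
            y.append(F.max_pool2d(y[-1], self.k, 1, self.k // 2))
        return self.cv2(Tensor.concat(y, axis=1))


class Attention(nn.Module):
    """Multi-head similarity attention with a positional conv branch."""

    def __init__(self, dim, num_heads=8, attn_ratio=0.5):
        super().__init__()
        self.num_heads = num_heads
        self.head_dim = dim // num_heads
        self.key_dim = int(self.head_dim * attn_ratio)
        self.scale = self.key_dim ** -0.5
        nh_kd = self.key_dim * num_heads
        h = dim + nh_kd * 2
        self.qkv = Conv(dim, h, 1, act=False)
        self.proj = Conv(dim, dim, 1, act=False)
        self.pe = Conv(dim, dim, 3, 1, g=dim, act=False)

    def forward(self, x):
        B, C, H, W = x.shape
        N = H * W
        qkv = self.qkv(x).reshape(B, self.num_heads, self.key_dim * 2 + self.head_dim, N)
        q = qkv[:, :, : self.key_dim, :]
        k = qkv[:, :, self.key_dim : 2 * self.key_dim, :]
        v = qkv[:, :, 2 * self.key_dim :, :]
        attn = (q.transpose((0, 1, 3, 2)) @ k) * self.scale
        attn = attn.softmax(axis=-1)
        out = v @ attn.transpose((0, 1, 3, 2))
        out = out.reshape(B, C, H, W) + self.pe(v.reshape(B, C, H, W))
        return self.proj(out)


class PSABlock(nn.Module):
    def __init__(self, c, attn_ratio=0.5, num_heads=4, shortcut=True):
        super().__init__()
        self.attn = Attention(c, attn_ratio=attn_ratio, num_heads=num_heads)
        self.ffn = nn.Sequential(Conv(c, c * 2, 1), Conv(c * 2, c, 1, act=False))
        self.add = shortcut

    def forward(self, x):
        x = x + self.attn(x) if self.add else self.attn(x)
        return x + self.ffn(x) if self.add else self.ffn(x)


class C2PSA(nn.Module):
    """CSP wrapper around a stack of position-sensitive attention blocks."""

    def __init__(self, c1, c2, n=1, e=0.5):
        super().__init__()
        assert c1 == c2
        self.c = int(c1 * e)
        self.cv1 = Conv(c1, 2 * self.c, 1, 1)
        self.cv2 = Conv(2 * self.c, c1, 1)
        self.m = nn.Sequential(
            *(PSABlock(self.c, attn_ratio=0.5, num_heads=self.c // 64) for _ in range(n))
        )

    def forward(self, x):
        a, b = self.cv1(x).chunk(2, axis=1)
        b = self.m(b)
        return self.cv2(Tensor.concat([a, b], axis=1))


class Detect(nn.Module):
    """Decoupled anchor-free detect head with DFL box regression.

    ``forward`` returns the raw per-level prediction maps
    (B, 4*reg_max + nc, H, W); decoding to boxes is inference plumbing that
    lives with the model assembly.
    """

    def __init__(self, nc=1, ch=(), reg_max=16):
        super().__init__()
        self.nc, self.reg_max = nc, reg_max
        self.strides = None  # filled by the assembly
        c2 = max(16, ch[0] // 4, reg_max * 4)
        c3 = max(ch[0], min(nc, 100))
        self.cv2 = nn.ModuleList(
            nn.Sequential(
                Conv(x, c2, 3), Conv(c2, c2, 3), nn.Conv2d(c2, 4 * reg_max, 1)
            )
            for x in ch
        )
        self.cv3 = nn.ModuleList(
            nn.Sequential(
                nn.Sequential(DWConv(x, x, 3), Conv(x, c3, 1)),
                nn.Sequential(DWConv(c3, c3, 3), Conv(c3, c3, 1)),
                nn.Conv2d(c3, nc, 1),
            )
            for x in ch
        )
        # DFL projection (fixed, non-trainable): expectation over reg_max bins
        self.dfl_proj = np.arange(reg_max, dtype=np.float32)

    def forward(self, feats):
        return [
            Tensor.concat([self.cv2[i](x), self.cv3[i](x)], axis=1)
            for i, x in enumerate(feats)
        ]
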