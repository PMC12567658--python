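"""Multi-scale Edge-Refinement Context Aggregator (MERCA).

A drop-in replacement for the backbone CSP stages, built for scenes whose
targets span a wide linear size range (tea-bud tips of a few millimetres next
to young leaves several times larger).  The block decouples the input into a
small pyramid of pooled scale spaces, refines high-frequency (edge) structure
in each, and aggregates the rescaled branches with a full-resolution local
branch in CSP style:

* scale adapter ``A_k``: adaptive average pooling to a ``g_k x g_k`` grid
  followed by a 1x1 reduction conv and a grouped 3x3 conv;
* edge refiner ``ER(X) = X + Conv(X - P_avg(X))``: a box-filter low-pass
  isolates the high-frequency residual, a depthwise 3x3 conv enhances it, and
  the residual connection preserves the original signal exactly when the conv
  is zero;
* context aggregation: branches are resized back to the input resolution by
  bilinear interpolation, concatenated with a 1x1 local branch, and fused by
  a 1x1 aggregation conv back to the block width.

Each of the ``N`` scale branches carries ``c2 / N`` channels so the
concatenation (branches + local) is exactly ``2 * c2`` wide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .. import functional as F
from .. import nn
from ..tensor import Tensor
from .yolo import Conv


@dataclass(frozen=True)
class MercaConfig:
    """Configuration of one MERCA block.

    Parameters
    ----------
    c1, c2:
        Input / output channel counts.
    scales:
        Strictly increasing pooled grid sizes ``g_k``.  The default
        ``(3, 6, 9, 12)`` is the ``g_k = 3k, k = 1..4`` pyramid.
    groups:
        Group count of the grouped 3x3 conv in each scale adapter.
    """

    c1: int
    c2: int
    scales: tuple = (3, 6, 9, 12)
    groups: int = 16

    def __post_init__(self):
        if self.c1 <= 0 or self.c2 <= 0:
            raise ValueError("channel counts must be positive")
        if len(self.scales) < 1 or any(g < 1 for g in self.scales):
            raise ValueError("pooled sizes must be >= 1")
        if list(self.scales) != sorted(set(self.scales)):
            raise ValueError("pooled sizes must be strictly increasing")
        if self.c2 % len(self.scales):
            raise ValueError("c2 must be divisible by the branch count")
        if (self.c2 // len(self.scales)) % self.groups:
            raise ValueError("branch width not divisible by group count")

    @property
    def branch_width(self) -> int:
        return self.c2 // len(self.scales)


class ScaleAdapter(nn.Module):
    """Pool to a fixed ``g x g`` grid, reduce width, mix with a grouped conv."""

    def __init__(self, c1: int, c_branch: int, g_pool: int, groups: int):
        super().__init__()
        if g_pool < 1:
            raise ValueError("pooled size must be positive")
        self.g_pool = g_pool
        self.reduce = Conv(c1, c_branch, 1)
        self.mix = Conv(c_branch, c_branch, 3, g=groups)

    def pooled_size(self, h: int, w: int) -> int:
        # behaviour below the largest pyramid size is unspecified upstream;
        # clamp so the pooled grid never exceeds the feature map
        return max(1, min(self.g_pool, h, w))

    def forward(self, x):
        _, _, h, w = x.shape
        g = self.pooled_size(h, w)
        return self.mix(self.reduce(F.adaptive_avg_pool2d(x, g)))


class EdgeRefiner(nn.Module):
    """High-frequency residual enhancement: ``X + Conv(X - P_avg(X))``.

    ``P_avg`` is a shape-preserving 3x3 box filter (stride 1; border windows
    divide by the number of real pixels, so the filter is exactly
    mean-preserving and constants yield a zero residual everywhere).  The
    enhancement conv is a depthwise 3x3 kept linear (bias, no
    norm/activation) so the identity on constant inputs and the residual
    arithmetic are exact.
    """

    def __init__(self, c: int):
        super().__init__()
        self.conv = nn.Conv2d(c, c, 3, padding=1, groups=c, bias=True)

    def forward(self, x):
        return x + self.conv(x - F.avg_pool2d(x, 3, 1, 1, count_include_pad=False))


class MERCA(nn.Module):
    def __init__(self, c1, c2, scales=(3, 6, 9, 12), groups=16):
        super().__init__()
        self.cfg = MercaConfig(c1, c2, tuple(scales), groups)
        cb = self.cfg.branch_width
        self.adapters = nn.ModuleList(
            ScaleAdapter(c1, cb, g, groups) for g in self.cfg.scales
        )
        self.refiners = nn.ModuleList(EdgeRefiner(cb) for _ in self.cfg.scales)
        self.local = Conv(c1, c2, 1)
        self.agg = Conv(2 * c2, c2, 1)

    def forward(self, x):
        _, _, h, w = x.shape
        feats = [self.local(x)]
        for adapter, refiner in zip(self.adapters, self.refiners):
            y = refiner(adapter(x))
            feats.append(F.resize_bilinear(y, (h, w)))
        return self.agg(Tensor.concat(feats, axis=1))
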