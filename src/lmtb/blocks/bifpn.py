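"""Weighted bidirectional feature-pyramid neck with P2 detail injection.

Replaces the PAFPN neck: all backbone levels are first compressed to a common
width by 1x1 convs, a top-down pass propagates semantics (P5 -> P4 -> P3), the
stride-4 P2 level is downsampled into the P3 fusion node to reinject fine
edge detail, and a bottom-up pass (P3 -> P4 -> P5) completes the bidirectional
flow.  Every fusion node combines its inputs by fast normalized fusion

    out = sum_i relu(w_i) * F_i / (sum_j relu(w_j) + eps)

with learnable scalar weights, so each effective coefficient is nonnegative
and the combination is convex up to the epsilon shrinkage.  The refined P3,
P4, P5 maps (strides 8/16/32) feed the detect head.
"""

from __future__ import annotations

import numpy as np

from .. import functional as F
from .. import nn
from ..tensor import Parameter, Tensor
from .yolo import Conv, DWConv


def _dwsep(width: int) -> nn.Sequential:
    """Depthwise-separable 3x3 refinement (depthwise spatial + 1x1 mix)."""
    return nn.Sequential(DWConv(width, width, 3), Conv(width, width, 1))


class FastNormalizedFusion(nn.Module):
    """Learnable nonnegative weighted average of m same-shape feature maps."""

    def __init__(self, m: int, eps: float = 1e-4):
        super().__init__()
        if m < 2:
            raise ValueError("fusion node needs at least two inputs")
        if eps <= 0:
            raise ValueError("eps must be positive")
        self.m, self.eps = m, eps
        self.w = Parameter(np.ones(m))

    def effective_weights(self) -> np.ndarray:
        wr = np.maximum(self.w.data, 0.0)
        return wr / (wr.sum() + self.eps)

    def forward(self, inputs):
        if len(inputs) != self.m:
            raise ValueError(f"expected {self.m} inputs, got {len(inputs)}")
        shapes = {t.shape for t in inputs}
        if len(shapes) != 1:
            raise ValueError(f"fusion inputs must share a shape, got {shapes}")
        wr = self.w.relu()
        denom = wr.sum() + self.eps
        out = inputs[0] * (wr[0] / denom)
        for i in range(1, self.m):
            out = out + inputs[i] * (wr[i] / denom)
        return out


class BiFPNNeck(nn.Module):
    """One bidirectional sweep over (P2, P3, P4, P5) at a common width.

    Returns refined (P3', P4', P5') at strides 8/16/32.  The three-conv
    enhancement stack sits after the top-down P4 fusion (its middle conv is
    depthwise-separable, giving a mix-refine-mix sandwich); the other fusion
    nodes are followed by a single refinement conv, lightweighted according
    to where the compute load sits: grouped 3x3 at the large stride-8 P3
    node, full 3x3 at the bottom-up P4 node, depthwise-separable at the
    small P5 node.  Downsampling is a stride-2 3x3 conv, upsampling
    nearest-neighbour x2.
    """

    def __init__(self, channels=(64, 128, 128, 256), width: int = 64):
        super().__init__()
        if len(channels) != 4:
            raise ValueError("expected channels for (P2, P3, P4, P5)")
        c2, c3, c4, c5 = channels
        self.width = width
        # channel compression to the common neck width
        self.red_p2 = Conv(c2, width, 1)
        self.red_p3 = Conv(c3, width, 1)
        self.red_p4 = Conv(c4, width, 1)
        self.red_p5 = Conv(c5, width, 1)
        self.up = nn.Upsample(2)
        # top-down
        self.fuse_td_p4 = FastNormalizedFusion(2)
        self.conv_td_p4 = nn.Sequential(
            Conv(width, width, 3), _dwsep(width), Conv(width, width, 3)
        )
        self.down_p2 = Conv(width, width, 3, 2)
        self.fuse_td_p3 = FastNormalizedFusion(3)
        self.conv_td_p3 = Conv(width, width, 3, g=2)
        # bottom-up
        self.down_p3 = Conv(width, width, 3, 2)
        self.fuse_bu_p4 = FastNormalizedFusion(3)
        self.conv_bu_p4 = Conv(width, width, 3)
        self.down_p4 = Conv(width, width, 3, 2)
        self.fuse_bu_p5 = FastNormalizedFusion(2)
        self.conv_bu_p5 = _dwsep(width)

    def forward(self, levels):
        if len(levels) != 4:
            raise ValueError("BiFPN neck needs (P2, P3, P4, P5); P2 is required")
        p2, p3, p4, p5 = levels
        c2 = self.red_p2(p2)
        c3 = self.red_p3(p3)
        c4 = self.red_p4(p4)
        c5 = self.red_p5(p5)
        # top-down semantic propagation
        td4 = self.conv_td_p4(self.fuse_td_p4([c4, self.up(c5)]))
        td3 = self.conv_td_p3(
            self.fuse_td_p3([c3, self.up(td4), self.down_p2(c2)])
        )
        # bottom-up spatial propagation
        out3 = td3
        out4 = self.conv_bu_p4(self.fuse_bu_p4([c4, td4, self.down_p3(out3)]))
        out5 = self.conv_bu_p5(self.fuse_bu_p5([c5, self.down_p4(out4)]))
        return out3, out4, out5
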