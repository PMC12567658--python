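"""Dynamic Hyperbolic Token Statistics Transformer (DHTST).

Replaces the similarity-based attention stage at the end of the backbone with
two cheaper mechanisms aimed at low-contrast scenes:

* **Dynamic tanh (DyT)** -- a learnable elementwise squashing
  ``beta * tanh(alpha * x + gamma)`` standing in for static normalisation:
  ``alpha`` adapts the input scaling, ``gamma`` the operating point, and
  ``beta`` the output range (so ``|output| <= |beta|`` always).

* **Token-statistics attention** -- attention weights derived from
  second-order token statistics rather than query-key similarity.  Tokens are
  projected, split into heads, and each token's squared norm (scaled by a
  learnable temperature) is softmaxed over the token axis into weights ``Pi``.
  The Pi-weighted second moment of the projected tokens gives a per-dimension
  variance estimate; tokens are rescaled by its inverse square root
  (epsilon-stabilised), gated, re-weighted by ``Pi`` and merged by a final
  linear projection.  Cost is linear in the token count (no n x n attention
  matrix).

The block follows the C2-family convention: a 1x1 conv then a 1:1 channel
split into a main branch (kept) and an auxiliary branch (DyT then attention,
rejoined residually), concatenation, a second DyT and a two-conv FFN added
residually.  Output shape always equals input shape.
"""

from __future__ import annotations

from .. import functional as F
from .. import nn
from ..tensor import Parameter, Tensor
from .yolo import Conv

import numpy as np


class DyT(nn.Module):
    """Learnable elementwise ``beta * tanh(alpha * x + gamma)`` per channel.

    ``axis`` selects the channel axis of the inputs this layer will see
    (1 for maps in BCHW, -1 for token sequences).
    """

    def __init__(self, c: int, axis: int = 1, alpha_init: float = 0.5):
        super().__init__()
        self.alpha = Parameter(np.full(c, alpha_init))
        self.beta = Parameter(np.ones(c))
        self.gamma = Parameter(np.zeros(c))
        self.axis = axis
        self.c = c

    def _shaped(self, p, ndim):
        if self.axis == -1:
            return p
        shape = [1] * ndim
        shape[self.axis] = self.c
        return p.reshape(shape)

    def forward(self, x):
        nd = x.ndim
        a = self._shaped(self.alpha, nd)
        b = self._shaped(self.beta, nd)
        g = self._shaped(self.gamma, nd)
        return b * (a * x + g).tanh()


class TokenStatAttention(nn.Module):
    """Attention from per-token second-moment statistics.

    Operates on token sequences of shape (B, n, dim); ``dim`` must be
    divisible by the head count.
    """

    def __init__(self, dim: int, num_heads: int = 4, eps: float = 1e-6, dropout: float = 0.0):
        super().__init__()
        if dim % num_heads:
            raise ValueError(f"dim={dim} not divisible by num_heads={num_heads}")
        self.dim, self.h, self.d = dim, num_heads, dim // num_heads
        self.eps = eps
        self.proj = nn.Linear(dim, dim)
        self.out = nn.Linear(dim, dim)
        self.tau = Parameter(np.ones(num_heads))
        self.gate = Parameter(np.ones((num_heads, 1, self.d)))
        self.drop = nn.Dropout(dropout)

    def attention_weights(self, x: Tensor) -> Tensor:
        """Pi in (B, h, n): softmax over tokens of tau-scaled squared norms."""
        B, n, _ = x.shape
        w = self._heads(self.proj(x))
        scores = (w * w).sum(axis=-1) * self.tau.reshape((1, self.h, 1))
        return scores.softmax(axis=-1)

    def _heads(self, t: Tensor) -> Tensor:
        B, n, _ = t.shape
        return t.reshape(B, n, self.h, self.d).transpose((0, 2, 1, 3))

    def forward(self, x: Tensor) -> Tensor:
        B, n, _ = x.shape
        if n < 1:
            raise ValueError("need at least one token")
        w = self._heads(self.proj(x))  # (B, h, n, d)
        scores = (w * w).sum(axis=-1) * self.tau.reshape((1, self.h, 1))
        pi = scores.softmax(axis=-1)  # (B, h, n)
        pin = pi / (pi.sum(axis=-1, keepdims=True) + self.eps)
        pin4 = pin.reshape(B, self.h, n, 1)
        second_moment = (pin4 * w * w).sum(axis=2, keepdims=True)  # (B,h,1,d)
        f_attn = w * (second_moment + self.eps).pow(-0.5)
        y = self.gate * pi.reshape(B, self.h, n, 1) * f_attn
        y = self.drop(y)
        merged = y.transpose((0, 2, 1, 3)).reshape(B, n, self.dim)
        return self.drop(self.out(merged))


class DHTST(nn.Module):
    """Dynamic-tanh + token-statistics block at the end of the backbone."""

    def __init__(self, c: int, num_heads: int = 4, eps: float = 1e-6, dropout: float = 0.0):
        super().__init__()
        if c % 2:
            raise ValueError("channel count must be even (1:1 split)")
        self.c = c
        self.cv1 = Conv(c, c, 1)
        self.dyn1 = DyT(c // 2, axis=1)
        self.attn = TokenStatAttention(c // 2, num_heads, eps, dropout)
        self.dyn2 = DyT(c, axis=1)
        self.ffn = nn.Sequential(Conv(c, c, 1), Conv(c, c, 1, act=False))

    def forward(self, x):
        B, C, H, W = x.shape
        main, aux = self.cv1(x).chunk(2, axis=1)
        a = self.dyn1(aux)
        tokens = a.reshape(B, C // 2, H * W).transpose((0, 2, 1))  # (B, n, dim)
        t = self.attn(tokens)
        t_map = t.transpose((0, 2, 1)).reshape(B, C // 2, H, W)
        fusion = Tensor.concat([main, aux + t_map], axis=1)
        return fusion + self.ffn(self.dyn2(fusion))
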