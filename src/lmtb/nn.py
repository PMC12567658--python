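"""Neural-network module layer over the autograd engine.

Mirrors the familiar torch-style API surface (Module / Sequential / Conv2d /
BatchNorm2d / ...) at the scale this package needs.  Parameter registration is
automatic through ``__setattr__``; ``parameters()`` walks the module tree.
"""

from __future__ import annotations

import math

import numpy as np

from . import functional as F
from .tensor import Parameter, Tensor

_rng = np.random.default_rng(0)


def manual_seed(seed: int):
    """Seed the global generator used for weight initialisation."""
    global _rng
    _rng = np.random.default_rng(seed)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name, value):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # -- traversal ------------------------------------------------------
    def named_modules(self, prefix=""):
        yield prefix, self
        for name, mod in self._modules.items():
            sub = f"{prefix}.{name}" if prefix else name
            yield from mod.named_modules(sub)

    def named_parameters(self, prefix=""):
        for name, p in self._params.items():
            yield (f"{prefix}.{name}" if prefix else name), p
        for name, mod in self._modules.items():
            sub = f"{prefix}.{name}" if prefix else name
            yield from mod.named_parameters(sub)

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def num_params(self) -> int:
        """Exact count of trainable scalars."""
        return sum(p.size for p in self.parameters() if p.requires_grad)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self, mode=True):
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def __call__(self, *args, **kw):
        return self.forward(*args, **kw)


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        for i, m in enumerate(mods):
            setattr(self, str(i), m)
        self._seq = list(mods)

    def __iter__(self):
        return iter(self._seq)

    def __getitem__(self, i):
        return self._seq[i]

    def __len__(self):
        return len(self._seq)

    def forward(self, x):
        for m in self._seq:
            x = m(x)
        return x


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list = []
        for m in mods:
            self.append(m)

    def append(self, m):
        setattr(self, str(len(self._list)), m)
        self._list.append(m)
        return self

    def __iter__(self):
        return iter(self._list)

    def __getitem__(self, i):
        return self._list[i]

    def __len__(self):
        return len(self._list)


class Identity(Module):
    def forward(self, x):
        return x


class SiLU(Module):
    def forward(self, x):
        return x.silu()


class Conv2d(Module):
    def __init__(self, c1, c2, k=1, stride=1, padding=0, groups=1, bias=True):
        super().__init__()
        if c1 % groups or c2 % groups:
            raise ValueError(f"channels {c1}->{c2} not divisible by groups={groups}")
        kh, kw = (k, k) if isinstance(k, int) else k
        fan_in = c1 // groups * kh * kw
        bound = 1.0 / math.sqrt(fan_in)
        self.weight = Parameter(
            _rng.uniform(-bound, bound, size=(c2, c1 // groups, kh, kw))
        )
        self.bias = Parameter(_rng.uniform(-bound, bound, size=(c2,))) if bias else None
        self.stride, self.padding, self.groups = stride, padding, groups

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, self.stride, self.padding, self.groups)


class Linear(Module):
    def __init__(self, c1, c2, bias=True):
        super().__init__()
        bound = 1.0 / math.sqrt(c1)
        self.weight = Parameter(_rng.uniform(-bound, bound, size=(c2, c1)))
        self.bias = Parameter(_rng.uniform(-bound, bound, size=(c2,))) if bias else None

    def forward(self, x):
        return F.linear(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, c, eps=1e-3, momentum=0.03):
        super().__init__()
        self.weight = Parameter(np.ones(c))
        self.bias = Parameter(np.zeros(c))
        self.register_buffer("running_mean", np.zeros(c, dtype=np.float32))
        self.register_buffer("running_var", np.ones(c, dtype=np.float32))
        self.eps, self.momentum, self.c = eps, momentum, c

    def forward(self, x):
        if self.training:
            out, mu, var = F.batch_norm_train(x, self.weight, self.bias, self.eps)
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            m = self.momentum
            self.running_mean += m * (mu - self.running_mean)
            self.running_var += m * (var * (n / max(n - 1, 1)) - self.running_var)
            return out
        return F.batch_norm_eval(
            x, self.weight, self.bias, self.running_mean, self.running_var, self.eps
        )


class MaxPool2d(Module):
    def __init__(self, k, stride=None, padding=0):
        super().__init__()
        self.k, self.stride, self.padding = k, stride, padding

    def forward(self, x):
        return F.max_pool2d(x, self.k, self.stride, self.padding)


class Upsample(Module):
    """Nearest-neighbour integer upsampling."""

    def __init__(self, scale=2):
        super().__init__()
        self.scale = scale

    def forward(self, x):
        return F.upsample_nearest2d(x, self.scale)


class Dropout(Module):
    def __init__(self, p=0.0):
        super().__init__()
        self.p = p

    def forward(self, x):
        if not self.training or self.p <= 0.0:
            return x
        mask = (_rng.random(x.data.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask.astype(x.data.dtype))
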