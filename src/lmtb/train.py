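"""Gradient-flow / trainability smoke utilities.

Full-scale training (300 epochs, SGD lr 0.01, momentum 0.973, weight decay
1e-5, batch 32, mosaic augmentation at 640 px — recorded in
:data:`REFERENCE_TRAIN_CONFIG`) is out of scope for this package; what matters
at desk scale is that the assembled graphs are *trainable*: every parameter
receives finite gradients and a few hundred optimisation steps on a handful
of synthetic scenes clearly reduce a simple dense loss.

The simplified dense loss supervises the raw head maps directly: the class
logit of every cell is pushed toward a binary occupancy map (stable
binary-cross-entropy), and at cells containing a target centre the
distribution-focal box bins are pulled (MSE after softmax) toward the
two-hot encoding of the true left/top/right/bottom distances.  Every ground
truth marks its centre cell at all three strides, so both head branches and
all pyramid levels are exercised.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor
from .model import DetectorGraph

REFERENCE_TRAIN_CONFIG = {
    "epochs": 300,
    "batch_size": 32,
    "optimizer": "sgd",
    "lr": 0.01,
    "momentum": 0.973,
    "weight_decay": 1e-5,
    "img_size": 640,
}


def dense_targets(anns: np.ndarray, img_size: int, strides=(8, 16, 32), reg_max: int = 16):
    """Per-level (cls_map, box_dist, pos_mask) targets for one image."""
    out = []
    for s in strides:
        g = img_size // s
        cls_map = np.zeros((1, g, g), dtype=np.float32)
        box = np.zeros((4, reg_max, g, g), dtype=np.float32)
        pos = np.zeros((g, g), dtype=bool)
        for _, cx, cy, w, h in np.asarray(anns).reshape(-1, 5):
            gx = min(int(cx * g), g - 1)
            gy = min(int(cy * g), g - 1)
            cls_map[0, gy, gx] = 1.0
            pos[gy, gx] = True
            ccx, ccy = (gx + 0.5) * s, (gy + 0.5) * s
            x1, y1 = (cx - w / 2) * img_size, (cy - h / 2) * img_size
            x2, y2 = (cx + w / 2) * img_size, (cy + h / 2) * img_size
            for side, dist in enumerate([(ccx - x1) / s, (ccy - y1) / s,
                                         (x2 - ccx) / s, (y2 - ccy) / s]):
                d = float(np.clip(dist, 0, reg_max - 1 - 1e-3))
                lo = int(d)
                box[side, lo, gy, gx] = 1 - (d - lo)
                box[side, min(lo + 1, reg_max - 1), gy, gx] += d - lo
        out.append((cls_map, box, pos))
    return out


def _bce_with_logits(z: Tensor, y: np.ndarray) -> Tensor:
    """Numerically stable mean binary cross-entropy on raw logits."""
    yt = Tensor(y.astype(z.dtype.type))
    absz = z.relu() + (-z).relu()
    return (z.relu() - z * yt + ((-absz).exp() + 1.0).log()).mean()


def dense_loss(preds, targets, reg_max: int = 16, box_weight: float = 5.0) -> Tensor:
    """Simplified dense detection loss over the raw per-level head maps."""
    total = None
    for p, (cls_map, box_t, pos) in zip(preds, targets):
        B, C, H, W = p.shape
        box_z = p[:, : 4 * reg_max].reshape(B, 4, reg_max, H, W)
        cls_z = p[:, 4 * reg_max :]
        term = _bce_with_logits(cls_z, cls_map[None].repeat(B, axis=0))
        if pos.any():
            prob = box_z.softmax(axis=2)
            diff = prob - Tensor(np.broadcast_to(box_t[None], (B, 4, reg_max, H, W)).astype(np.float32))
            mask = Tensor(np.broadcast_to(pos[None, None, None], (B, 4, reg_max, H, W)).astype(np.float32))
            term = term + box_weight * ((diff * diff) * mask).sum() * (1.0 / (B * 4 * reg_max * max(pos.sum(), 1)))
        total = term if total is None else total + term
    return total * (1.0 / len(targets))


class SGD:
    def __init__(self, params, lr=0.01, momentum=0.9, weight_decay=0.0):
        self.params = list(params)
        self.lr, self.momentum, self.wd = lr, momentum, weight_decay
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self.v):
            if p.grad is None:
                continue
            g = p.grad + self.wd * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class Adam:
    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad * p.grad
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def train_smoke(model: DetectorGraph, scenes, steps: int = 200, img_size: int = 320,
                lr: float = 2e-3, check_grads_at: int = 0):
    """Run the dense-loss smoke optimisation; returns (losses, grad_report).

    ``scenes`` is a list of (uint8 image, annotations) pairs at ``img_size``.
    One scene per step, cycled in order.  ``grad_report`` maps parameter
    names to True if the parameter received a finite, not-all-zero gradient
    at step ``check_grads_at``.
    """
    model.train()
    opt = Adam(model.parameters(), lr=lr)
    pre = []
    for img, anns in scenes:
        x = np.ascontiguousarray(img.transpose(2, 0, 1)[None], dtype=np.float32) / 255.0
        pre.append((x, dense_targets(anns, img_size, model.strides)))
    losses = []
    grad_report = {}
    for step in range(steps):
        x, tgt = pre[step % len(pre)]
        opt.zero_grad()
        preds = model(Tensor(x))
        loss = dense_loss(preds, tgt)
        loss.backward()
        if step == check_grads_at:
            for name, p in model.named_parameters():
                ok = (
                    p.grad is not None
                    and np.all(np.isfinite(p.grad))
                    and np.any(p.grad != 0)
                )
                grad_report[name] = bool(ok)
        opt.step()
        losses.append(loss.item())
    return losses, grad_report
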