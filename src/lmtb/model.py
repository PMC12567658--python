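"""Detector graph assembly and inference plumbing.

Builds the nano-scale one-stage detector family this package studies:

* the unmodified baseline (CSP ``C3k2`` backbone stages, ``C2PSA`` attention
  stage, PAFPN neck, three decoupled detect heads), reconstructed from the
  publicly documented nano layout, and
* the lightweight variant ("lmtb"): MERCA replacing the backbone C3k2
  stages, DHTST replacing C2PSA, and the P2-injected BiFPN neck at a common
  width of 64 channels — plus every intermediate ablation combination.

``forward`` returns the three raw prediction maps at strides 8/16/32;
``decode_predictions`` and ``nms`` turn them into boxes for smoke tests.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .blocks import (
    C2PSA,
    C3k2,
    Conv,
    Detect,
    DHTST,
    MERCA,
    SPPF,
    BiFPNNeck,
)
from .tensor import Tensor, no_grad

NANO_WIDTHS = (16, 32, 64, 128, 256)  # stem..P5 channel progression

#: ablation variants, Table-style rows: (merca placement, dhtst, bifpn)
VARIANTS = {
    "baseline": ("none", False, False),
    "merca-backbone": ("backbone", False, False),
    "merca-neck": ("neck", False, False),
    "merca-all": ("all", False, False),
    "dhtst": ("none", True, False),
    "bifpn": ("none", False, True),
    "merca+dhtst": ("backbone", True, False),
    "merca+bifpn": ("backbone", False, True),
    "dhtst+bifpn": ("none", True, True),
    "lmtb": ("backbone", True, True),
}


def _csp_or_merca(use_merca: bool, c1, c2, **csp_kw):
    if use_merca:
        return MERCA(c1, c2)
    return C3k2(c1, c2, **csp_kw)


class PAFPNNeck(nn.Module):
    """Baseline path-aggregation neck over (P3, P4, P5)."""

    def __init__(self, channels=(128, 128, 256), merca: bool = False):
        super().__init__()
        c3, c4, c5 = channels
        self.up = nn.Upsample(2)
        self.td_p4 = _csp_or_merca(merca, c5 + c4, 128, n=1, c3k=False)
        self.td_p3 = _csp_or_merca(merca, 128 + c3, 64, n=1, c3k=False)
        self.down3 = Conv(64, 64, 3, 2)
        self.pan_p4 = _csp_or_merca(merca, 64 + 128, 128, n=1, c3k=False)
        self.down4 = Conv(128, 128, 3, 2)
        self.pan_p5 = _csp_or_merca(merca, 128 + c5, 256, n=1, c3k=True)

    def forward(self, levels):
        p3, p4, p5 = levels
        td4 = self.td_p4(Tensor.concat([self.up(p5), p4], axis=1))
        td3 = self.td_p3(Tensor.concat([self.up(td4), p3], axis=1))
        out4 = self.pan_p4(Tensor.concat([self.down3(td3), td4], axis=1))
        out5 = self.pan_p5(Tensor.concat([self.down4(out4), p5], axis=1))
        return td3, out4, out5


class DetectorGraph(nn.Module):
    """Full detector: backbone + neck + decoupled heads at strides 8/16/32."""

    strides = (8, 16, 32)

    def __init__(self, merca: str = "none", dhtst: bool = False,
                 bifpn: bool = False, nc: int = 1, scale: str = "n"):
        super().__init__()
        if scale != "n":
            raise ValueError(f"unknown scale preset {scale!r}; only 'n' (nano)")
        if merca not in ("none", "backbone", "neck", "all"):
            raise ValueError(f"bad merca placement {merca!r}")
        w1, w2, w3, w4, w5 = NANO_WIDTHS
        mb = merca in ("backbone", "all")
        self.nc = nc
        self.stem0 = Conv(3, w1, 3, 2)
        self.stem1 = Conv(w1, w2, 3, 2)
        self.stage2 = _csp_or_merca(mb, w2, w3, n=1, c3k=False, e=0.25)
        self.down3 = Conv(w3, w3, 3, 2)
        self.stage4 = _csp_or_merca(mb, w3, w4, n=1, c3k=False, e=0.25)
        self.down5 = Conv(w4, w4, 3, 2)
        self.stage6 = _csp_or_merca(mb, w4, w4, n=1, c3k=True)
        self.down7 = Conv(w4, w5, 3, 2)
        self.stage8 = _csp_or_merca(mb, w5, w5, n=1, c3k=True)
        self.sppf = SPPF(w5, w5, 5)
        self.psa = DHTST(w5) if dhtst else C2PSA(w5, w5, n=1)
        self.use_bifpn = bifpn
        if bifpn:
            self.neck = BiFPNNeck(channels=(w3, w4, w4, w5), width=64)
            head_ch = (64, 64, 64)
        else:
            self.neck = PAFPNNeck(channels=(w4, w4, w5),
                                  merca=merca in ("neck", "all"))
            head_ch = (64, 128, 256)
        self.head = Detect(nc=nc, ch=head_ch)
        self.head.strides = self.strides

    # -- forward --------------------------------------------------------
    def backbone(self, x):
        """Return pyramid taps (P2, P3, P4, P5) at strides 4/8/16/32."""
        from .functional import flop_audit

        def tag(name):
            a = flop_audit._active
            return _Tag(a, name)

        with tag("backbone"):
            x = self.stem1(self.stem0(x))
            p2 = self.stage2(x)
            p3 = self.stage4(self.down3(p2))
            p4 = self.stage6(self.down5(p3))
            x = self.stage8(self.down7(p4))
            p5 = self.psa(self.sppf(x))
        return p2, p3, p4, p5

    def forward(self, x):
        from .functional import flop_audit

        def tag(name):
            return _Tag(flop_audit._active, name)

        p2, p3, p4, p5 = self.backbone(x)
        with tag("neck"):
            feats = self.neck((p2, p3, p4, p5) if self.use_bifpn else (p3, p4, p5))
        with tag("head"):
            return self.head(list(feats))


class _Tag:
    def __init__(self, audit, name):
        self.audit, self.name = audit, name

    def __enter__(self):
        if self.audit is not None:
            self.audit.push_tag(self.name)

    def __exit__(self, *exc):
        if self.audit is not None:
            self.audit.pop_tag()
        return False


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------
def build_variant(name: str, nc: int = 1, scale: str = "n", seed: int | None = None) -> DetectorGraph:
    if name not in VARIANTS:
        raise ValueError(f"unknown variant {name!r}; choose from {sorted(VARIANTS)}")
    if seed is not None:
        nn.manual_seed(seed)
    merca, dhtst, bifpn = VARIANTS[name]
    return DetectorGraph(merca=merca, dhtst=dhtst, bifpn=bifpn, nc=nc, scale=scale)


def build_baseline(scale: str = "n", nc: int = 1, seed: int | None = None) -> DetectorGraph:
    """Unmodified nano reference graph (C3k2 / C2PSA / PAFPN)."""
    return build_variant("baseline", nc=nc, scale=scale, seed=seed)


def build_lmtb(scale: str = "n", nc: int = 1, seed: int | None = None) -> DetectorGraph:
    """Lightweight variant: MERCA backbone, DHTST, BiFPN with P2 injection."""
    return build_variant("lmtb", nc=nc, scale=scale, seed=seed)


# ---------------------------------------------------------------------------
# inference plumbing: DFL decode + NMS
# ---------------------------------------------------------------------------
def decode_predictions(preds, strides=(8, 16, 32), reg_max: int = 16,
                       conf_thresh: float = 0.25, img_size: int | None = None):
    """Decode raw head maps into (xyxy pixels, confidence, class) arrays.

    Box regression follows the distribution-focal convention: per side, a
    softmax over ``reg_max`` bins whose expectation gives the distance (in
    stride units) from the anchor cell centre.
    """
    rows = []
    for p, s in zip(preds, strides):
        arr = p.data if isinstance(p, Tensor) else np.asarray(p)
        B, C, H, W = arr.shape
        nc = C - 4 * reg_max
        box = arr[:, : 4 * reg_max].reshape(B, 4, reg_max, H * W)
        box = box - box.max(axis=2, keepdims=True)
        e = np.exp(box)
        dist = (e / e.sum(axis=2, keepdims=True) * np.arange(reg_max).reshape(1, 1, reg_max, 1)).sum(axis=2)
        cls = 1.0 / (1.0 + np.exp(-arr[:, 4 * reg_max :].reshape(B, nc, H * W)))
        gy, gx = np.mgrid[0:H, 0:W]
        cx, cy = (gx.ravel() + 0.5) * s, (gy.ravel() + 0.5) * s
        x1 = cx - dist[:, 0] * s
        y1 = cy - dist[:, 1] * s
        x2 = cx + dist[:, 2] * s
        y2 = cy + dist[:, 3] * s
        conf = cls.max(axis=1)
        cid = cls.argmax(axis=1)
        for b in range(B):
            keep = conf[b] >= conf_thresh
            rows.append(
                np.column_stack([
                    np.full(keep.sum(), b),
                    x1[b, keep], y1[b, keep], x2[b, keep], y2[b, keep],
                    conf[b, keep], cid[b, keep],
                ])
            )
    out = np.concatenate(rows, axis=0) if rows else np.zeros((0, 7))
    if img_size is not None:
        out[:, 1:5] = np.clip(out[:, 1:5], 0, img_size)
    return out


def nms(boxes: np.ndarray, scores: np.ndarray, iou_thresh: float = 0.45) -> np.ndarray:
    """Greedy non-maximum suppression; returns kept indices."""
    order = np.argsort(-scores)
    keep = []
    while order.size:
        i = order[0]
        keep.append(i)
        if order.size == 1:
            break
        rest = order[1:]
        xx1 = np.maximum(boxes[i, 0], boxes[rest, 0])
        yy1 = np.maximum(boxes[i, 1], boxes[rest, 1])
        xx2 = np.minimum(boxes[i, 2], boxes[rest, 2])
        yy2 = np.minimum(boxes[i, 3], boxes[rest, 3])
        inter = np.maximum(xx2 - xx1, 0) * np.maximum(yy2 - yy1, 0)
        a = (boxes[i, 2] - boxes[i, 0]) * (boxes[i, 3] - boxes[i, 1])
        b = (boxes[rest, 2] - boxes[rest, 0]) * (boxes[rest, 3] - boxes[rest, 1])
        iou = inter / np.maximum(a + b - inter, 1e-12)
        order = rest[iou <= iou_thresh]
    return np.asarray(keep, dtype=int)


def predict(model: DetectorGraph, image: np.ndarray, conf_thresh=0.25, iou_thresh=0.45):
    """Run one image (H, W, 3 uint8 or float) through the detector.

    Returns an (n, 6) array: x1, y1, x2, y2, confidence, class.
    """
    img = np.asarray(image, dtype=np.float32)
    if img.max() > 1.5:
        img = img / 255.0
    x = Tensor(img.transpose(2, 0, 1)[None])
    model.eval()
    with no_grad():
        preds = model(x)
    dets = decode_predictions(preds, model.strides, conf_thresh=conf_thresh,
                              img_size=img.shape[0])
    out = []
    for c in np.unique(dets[:, 6]) if len(dets) else []:
        sub = dets[dets[:, 6] == c]
        keep = nms(sub[:, 1:5], sub[:, 5], iou_thresh)
        out.append(sub[keep][:, 1:7])
    return np.concatenate(out, axis=0) if out else np.zeros((0, 6))
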