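"""Synthetic tea-scene generator, mosaic augmentation and dataset splitting.

Field imagery of young tea shoots has four properties that drive detector
design and that this generator reproduces: a wide linear size range within
one frame (tightly wrapped tips of a few millimetres next to partially
unfolded leaves several times larger), dense clustering with mutual
occlusion, low foreground/background contrast (green on green), and uneven
illumination.  Scenes are rendered as elongated bud-like ellipses over a
multi-octave green noise background, with tight normalised ``cx cy w h``
boxes in YOLO TXT format.  It is an emulation of that data regime, not a
photorealistic plant renderer.

All randomness flows from the seed in :class:`SceneSpec`, so every artefact
is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

__all__ = [
    "SceneSpec",
    "generate_scene",
    "mosaic_augment",
    "split_dataset",
    "write_yolo_labels",
    "read_yolo_labels",
    "generate_dataset",
]


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic tea scene.

    ``scale_spread`` is the ratio of the largest to the smallest target's
    linear size; the default 5 mirrors ~3-5 mm bud tips against ~2 cm young
    leaves.  ``contrast`` is the mean foreground-background lightness
    offset on the 0-255 scale (low values = camouflaged targets).
    ``occlusion`` in [0, 1] sets how strongly targets pile into clusters
    (and hence overlap); ``cluster_tightness`` the spatial spread of each
    cluster relative to the image; ``illumination`` the strength of a
    linear lighting ramp across the frame.
    """

    image_size: int = 640
    n_targets: int = 30
    min_size: int = 12  # smallest target's long side, px
    scale_spread: float = 5.0
    contrast: float = 22.0
    occlusion: float = 0.5
    n_clusters: int = 4
    cluster_tightness: float = 0.12
    illumination: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if self.n_targets < 0:
            raise ValueError("target count must be >= 0")
        if self.scale_spread < 1:
            raise ValueError("scale spread must be >= 1")
        if not (0 <= self.occlusion <= 1):
            raise ValueError("occlusion must be in [0, 1]")


def _smooth_noise(rng, size, octaves=(4, 8, 16, 32)):
    """Multi-octave value noise in [0, 1] (coarse grids, bilinear upsample)."""
    acc = np.zeros((size, size))
    amp_total = 0.0
    for i, g in enumerate(octaves):
        grid = rng.random((g, g))
        xs = np.linspace(0, g - 1, size)
        gi = np.floor(xs).astype(int)
        gi1 = np.minimum(gi + 1, g - 1)
        f = xs - gi
        rows = grid[gi][:, gi] * np.outer(1 - f, 1 - f) \
            + grid[gi][:, gi1] * np.outer(1 - f, f) \
            + grid[gi1][:, gi] * np.outer(f, 1 - f) \
            + grid[gi1][:, gi1] * np.outer(f, f)
        amp = 0.5 ** i
        acc += amp * rows
        amp_total += amp
    return acc / amp_total


def _render_background(rng, spec: SceneSpec) -> np.ndarray:
    s = spec.image_size
    tex = _smooth_noise(rng, s)
    # mature-foliage green band: darker and bluer than young shoots
    base = np.empty((s, s, 3))
    base[..., 0] = 46 + 28 * tex  # R
    base[..., 1] = 98 + 42 * tex  # G
    base[..., 2] = 40 + 24 * tex  # B
    return base


def _ellipse_mask(h, w, cy, cx, ry, rx, theta):
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    ct, st = math.cos(theta), math.sin(theta)
    u = (dx * ct + dy * st) / max(rx, 1e-6)
    v = (-dx * st + dy * ct) / max(ry, 1e-6)
    return u * u + v * v <= 1.0


def generate_scene(spec: SceneSpec):
    """Render one scene.

    Returns ``(image, annotations)`` where ``image`` is (S, S, 3) uint8 and
    ``annotations`` is an (n, 5) float array of ``cls cx cy w h`` rows in
    [0, 1].  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    s = spec.image_size
    img = _render_background(rng, spec)

    # cluster centres pulled toward the frame centre
    centres = rng.uniform(0.15 * s, 0.85 * s, size=(max(spec.n_clusters, 1), 2))

    # linear sizes: anchor the extremes so the configured spread is realised,
    # then log-uniform in between
    smin = float(spec.min_size)
    smax = smin * spec.scale_spread
    sizes = smin * spec.scale_spread ** rng.random(spec.n_targets)
    if spec.n_targets >= 2:
        sizes[0], sizes[1] = smin, smax

    anns = []
    for i in range(spec.n_targets):
        long_side = sizes[i]
        aspect = rng.uniform(2.2, 3.6)  # elongated bud silhouette
        ry, rx = long_side / 2.0, long_side / (2.0 * aspect)
        theta = rng.normal(0.0, 0.45)  # mostly vertical growth
        placed = False
        for _ in range(60):
            if rng.random() < spec.occlusion:
                c = centres[rng.integers(len(centres))]
                pos = c + rng.normal(0.0, spec.cluster_tightness * s, size=2)
            else:
                pos = rng.uniform(0, s, size=2)
            cy, cx = pos
            ext_x = abs(rx * math.cos(theta)) + abs(ry * math.sin(theta))
            ext_y = abs(rx * math.sin(theta)) + abs(ry * math.cos(theta))
            if ext_x <= cx <= s - ext_x and ext_y <= cy <= s - ext_y:
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place target {i} (size {long_side:.0f}px) in a "
                f"{s}px frame after 60 attempts; reduce target count or sizes"
            )
        mask = _ellipse_mask(s, s, cy, cx, ry, rx, theta)
        # young-shoot colour: same hue family, shifted lighter/yellower by
        # the (low) contrast parameter
        delta = spec.contrast * rng.uniform(0.7, 1.3)
        colour = np.array([46 + 0.9 * delta, 98 + delta, 40 + 0.25 * delta])
        colour += rng.normal(0, 3, size=3)
        alpha = 0.85
        img[mask] = (1 - alpha) * img[mask] + alpha * colour
        x1, x2 = cx - ext_x, cx + ext_x
        y1, y2 = cy - ext_y, cy + ext_y
        anns.append([0, (x1 + x2) / 2 / s, (y1 + y2) / 2 / s,
                     (x2 - x1) / s, (y2 - y1) / s])

    if spec.illumination > 0:
        ramp_dir = rng.uniform(0, 2 * math.pi)
        yy, xx = np.mgrid[0:s, 0:s]
        proj = (xx * math.cos(ramp_dir) + yy * math.sin(ramp_dir)) / s
        proj = (proj - proj.min()) / max(proj.max() - proj.min(), 1e-9)
        img *= (1 - spec.illumination / 2 + spec.illumination * proj)[..., None]

    img = np.clip(img, 0, 255).astype(np.uint8)
    anns = np.asarray(anns, dtype=np.float64).reshape(-1, 5)
    return img, anns


# ---------------------------------------------------------------------------
# mosaic augmentation
# ---------------------------------------------------------------------------
def mosaic_augment(samples, seed: int, min_side_px: float = 2.0):
    """2x2 mosaic collage of four (image, annotations) samples.

    The collage centre is drawn uniformly from the central 40% of the
    canvas; each source image is translated so its far corner meets the
    centre, labels are translated and clipped to their quadrant, and boxes
    whose clipped width or height falls below ``min_side_px`` are dropped.
    """
    if len(samples) != 4:
        raise ValueError("mosaic needs exactly 4 samples")
    sizes = {im.shape for im, _ in samples}
    if len(sizes) != 1:
        raise ValueError("mosaic samples must share a canvas size")
    s = samples[0][0].shape[0]
    rng = np.random.default_rng(seed)
    xc = int(rng.uniform(0.3 * s, 0.7 * s))
    yc = int(rng.uniform(0.3 * s, 0.7 * s))
    canvas = np.zeros_like(samples[0][0])
    # per quadrant: translation of the source image and the visible rect
    layout = [
        ((xc - s, yc - s), (0, 0, xc, yc)),      # top-left
        ((xc, yc - s), (xc, 0, s, yc)),          # top-right
        ((xc - s, yc), (0, yc, xc, s)),          # bottom-left
        ((xc, yc), (xc, yc, s, s)),              # bottom-right
    ]
    out = []
    for (img, anns), ((dx, dy), (qx1, qy1, qx2, qy2)) in zip(samples, layout):
        sx1, sy1 = qx1 - dx, qy1 - dy
        canvas[qy1:qy2, qx1:qx2] = img[sy1 : sy1 + (qy2 - qy1), sx1 : sx1 + (qx2 - qx1)]
        for cls, cx, cy, w, h in np.asarray(anns).reshape(-1, 5):
            x1 = cx * s - w * s / 2 + dx
            y1 = cy * s - h * s / 2 + dy
            x2 = x1 + w * s
            y2 = y1 + h * s
            x1, x2 = max(x1, qx1), min(x2, qx2)
            y1, y2 = max(y1, qy1), min(y2, qy2)
            if x2 - x1 < min_side_px or y2 - y1 < min_side_px:
                continue
            out.append([cls, (x1 + x2) / 2 / s, (y1 + y2) / 2 / s,
                        (x2 - x1) / s, (y2 - y1) / s])
    return canvas, np.asarray(out, dtype=np.float64).reshape(-1, 5)


# ---------------------------------------------------------------------------
# dataset splitting and label I/O
# ---------------------------------------------------------------------------
def split_dataset(items, ratios=(0.7, 0.2, 0.1), seed: int = 0):
    """Seed-deterministic disjoint (train, test, val) split.

    Counts use floor for the train and val partitions with the remainder
    assigned to test, which reproduces 3062 -> 2143/613/306 at 7:2:1.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    items = list(items)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(items))
    n = len(items)
    n_train = int(n * ratios[0])
    n_val = int(n * ratios[2])
    n_test = n - n_train - n_val
    train = [items[i] for i in order[:n_train]]
    test = [items[i] for i in order[n_train : n_train + n_test]]
    val = [items[i] for i in order[n_train + n_test :]]
    return train, test, val


def write_yolo_labels(path, anns):
    lines = [
        f"{int(c)} {cx:.9f} {cy:.9f} {w:.9f} {h:.9f}"
        for c, cx, cy, w, h in np.asarray(anns).reshape(-1, 5)
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_yolo_labels(path) -> np.ndarray:
    rows = []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if parts:
            rows.append([float(parts[0])] + [float(v) for v in parts[1:5]])
    return np.asarray(rows, dtype=np.float64).reshape(-1, 5)


def generate_dataset(out_dir, n: int, seed: int = 0, spec: SceneSpec | None = None,
                     ratios=(0.7, 0.2, 0.1)):
    """Render ``n`` scenes, write PNG+TXT pairs and a split manifest."""
    from PIL import Image
    import yaml

    base = spec or SceneSpec()
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "labels").mkdir(parents=True, exist_ok=True)
    names = []
    for i in range(n):
        sc = replace(base, seed=seed + i)
        img, anns = generate_scene(sc)
        name = f"scene_{i:05d}"
        Image.fromarray(img).save(out / "images" / f"{name}.png")
        write_yolo_labels(out / "labels" / f"{name}.txt", anns)
        names.append(name)
    train, test, val = split_dataset(names, ratios, seed)
    manifest = {
        "classes": ["tea_bud"],
        "seed": seed,
        "n": n,
        "splits": {"train": sorted(train), "test": sorted(test), "val": sorted(val)},
    }
    (out / "dataset.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return manifest
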