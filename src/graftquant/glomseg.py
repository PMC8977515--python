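"""Glomerulus mask production: polygon-annotation rasterization, the
tile / predict / stitch / threshold harness around a pluggable segmenter,
and a scaled-down trainable per-pixel classifier.

The harness is segmenter-agnostic: any callable mapping an RGB tile to a
same-shaped probability map (probability of "inside a glomerulus") plugs in.
Whole-slide inference tiles the image at ``infer_tile`` with stride
``infer_step`` (edge tiles padded by reflection), takes the per-pixel
maximum over overlapping predictions, thresholds strictly above
``prob_threshold`` and labels connected components as glomerulus instances.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
from PIL import Image, ImageDraw
from scipy import ndimage

from .geometry import RegionMask, _structure

__all__ = [
    "TileSpec", "TrainConfig", "read_labelme_annotations", "rasterize_polygons",
    "tile_image", "stitch_probability", "prob_to_glomerulus_mask",
    "segment_slide", "oracle_probability_map", "learning_rate",
    "PixelSoftmaxSegmenter", "train_segmenter",
]


@dataclass
class TileSpec:
    train_tile: tuple[int, int] = (768, 768)
    infer_tile: tuple[int, int] = (1024, 1024)
    infer_step: tuple[int, int] = (768, 768)
    prob_threshold: float = 0.5

    def __post_init__(self) -> None:
        if any(s > t for s, t in zip(self.infer_step, self.infer_tile)):
            raise ValueError("infer_step must not exceed infer_tile")
        if not 0 < self.prob_threshold < 1:
            raise ValueError("prob_threshold must be in (0, 1)")


# ---------------------------------------------------------------------------
# Annotations

def read_labelme_annotations(path: str | Path) -> list[np.ndarray]:
    """Polygon point lists (x, y pixel coordinates) from a LabelMe-style JSON."""
    data = json.loads(Path(path).read_text())
    polys = []
    for shape in data.get("shapes", []):
        if shape.get("shape_type", "polygon") != "polygon":
            continue
        polys.append(np.asarray(shape["points"], dtype=float))
    return polys


def rasterize_polygons(
    polygons: Sequence[np.ndarray],
    image_shape: tuple[int, int],
    px_per_micron: float = 2.3,
) -> RegionMask:
    """Rasterize annotation polygons to a labeled instance mask.

    Each polygon becomes one labeled instance (label = 1-based list index);
    fill is even-odd with boundary pixels counted inside. Self-intersecting
    polygons are rejected; polygons extending beyond the image are clipped
    with a warning.
    """
    from shapely.geometry import LinearRing

    h, w = image_shape[:2]
    canvas = Image.new("I", (w, h), 0)
    draw = ImageDraw.Draw(canvas)
    for idx, poly in enumerate(polygons):
        pts = np.asarray(poly, dtype=float)
        if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 2:
            raise ValueError(f"shape {idx}: polygon needs >= 3 (x, y) points")
        if not LinearRing(pts).is_simple:
            raise ValueError(f"shape {idx}: polygon is self-intersecting")
        if pts[:, 0].min() < 0 or pts[:, 1].min() < 0 or \
           pts[:, 0].max() > w - 1 or pts[:, 1].max() > h - 1:
            warnings.warn(f"shape {idx}: polygon extends beyond image; clipped")
        xy = [(float(x), float(y)) for x, y in pts]
        draw.polygon(xy, fill=idx + 1, outline=idx + 1)
    labels = np.asarray(canvas, dtype=np.int32)
    return RegionMask(labels=labels, px_per_micron=px_per_micron)


# ---------------------------------------------------------------------------
# Tiling and stitching

def _starts(length: int, tile: int, step: int) -> list[int]:
    starts, s = [], 0
    while True:
        starts.append(s)
        if s + tile >= length:
            break
        s += step
    return starts


def tile_image(image: np.ndarray, spec: TileSpec | None = None):
    """Cut an image into ``infer_tile`` tiles at ``infer_step`` strides.

    Edge tiles extending past the image are padded by reflection. Returns a
    list of ``(tile, (y0, x0))`` with origins in un-padded image coordinates;
    every image pixel is covered by at least one tile.
    """
    spec = spec or TileSpec()
    image = np.asarray(image)
    h, w = image.shape[:2]
    th, tw = spec.infer_tile
    sy, sx = spec.infer_step
    pad_h, pad_w = max(0, th - h), max(0, tw - w)
    ys, xs = _starts(h, th, sy), _starts(w, tw, sx)
    need_h = max(y + th for y in ys) - h
    need_w = max(x + tw for x in xs) - w
    pad = [(0, max(need_h, 0)), (0, max(need_w, 0))] + [(0, 0)] * (image.ndim - 2)
    padded = np.pad(image, pad, mode="reflect") if (need_h > 0 or need_w > 0) else image
    return [(padded[y:y + th, x:x + tw], (y, x)) for y in ys for x in xs]


def stitch_probability(
    tiles: Sequence[tuple[np.ndarray, tuple[int, int]]],
    image_shape: tuple[int, int],
) -> np.ndarray:
    """Recompose tile probability maps: overlaps resolve to the maximum.

    Tile regions beyond ``image_shape`` (padding) are cropped away. Raises
    if any pixel ends up uncovered (violated tiling contract).
    """
    h, w = image_shape[:2]
    out = np.zeros((h, w), dtype=float)
    covered = np.zeros((h, w), dtype=bool)
    for prob, (y0, x0) in tiles:
        prob = np.asarray(prob, dtype=float)
        if prob.min() < 0 or prob.max() > 1:
            raise ValueError("probability map values outside [0, 1]")
        y1 = min(y0 + prob.shape[0], h)
        x1 = min(x0 + prob.shape[1], w)
        crop = prob[: y1 - y0, : x1 - x0]
        region = out[y0:y1, x0:x1]
        np.maximum(region, crop, out=region)
        covered[y0:y1, x0:x1] = True
    if not covered.all():
        raise RuntimeError("stitching left uncovered pixels; tiling contract violated")
    return out


def prob_to_glomerulus_mask(
    prob_map: np.ndarray,
    spec: TileSpec | None = None,
    biopsy_mask: Optional[RegionMask] = None,
    px_per_micron: float = 2.3,
    connectivity: int = 8,
) -> RegionMask:
    """Threshold a probability map (strictly above ``prob_threshold``) and
    label connected components as glomerulus instances, optionally clipped to
    the biopsy tissue mask so compartment areas partition the tissue."""
    spec = spec or TileSpec()
    prob_map = np.asarray(prob_map, dtype=float)
    fg = prob_map > spec.prob_threshold
    if biopsy_mask is not None:
        fg &= biopsy_mask.binary()
    labels, _ = ndimage.label(fg, structure=_structure(connectivity))
    return RegionMask(labels=labels.astype(np.int32), px_per_micron=px_per_micron)


def segment_slide(
    image: np.ndarray,
    segmenter: Callable[[np.ndarray], np.ndarray],
    spec: TileSpec | None = None,
) -> np.ndarray:
    """Tile -> predict -> max-stitch. Returns the full-slide probability map."""
    spec = spec or TileSpec()
    tiles = tile_image(image, spec)
    preds = [(segmenter(tile), origin) for tile, origin in tiles]
    return stitch_probability(preds, image.shape[:2])


def oracle_probability_map(glom_mask: RegionMask) -> np.ndarray:
    """Ground-truth probability map (1 inside annotated glomeruli, else 0).

    Tiling this map through :func:`tile_image` and stitching the tiles back
    is the oracle path used to validate the harness independently of any
    trained model."""
    return glom_mask.binary().astype(float)


# ---------------------------------------------------------------------------
# Scaled-down trainable segmenter

@dataclass
class TrainConfig:
    """Training schedule for the per-pixel classifier.

    Three target channels partition each training tile: inside-glomerulus,
    glomerulus contour, and outside. The loss is softmax cross-entropy,
    optimized with Adam at ``lr_initial`` through ``lr_switch_epoch`` epochs
    and ``lr_late`` afterwards, up to ``n_epochs``.
    """

    n_epochs: int = 150
    lr_initial: float = 1e-3
    lr_late: float = 1e-4
    lr_switch_epoch: int = 100
    n_train_images: int = 30
    batches_per_epoch: int = 50
    batch_px: int = 4096
    blur_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr_initial <= 0 or self.lr_late <= 0:
            raise ValueError("learning rates must be positive")
        if self.n_epochs < 0 or self.lr_switch_epoch <= 0:
            raise ValueError("epochs must be positive")


def learning_rate(epoch: int, cfg: TrainConfig | None = None) -> float:
    """Learning rate for a 1-based epoch index under the two-phase schedule."""
    cfg = cfg or TrainConfig()
    return cfg.lr_initial if epoch <= cfg.lr_switch_epoch else cfg.lr_late


def _features(image: np.ndarray, blur_sigma: float) -> np.ndarray:
    """Per-pixel feature stack: RGB, Gaussian-blurred RGB, bias (all in 0-1)."""
    rgb = np.asarray(image, dtype=float) / 255.0
    if rgb.ndim == 2:
        rgb = np.stack([rgb] * 3, axis=-1)
    blurred = np.stack(
        [ndimage.gaussian_filter(rgb[..., c], blur_sigma) for c in range(3)], axis=-1
    )
    ones = np.ones(rgb.shape[:2] + (1,))
    return np.concatenate([rgb, blurred, ones], axis=-1)


class PixelSoftmaxSegmenter:
    """Per-pixel 3-class softmax classifier over local colour features.

    Channel 0 is inside-glomerulus; ``__call__`` returns that channel's
    probability map for a tile, fulfilling the pluggable-segmenter contract.
    """

    N_FEATURES = 7
    N_CLASSES = 3  # inside, contour, outside

    def __init__(self, weights: Optional[np.ndarray] = None, blur_sigma: float = 2.0,
                 feat_mean: Optional[np.ndarray] = None,
                 feat_std: Optional[np.ndarray] = None):
        self.weights = (np.zeros((self.N_FEATURES, self.N_CLASSES))
                        if weights is None else weights)
        self.blur_sigma = blur_sigma
        self.feat_mean = np.zeros(self.N_FEATURES) if feat_mean is None else feat_mean
        self.feat_std = np.ones(self.N_FEATURES) if feat_std is None else feat_std

    def probabilities(self, tile: np.ndarray) -> np.ndarray:
        feats = (_features(tile, self.blur_sigma) - self.feat_mean) / self.feat_std
        logits = feats @ self.weights
        logits -= logits.max(axis=-1, keepdims=True)
        exp = np.exp(logits)
        return exp / exp.sum(axis=-1, keepdims=True)

    def __call__(self, tile: np.ndarray) -> np.ndarray:
        return self.probabilities(tile)[..., 0]


def _target_channels(mask_binary: np.ndarray) -> np.ndarray:
    """Class index map: 0 inside, 1 contour (1-px band), 2 outside."""
    inside = mask_binary.astype(bool)
    dil = ndimage.binary_dilation(inside, structure=_structure(8))
    ero = ndimage.binary_erosion(inside, structure=_structure(8))
    contour = dil & ~ero
    target = np.full(mask_binary.shape, 2, dtype=np.int8)
    target[inside] = 0
    target[contour] = 1
    return target


def train_segmenter(
    images: Sequence[np.ndarray],
    masks: Sequence[np.ndarray],
    cfg: TrainConfig | None = None,
) -> PixelSoftmaxSegmenter:
    """Fit the per-pixel softmax classifier with Adam + cross-entropy.

    ``masks`` are binary (inside-glomerulus) rasters matching each image.
    With ``n_epochs=0`` the initialized (uniform-probability) model is
    returned, so the surrounding harness still runs end to end.
    """
    cfg = cfg or TrainConfig()
    if len(images) != len(masks):
        raise ValueError("images and masks must pair up")
    feats, targets = [], []
    for img, msk in zip(images, masks):
        img = np.asarray(img)
        msk = np.asarray(msk)
        if img.shape[:2] != msk.shape[:2]:
            raise ValueError(
                f"image shape {img.shape[:2]} != mask shape {msk.shape[:2]}")
        feats.append(_features(img, cfg.blur_sigma).reshape(-1, PixelSoftmaxSegmenter.N_FEATURES))
        targets.append(_target_channels(msk > 0).reshape(-1))
    X = np.concatenate(feats)
    y = np.concatenate(targets)
    # standardize features on the training set (bias column keeps std 1)
    feat_mean = X.mean(axis=0)
    feat_std = X.std(axis=0)
    feat_mean[-1], feat_std[-1] = 0.0, 1.0
    feat_std[feat_std == 0] = 1.0
    model = PixelSoftmaxSegmenter(blur_sigma=cfg.blur_sigma,
                                  feat_mean=feat_mean, feat_std=feat_std)
    if cfg.n_epochs == 0:
        return model
    X = (X - feat_mean) / feat_std
    rng = np.random.default_rng(cfg.seed)
    W = model.weights
    m = np.zeros_like(W)
    v = np.zeros_like(W)
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    onehot = np.eye(PixelSoftmaxSegmenter.N_CLASSES)
    # classes are wildly imbalanced (glomeruli are a small tissue fraction),
    # so minibatches are stratified: equal pixel counts per present class
    class_idx = [np.nonzero(y == k)[0] for k in range(PixelSoftmaxSegmenter.N_CLASSES)]
    class_idx = [ix for ix in class_idx if len(ix)]
    per_class = max(1, cfg.batch_px // max(len(class_idx), 1))
    for epoch in range(1, cfg.n_epochs + 1):
        lr = learning_rate(epoch, cfg)
        for _ in range(cfg.batches_per_epoch):
            t += 1
            idx = np.concatenate([ix[rng.integers(0, len(ix), size=per_class)]
                                  for ix in class_idx])
            xb, yb = X[idx], y[idx]
            logits = xb @ W
            logits -= logits.max(axis=1, keepdims=True)
            exp = np.exp(logits)
            probs = exp / exp.sum(axis=1, keepdims=True)
            grad = xb.T @ (probs - onehot[yb]) / len(xb)
            m = beta1 * m + (1 - beta1) * grad
            v = beta2 * v + (1 - beta2) * grad**2
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            W -= lr * mhat / (np.sqrt(vhat) + eps)
    model.weights = W
    return model
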