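"""Paired RGB-D augmentation: eight stages applied jointly to color,
depth, and boxes.

The pipeline (ToSensor, PhotometricDistort, Expand, RandomSampleCrop,
RandomMirror, ToPercentCoords, Resize, SubtractMeans) is the canonical
single-shot-detector recipe extended to a registered depth channel:
every geometric stage transforms RGB and depth with identical
parameters, while photometric jitter touches the color channel only.
Depth is expected in [0, 1] (near..far normalized); pad/fill values for
depth are the far plane (1.0).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage.transform import resize as _sk_resize

__all__ = [
    "Sample",
    "AugmentConfig",
    "to_sensor",
    "photometric_distort",
    "expand",
    "random_sample_crop",
    "random_mirror",
    "to_percent_coords",
    "resize",
    "subtract_means",
    "augment",
    "materialize_augmented_copies",
    "channel_means",
]

from .geometry import iou_matrix


@dataclass
class Sample:
    """One training example moving through the pipeline.

    Boxes are corner-form; ``coord_mode`` says whether they are absolute
    pixels or fractions of the image.
    """

    rgb: np.ndarray                  # (H, W, 3) float
    depth: np.ndarray                # (H, W) float
    boxes: np.ndarray                # (n, 4)
    labels: np.ndarray               # (n,)
    coord_mode: str = "absolute"     # 'absolute' | 'percent'

    def __post_init__(self):
        if self.rgb.shape[:2] != self.depth.shape:
            raise ValueError("rgb and depth must share H x W")
        b = np.asarray(self.boxes, dtype=float).reshape(-1, 4)
        if len(b) and ((b[:, 2] <= b[:, 0]).any()
                       or (b[:, 3] <= b[:, 1]).any()):
            raise ValueError("degenerate box")
        if len(b) != len(self.labels):
            raise ValueError("boxes and labels must align")
        self.boxes = b
        self.labels = np.asarray(self.labels, dtype=np.intp)

    @property
    def rgb_chw(self) -> np.ndarray:
        return np.ascontiguousarray(self.rgb.transpose(2, 0, 1))

    @property
    def depth_chw(self) -> np.ndarray:
        return self.depth[None, :, :]

    def copy(self) -> "Sample":
        return Sample(self.rgb.copy(), self.depth.copy(), self.boxes.copy(),
                      self.labels.copy(), self.coord_mode)


@dataclass(frozen=True)
class AugmentConfig:
    """Stage parameters; the stochastic-stage defaults follow the
    standard SSD recipe (the stage names fix the recipe, not the knobs)."""

    expand_max_ratio: float = 4.0
    expand_prob: float = 0.5
    crop_min_ious: tuple = (0.1, 0.3, 0.5, 0.7, 0.9)
    mirror_prob: float = 0.5
    brightness_delta: float = 32.0
    contrast_range: tuple = (0.5, 1.5)
    saturation_range: tuple = (0.5, 1.5)
    hue_delta: float = 18.0
    rgb_means: tuple = (50.0, 91.0, 27.0)
    depth_mean: float = 0.90
    depth_fill: float = 1.0
    size: int = 300


def to_sensor(rgb: np.ndarray, depth: np.ndarray, boxes, labels,
              depth_range: tuple | None = None) -> Sample:
    """Numeric conversion: float arrays, depth normalized to [0, 1] when a
    (near, far) millimeter range is given."""
    d = np.asarray(depth, dtype=np.float64)
    if depth_range is not None:
        near, far = depth_range
        d = np.clip((d - near) / (far - near), 0.0, 1.0)
    return Sample(np.asarray(rgb, dtype=np.float64), d,
                  np.asarray(boxes, dtype=float).reshape(-1, 4),
                  np.asarray(labels), "absolute")


# -- photometric -----------------------------------------------------------

def _rgb_to_hsv(rgb01: np.ndarray) -> np.ndarray:
    from skimage.color import rgb2hsv
    return rgb2hsv(np.clip(rgb01, 0, 1))


def _hsv_to_rgb(hsv: np.ndarray) -> np.ndarray:
    from skimage.color import hsv2rgb
    return hsv2rgb(np.clip(hsv, 0, 1) * [1.0, 1.0, 1.0])


def photometric_distort(s: Sample, rng: np.random.Generator,
                        cfg: AugmentConfig = AugmentConfig()) -> Sample:
    """Random brightness/contrast/saturation/hue jitter on RGB only.

    Depth and boxes pass through untouched; output clipped to [0, 255].
    All-zero jitter magnitudes give the identity.
    """
    rgb = s.rgb.astype(np.float64)
    if cfg.brightness_delta > 0 and rng.random() < 0.5:
        rgb = rgb + rng.uniform(-cfg.brightness_delta, cfg.brightness_delta)
    if cfg.contrast_range != (1.0, 1.0) and rng.random() < 0.5:
        rgb = rgb * rng.uniform(*cfg.contrast_range)
    if (cfg.saturation_range != (1.0, 1.0) or cfg.hue_delta > 0) \
            and rng.random() < 0.5:
        hsv = _rgb_to_hsv(np.clip(rgb, 0, 255) / 255.0)
        if cfg.saturation_range != (1.0, 1.0):
            hsv[..., 1] = np.clip(hsv[..., 1]
                                  * rng.uniform(*cfg.saturation_range), 0, 1)
        if cfg.hue_delta > 0:
            hsv[..., 0] = (hsv[..., 0]
                           + rng.uniform(-cfg.hue_delta, cfg.hue_delta)
                           / 360.0) % 1.0
        rgb = _hsv_to_rgb(hsv) * 255.0
    out = s.copy()
    out.rgb = np.clip(rgb, 0.0, 255.0)
    return out


# -- geometric -------------------------------------------------------------

def expand(s: Sample, rng: np.random.Generator, max_ratio: float = 4.0,
           rgb_fill=(50.0, 91.0, 27.0), depth_fill: float = 1.0,
           prob: float = 1.0) -> Sample:
    """Paste both channels at a random offset onto an enlarged canvas.

    The canvas scale r is uniform in [1, max_ratio]; RGB is filled with
    the dataset channel means and depth with the far value; boxes are
    translated by the chosen offset.
    """
    if max_ratio < 1:
        raise ValueError("max_ratio must be >= 1")
    if s.coord_mode != "absolute":
        raise ValueError("expand requires absolute coordinates")
    if rng.random() >= prob:
        return s.copy()
    h, w = s.depth.shape
    r = rng.uniform(1.0, max_ratio)
    nh, nw = int(h * r), int(w * r)
    top = int(rng.uniform(0, nh - h + 1))
    left = int(rng.uniform(0, nw - w + 1))
    rgb = np.empty((nh, nw, 3), dtype=s.rgb.dtype)
    rgb[...] = np.asarray(rgb_fill, dtype=s.rgb.dtype)
    depth = np.full((nh, nw), depth_fill, dtype=s.depth.dtype)
    rgb[top:top + h, left:left + w] = s.rgb
    depth[top:top + h, left:left + w] = s.depth
    boxes = s.boxes + np.array([left, top, left, top], dtype=float)
    return Sample(rgb, depth, boxes, s.labels.copy(), "absolute")


def random_sample_crop(s: Sample, rng: np.random.Generator,
                       min_ious: tuple = (0.1, 0.3, 0.5, 0.7, 0.9),
                       max_trials: int = 50) -> Sample:
    """SSD-style random crop.

    A mode is drawn from {no-crop, each minimum-IoU constraint,
    unconstrained}; candidate windows keep boxes whose centers fall
    inside and must overlap each kept box by at least the sampled
    minimum IoU.  Bounded retries fall back to no-crop.
    """
    if s.coord_mode != "absolute":
        raise ValueError("crop requires absolute coordinates")
    modes: list = [None, *min_ious, "any"]
    mode = modes[rng.integers(len(modes))]
    if mode is None or len(s.boxes) == 0:
        return s.copy()
    min_iou = 0.0 if mode == "any" else float(mode)
    h, w = s.depth.shape
    for _ in range(max_trials):
        cw = rng.uniform(0.3, 1.0) * w
        ch = rng.uniform(0.3, 1.0) * h
        if not 0.5 <= cw / ch <= 2.0:
            continue
        left = rng.uniform(0, w - cw)
        top = rng.uniform(0, h - ch)
        rect = np.array([left, top, left + cw, top + ch])
        centers = (s.boxes[:, :2] + s.boxes[:, 2:]) / 2.0
        inside = ((centers[:, 0] > rect[0]) & (centers[:, 0] < rect[2])
                  & (centers[:, 1] > rect[1]) & (centers[:, 1] < rect[3]))
        if not inside.any():
            continue
        overlap = iou_matrix(rect, s.boxes[inside])[0]
        if (overlap < min_iou).any():
            continue
        li, ti = int(round(left)), int(round(top))
        ri, bi = int(round(left + cw)), int(round(top + ch))
        boxes = s.boxes[inside].copy()
        boxes[:, 0::2] = boxes[:, 0::2].clip(li, ri) - li
        boxes[:, 1::2] = boxes[:, 1::2].clip(ti, bi) - ti
        return Sample(s.rgb[ti:bi, li:ri].copy(),
                      s.depth[ti:bi, li:ri].copy(),
                      boxes, s.labels[inside].copy(), "absolute")
    return s.copy()


def random_mirror(s: Sample, rng: np.random.Generator, prob: float = 0.5,
                  force: bool | None = None) -> Sample:
    """Horizontal flip of both channels with probability ``prob``;
    ``force`` pins the coin for tests."""
    flip = force if force is not None else bool(rng.random() < prob)
    if not flip:
        return s.copy()
    width = 1.0 if s.coord_mode == "percent" else s.depth.shape[1]
    boxes = s.boxes.copy()
    boxes[:, 0], boxes[:, 2] = width - s.boxes[:, 2], width - s.boxes[:, 0]
    return Sample(s.rgb[:, ::-1].copy(), s.depth[:, ::-1].copy(),
                  boxes, s.labels.copy(), s.coord_mode)


def to_percent_coords(s: Sample) -> Sample:
    if s.coord_mode == "percent":
        return s.copy()
    h, w = s.depth.shape
    boxes = s.boxes / np.array([w, h, w, h], dtype=float)
    return Sample(s.rgb.copy(), s.depth.copy(), boxes, s.labels.copy(),
                  "percent")


def resize(s: Sample, size: int = 300) -> Sample:
    """Bilinear resize of both channels to size x size; percent boxes are
    scale-free, absolute boxes are rescaled."""
    h, w = s.depth.shape
    rgb = _sk_resize(s.rgb, (size, size), order=1, preserve_range=True,
                     anti_aliasing=False)
    depth = _sk_resize(s.depth, (size, size), order=1, preserve_range=True,
                       anti_aliasing=False)
    boxes = s.boxes.copy()
    if s.coord_mode == "absolute" and len(boxes):
        boxes *= np.array([size / w, size / h, size / w, size / h])
    return Sample(rgb, depth, boxes, s.labels.copy(), s.coord_mode)


def subtract_means(s: Sample, rgb_means=(50.0, 91.0, 27.0),
                   depth_mean: float = 0.90) -> Sample:
    out = s.copy()
    out.rgb = s.rgb - np.asarray(rgb_means, dtype=float)
    out.depth = s.depth - float(depth_mean)
    return out


def augment(s: Sample, rng: np.random.Generator,
            cfg: AugmentConfig = AugmentConfig(),
            deterministic: bool = False) -> Sample:
    """Compose the eight stages in order.

    ``deterministic`` pins every stochastic stage to the identity,
    leaving the deterministic normalize + resize path (used when
    overfitting tiny training sets and at evaluation time).
    """
    out = s.copy()  # stage 1, ToSensor, happens at construction
    if not deterministic:
        out = photometric_distort(out, rng, cfg)
        out = expand(out, rng, cfg.expand_max_ratio,
                     rgb_fill=cfg.rgb_means, depth_fill=cfg.depth_fill,
                     prob=cfg.expand_prob)
        out = random_sample_crop(out, rng, cfg.crop_min_ious)
        out = random_mirror(out, rng, cfg.mirror_prob)
    out = to_percent_coords(out)
    out = resize(out, cfg.size)
    out = subtract_means(out, cfg.rgb_means, cfg.depth_mean)
    return out


def materialize_augmented_copies(s: Sample, k: int,
                                 rng: np.random.Generator,
                                 cfg: AugmentConfig = AugmentConfig()
                                 ) -> list[Sample]:
    """Dataset-expansion mode: k independently augmented copies of one
    sample (the alternative reading of 'eight transformed versions')."""
    return [augment(s, rng, cfg) for _ in range(k)]


def channel_means(samples: list[Sample]) -> tuple:
    """Per-channel RGB means and the depth mean over a list of samples."""
    rgb = np.mean([s.rgb.reshape(-1, 3).mean(axis=0) for s in samples],
                  axis=0)
    depth = float(np.mean([s.depth.mean() for s in samples]))
    return tuple(float(v) for v in rgb), depth
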