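"""Prior-box (default-box) geometry for the dual-branch detector.

Each detection feature map tiles the image with a fixed menu of anchor
rectangles ("prior boxes"): at every cell center one small square, one
square at the geometric mean of this layer's and the next layer's scale,
and a width/height-swapped pair for every aspect ratio above 1.  The RGB
and depth branches each carry the full 6-layer, 8,732-box set; the fused
detector concatenates the two sets into 17,464 priors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LayerSpec",
    "PriorBoxSet",
    "layer_specs_300",
    "scale_fraction",
    "generate_priors",
    "map_to_image",
    "fuse",
]


@dataclass(frozen=True)
class LayerSpec:
    """One detection layer: grid resolution, pixel scales, aspect-ratio menu."""

    grid: int
    min_size: float
    max_size: float
    aspect_ratios: tuple = (1.0, 2.0, 0.5)

    def __post_init__(self):
        if self.grid < 1:
            raise ValueError("grid must be positive")
        if not self.min_size < self.max_size:
            raise ValueError("min_size must be < max_size")
        allowed = {1.0, 2.0, 3.0, 0.5, 1.0 / 3.0}
        if not set(self.aspect_ratios) <= allowed:
            raise ValueError(f"aspect ratios must be within {sorted(allowed)}")

    @property
    def boxes_per_location(self) -> int:
        # 2 squares + a (w,h)/(h,w) pair per ratio above 1
        return 2 + 2 * sum(1 for r in self.aspect_ratios if r > 1)


@dataclass
class PriorBoxSet:
    """Ordered normalized priors in center form (cx, cy, w, h)."""

    boxes: np.ndarray                 # (N, 4) center-form, clamped to [0, 1]
    branch: str                       # 'rgb' | 'depth' | 'fused'
    layer_index: np.ndarray           # (N,) int
    image_size: int = 300
    specs: tuple = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.boxes)

    @property
    def corner(self) -> np.ndarray:
        """Corner-form view (x_min, y_min, x_max, y_max), clamped to [0, 1]."""
        cx, cy, w, h = self.boxes.T
        corners = np.stack(
            [cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2], axis=1)
        return np.clip(corners, 0.0, 1.0)

    def to_tsv(self, path) -> None:
        """Dump (layer, cx, cy, w, h) rows for inspection."""
        with open(path, "w") as fh:
            fh.write("layer\tcx\tcy\tw\th\n")
            for layer, (cx, cy, w, h) in zip(self.layer_index, self.boxes):
                fh.write(f"{layer}\t{cx:.6f}\t{cy:.6f}\t{w:.6f}\t{h:.6f}\n")


_RATIOS_SMALL = (1.0, 2.0, 0.5)
_RATIOS_FULL = (1.0, 2.0, 3.0, 0.5, 1.0 / 3.0)


def layer_specs_300() -> list[LayerSpec]:
    """The six-layer schedule of the 300x300 detector.

    Grids 38..1 with pixel scale pairs (30,60), (60,111), (111,162),
    (162,213), (213,264), (264,315); the middle four layers add the
    3:1 / 1:3 ratios for 6 boxes per location, the rest carry 4.
    """
    return [
        LayerSpec(38, 30, 60, _RATIOS_SMALL),
        LayerSpec(19, 60, 111, _RATIOS_FULL),
        LayerSpec(10, 111, 162, _RATIOS_FULL),
        LayerSpec(5, 162, 213, _RATIOS_FULL),
        LayerSpec(3, 213, 264, _RATIOS_SMALL),
        LayerSpec(1, 264, 315, _RATIOS_SMALL),
    ]


def scale_fraction(k: int, m: int, s_min: float = 0.2,
                   s_max: float = 0.9) -> float:
    """Linear scale schedule s_k = s_min + (s_max - s_min)/(m - 1) * (k - 1).

    ``k`` is 1-based; ``m`` is the number of detection layers.  Exposed on
    its own terms: the pixel schedule of :func:`layer_specs_300` is the
    authoritative geometry (see the methods note on the discrepancy).
    """
    if m < 2:
        raise ValueError("need at least two feature maps")
    if not 1 <= k <= m:
        raise ValueError(f"layer index {k} outside [1, {m}]")
    return s_min + (s_max - s_min) / (m - 1) * (k - 1)


def _location_sizes(spec: LayerSpec, image_size: int) -> np.ndarray:
    """The (w, h) menu for one cell, normalized by image size."""
    s = spec.min_size / image_size
    s_prime = np.sqrt(spec.min_size * spec.max_size) / image_size
    sizes = [(s, s), (s_prime, s_prime)]
    for r in spec.aspect_ratios:
        if r > 1:
            root = np.sqrt(r)
            sizes.append((s * root, s / root))
            sizes.append((s / root, s * root))
    return np.asarray(sizes)


def generate_priors(specs: list[LayerSpec] | None = None,
                    image_size: int = 300,
                    branch: str = "rgb") -> PriorBoxSet:
    """Tile every layer's grid with its box menu, row-major, cell-major.

    Ordering matches the detection heads' flattening: for each layer,
    for each cell (row, col), the ``boxes_per_location`` menu in order.
    Coordinates are center-form fractions of the image, clamped to [0, 1].
    """
    if specs is None:
        specs = layer_specs_300()
    boxes, layer_idx = [], []
    for li, spec in enumerate(specs):
        f = spec.grid
        sizes = _location_sizes(spec, image_size)          # (k, 2)
        ab = np.arange(f)
        cy, cx = np.meshgrid((ab + 0.5) / f, (ab + 0.5) / f, indexing="ij")
        centers = np.stack([cx.ravel(), cy.ravel()], axis=1)  # (f*f, 2)
        k = len(sizes)
        cell = np.concatenate(
            [np.repeat(centers, k, axis=0), np.tile(sizes, (f * f, 1))],
            axis=1)
        boxes.append(cell)
        layer_idx.append(np.full(f * f * k, li, dtype=np.intp))
    all_boxes = np.clip(np.concatenate(boxes, axis=0), 0.0, 1.0)
    return PriorBoxSet(all_boxes, branch,
                       np.concatenate(layer_idx), image_size, tuple(specs))


def map_to_image(prior: np.ndarray, w_img: float, h_img: float,
                 w_feature: float = 1.0, h_feature: float = 1.0) -> np.ndarray:
    """Map a normalized center-form prior to corner-form image pixels.

    With priors already normalized to the unit square, the feature sizes
    default to 1; passing feature-grid extents instead maps a prior
    expressed on the feature grid.  Per-axis indices are kept consistent
    (column -> x, row -> y).
    """
    cx, cy, w, h = np.asarray(prior, dtype=float)
    x_min = (cx - w / 2) * (w_img / w_feature)
    y_min = (cy - h / 2) * (h_img / h_feature)
    x_max = (cx + w / 2) * (w_img / w_feature)
    y_max = (cy + h / 2) * (h_img / h_feature)
    return np.array([x_min, y_min, x_max, y_max])


def fuse(rgb_priors: PriorBoxSet, depth_priors: PriorBoxSet) -> PriorBoxSet:
    """Concatenate the two branches' priors (RGB first) into the fused set."""
    if rgb_priors.image_size != depth_priors.image_size:
        raise ValueError("cannot fuse priors built for different image sizes")
    return PriorBoxSet(
        np.concatenate([rgb_priors.boxes, depth_priors.boxes], axis=0),
        "fused",
        np.concatenate([rgb_priors.layer_index, depth_priors.layer_index]),
        rgb_priors.image_size,
        rgb_priors.specs + depth_priors.specs,
    )
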