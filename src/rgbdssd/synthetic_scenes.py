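"""Seeded generator of Kinect-style registered RGB-D greenhouse scenes.

Scenes emulate the data the detector is built for: ellipsoidal tomato
fruits in three maturity color classes (green / orange / red) rendered
onto a foliage-textured background, with irregular leaf-like occluders
placed strictly nearer in depth, a per-pixel millimeter depth map, and
optional specular highlight blobs with ground-truth intensity masks.
Each fruit is labeled 1..6 by maturity crossed with occlusion:
1/3/5 = non-occluded green/orange/red, 2/4/6 = the occluded variants.

Everything is drawn from one ``numpy`` generator, so identical
(config, seed) pairs reproduce scenes bit for bit.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "SceneConfig",
    "RGBDScene",
    "generate_scene",
    "generate_dataset",
    "synthesize_highlights",
    "CLASS_NAMES",
]

#: VOC label strings, class id 1..6.
CLASS_NAMES = ("tomato1", "tomato2", "tomato3", "tomato4", "tomato5",
               "tomato6")

#: HSV hue bands (degrees) per maturity class; visually separable defaults.
MATURITY_HUES = {0: (90.0, 140.0), 1: (20.0, 40.0), 2: (0.0, 15.0)}


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic scene family.

    Sizes are pixels, depths are millimeters.  ``occluder_density`` is the
    fraction of fruits that receive a leaf occluder;
    ``occlusion_label_threshold`` is the covered-area fraction above which
    a fruit is labeled occluded.
    """

    image_width: int = 512
    image_height: int = 424
    n_fruits: tuple = (3, 6)
    fruit_radius: tuple = (30, 70)
    maturity_probs: tuple = (1 / 3, 1 / 3, 1 / 3)
    occluder_density: float = 0.5
    occlusion_label_threshold: float = 0.10
    depth_range: tuple = (500.0, 4500.0)
    highlight: bool = False
    highlight_blobs: tuple = (1, 3)
    seed: int = 0

    def validate(self) -> None:
        if self.image_width <= 0 or self.image_height <= 0:
            raise ValueError("image must have positive area")
        if self.n_fruits[0] > self.n_fruits[1] or self.n_fruits[0] < 0:
            raise ValueError("invalid n_fruits range")
        if self.fruit_radius[0] > self.fruit_radius[1] \
                or self.fruit_radius[0] <= 0:
            raise ValueError("invalid (empty) fruit_radius range")
        if abs(sum(self.maturity_probs) - 1.0) > 1e-9:
            raise ValueError("maturity_probs must sum to 1")
        if not 0.0 < self.occlusion_label_threshold < 1.0:
            raise ValueError("occlusion_label_threshold must be in (0, 1)")
        if not self.depth_range[0] < self.depth_range[1]:
            raise ValueError("depth near plane must be nearer than far plane")


@dataclass
class RGBDScene:
    """A registered color+depth pair with 6-way ground truth."""

    rgb: np.ndarray                    # (H, W, 3) uint8
    depth: np.ndarray                  # (H, W) float millimeters
    boxes: np.ndarray                  # (n, 4) corner-form pixels
    labels: np.ndarray                 # (n,) int class ids 1..6
    highlight_mask: np.ndarray | None = None   # (H, W) in [0, 1]
    clean_rgb: np.ndarray | None = None
    fruit_masks: list = field(default_factory=list)   # diagnostic rasters
    fruit_depths: list = field(default_factory=list)  # per-fruit base depth
    occlusion_fractions: np.ndarray | None = None

    def __post_init__(self):
        h, w = self.depth.shape
        if len(self.boxes) != len(self.labels):
            raise ValueError("boxes and labels must align")
        if len(self.boxes):
            b = np.asarray(self.boxes, dtype=float)
            if (b[:, 0] < 0).any() or (b[:, 1] < 0).any() \
                    or (b[:, 2] > w).any() or (b[:, 3] > h).any():
                raise ValueError("box outside the image")
            if (b[:, 2] <= b[:, 0]).any() or (b[:, 3] <= b[:, 1]).any():
                raise ValueError("degenerate box")


def _ellipse_mask(h: int, w: int, cx: float, cy: float, ax: float,
                  ay: float, theta: float = 0.0) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    dx, dy = xx - cx, yy - cy
    if theta:
        c, s = np.cos(theta), np.sin(theta)
        dx, dy = c * dx + s * dy, -s * dx + c * dy
    return (dx / ax) ** 2 + (dy / ay) ** 2 <= 1.0


def _hsv(h_deg: float, s: float, v: float) -> np.ndarray:
    return np.array(colorsys.hsv_to_rgb((h_deg % 360) / 360.0, s, v))


def _background(h: int, w: int, rng: np.random.Generator) -> np.ndarray:
    """Dark foliage-like texture: smoothed green noise."""
    noise = ndimage.gaussian_filter(rng.normal(size=(h, w)), sigma=12)
    noise = (noise - noise.min()) / (np.ptp(noise) + 1e-9)
    base = np.empty((h, w, 3))
    base[..., 0] = 0.08 + 0.10 * noise
    base[..., 1] = 0.22 + 0.25 * noise
    base[..., 2] = 0.06 + 0.08 * noise
    return base


def generate_scene(config: SceneConfig, seed: int | None = None) -> RGBDScene:
    """Render one scene; identical (config, seed) gives identical arrays."""
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    h, w = config.image_height, config.image_width
    near, far = config.depth_range
    span = far - near

    rgb = _background(h, w, rng)
    depth = np.full((h, w), far)
    owner = np.full((h, w), -1, dtype=int)     # object id per pixel

    n_fruits = int(rng.integers(config.n_fruits[0], config.n_fruits[1] + 1))
    fruits = []
    for i in range(n_fruits):
        r = rng.uniform(*config.fruit_radius)
        ax = r * rng.uniform(0.9, 1.1)
        ay = r * rng.uniform(0.9, 1.1)
        cx = rng.uniform(ax, max(ax + 1e-6, w - ax))
        cy = rng.uniform(ay, max(ay + 1e-6, h - ay))
        maturity = int(rng.choice(3, p=np.asarray(config.maturity_probs)))
        base_depth = rng.uniform(near + 0.35 * span, near + 0.80 * span)
        mask = _ellipse_mask(h, w, cx, cy, ax, ay)
        if not mask.any():
            continue
        fruits.append(dict(mask=mask, cx=cx, cy=cy, ax=ax, ay=ay,
                           maturity=maturity, base_depth=base_depth,
                           hue=rng.uniform(*MATURITY_HUES[maturity]),
                           sat=rng.uniform(0.75, 0.95)))

    # paint fruits with a z-buffer; depth bulges toward the camera
    for idx, f in enumerate(fruits):
        yy, xx = np.nonzero(f["mask"])
        rho2 = (((xx - f["cx"]) / f["ax"]) ** 2
                + ((yy - f["cy"]) / f["ay"]) ** 2).clip(max=1.0)
        bulge = np.sqrt(1.0 - rho2)
        obj_depth = f["base_depth"] - 40.0 * bulge
        win = obj_depth < depth[yy, xx]
        yy, xx, bulge, obj_depth = yy[win], xx[win], bulge[win], obj_depth[win]
        depth[yy, xx] = obj_depth
        owner[yy, xx] = idx
        value = 0.50 + 0.45 * bulge
        color = np.array([_hsv(f["hue"], f["sat"], v) for v in
                          np.round(value, 3)])
        rgb[yy, xx] = color

    # leaf occluders: unions of small ellipses, strictly nearer than fruit
    n_occluded_target = int(round(config.occluder_density * len(fruits)))
    occluded_ids = rng.permutation(len(fruits))[:n_occluded_target]
    occ_id = len(fruits)
    for fi in occluded_ids:
        f = fruits[fi]
        parts = []
        anchor_angle = rng.uniform(0, 2 * np.pi)
        anchor = (f["cx"] + np.cos(anchor_angle) * f["ax"] * 0.6,
                  f["cy"] + np.sin(anchor_angle) * f["ay"] * 0.6)
        for _ in range(int(rng.integers(2, 5))):
            ox = anchor[0] + rng.uniform(-0.5, 0.5) * f["ax"]
            oy = anchor[1] + rng.uniform(-0.5, 0.5) * f["ay"]
            parts.append(_ellipse_mask(
                h, w, ox, oy, f["ax"] * rng.uniform(0.35, 0.75),
                f["ay"] * rng.uniform(0.35, 0.75),
                theta=rng.uniform(0, np.pi)))
        mask = np.logical_or.reduce(parts)
        if not mask.any():
            continue
        occ_depth = rng.uniform(near + 0.08 * span, near + 0.28 * span)
        leaf_hue = rng.uniform(95, 140)
        leaf_v = rng.uniform(0.25, 0.45)
        yy, xx = np.nonzero(mask)
        win = occ_depth < depth[yy, xx]
        yy, xx = yy[win], xx[win]
        depth[yy, xx] = occ_depth + rng.normal(0, 3.0, size=len(yy))
        owner[yy, xx] = occ_id
        shade = 0.85 + 0.3 * rng.random(len(yy))
        rgb[yy, xx] = np.clip(_hsv(leaf_hue, 0.7, leaf_v)[None, :]
                              * shade[:, None], 0, 1)
        occ_id += 1

    boxes, labels, masks, depths, fractions = [], [], [], [], []
    for idx, f in enumerate(fruits):
        mask = f["mask"]
        covered = float((owner[mask] != idx).mean())
        occluded = covered > config.occlusion_label_threshold
        yy, xx = np.nonzero(mask)
        box = (float(xx.min()), float(yy.min()),
               float(xx.max() + 1), float(yy.max() + 1))
        if box[2] <= box[0] or box[3] <= box[1]:
            continue
        boxes.append(box)
        labels.append(2 * f["maturity"] + 1 + int(occluded))
        masks.append(mask)
        depths.append(f["base_depth"])
        fractions.append(covered)

    rgb8 = (np.clip(rgb, 0, 1) * 255).round().astype(np.uint8)
    scene = RGBDScene(
        rgb=rgb8,
        depth=depth,
        boxes=np.asarray(boxes, dtype=float).reshape(-1, 4),
        labels=np.asarray(labels, dtype=np.intp),
        fruit_masks=masks,
        fruit_depths=depths,
        occlusion_fractions=np.asarray(fractions),
    )
    if config.highlight:
        n_blobs = int(rng.integers(config.highlight_blobs[0],
                                   config.highlight_blobs[1] + 1))
        scene.clean_rgb = scene.rgb.copy()
        scene.rgb, scene.highlight_mask = _add_highlights(
            scene.rgb, rng, n_blobs)
    return scene


def _add_highlights(rgb: np.ndarray, rng: np.random.Generator,
                    n_blobs: int) -> tuple:
    if n_blobs < 0:
        raise ValueError("n_blobs must be non-negative")
    h, w = rgb.shape[:2]
    added = np.zeros((h, w))
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(n_blobs):
        cx, cy = rng.uniform(0, w), rng.uniform(0, h)
        sx = rng.uniform(0.02, 0.08) * w
        sy = rng.uniform(0.02, 0.08) * h
        theta = rng.uniform(0, np.pi)
        amp = rng.uniform(90, 200)
        c, s = np.cos(theta), np.sin(theta)
        dx, dy = xx - cx, yy - cy
        u, v = c * dx + s * dy, -s * dx + c * dy
        added += amp * np.exp(-0.5 * ((u / sx) ** 2 + (v / sy) ** 2))
    out = np.clip(rgb.astype(float) + added[..., None], 0, 255)
    mask = np.clip(added / 255.0, 0.0, 1.0)
    return out.round().astype(np.uint8), mask


def synthesize_highlights(rgb: np.ndarray, seed: int,
                          n_blobs: int) -> tuple:
    """Add elliptical Gaussian brightness blobs to an RGB image.

    Returns (highlighted_rgb, mask): the image with additive specular
    blobs clipped to [0, 255], and the added intensity normalized to
    [0, 1] (a 255-intensity addition saturates the mask).
    """
    if n_blobs < 0:
        raise ValueError("n_blobs must be non-negative")
    rng = np.random.default_rng(seed)
    return _add_highlights(np.asarray(rgb), rng, int(n_blobs))


def make_highlight_pairs(n_pairs: int, size: int = 64,
                         seed: int = 0) -> list:
    """(highlighted, clean, mask) triples from small rendered scenes,
    the paired supervision the highlight-removal losses require."""
    config = SceneConfig(image_width=size, image_height=size,
                         n_fruits=(1, 2),
                         fruit_radius=(max(4, size // 8),
                                       max(5, size // 4)),
                         occluder_density=0.3, highlight=True,
                         highlight_blobs=(1, 2))
    children = np.random.SeedSequence(seed).spawn(n_pairs)
    pairs = []
    for child in children:
        scene = generate_scene(config,
                               int(child.generate_state(1)[0] % (2 ** 31)))
        pairs.append((scene.rgb, scene.clean_rgb, scene.highlight_mask))
    return pairs


def generate_dataset(n_scenes: int, config: SceneConfig, out_dir,
                     seed: int = 0) -> list[dict]:
    """Write `n_scenes` scenes as RGB PNG + 16-bit depth PNG + VOC XML.

    Returns the manifest (list of per-scene path triples, generation
    order) and writes it to ``out_dir/manifest.tsv``.
    """
    import imageio.v3 as iio

    from .cli_io import write_voc_xml

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    children = np.random.SeedSequence(seed).spawn(n_scenes)
    manifest = []
    for i, child in enumerate(children):
        scene_seed = int(child.generate_state(1)[0] % (2 ** 31))
        scene = generate_scene(config, scene_seed)
        rgb_path = out_dir / f"scene_{i:04d}_rgb.png"
        depth_path = out_dir / f"scene_{i:04d}_depth.png"
        xml_path = out_dir / f"scene_{i:04d}.xml"
        iio.imwrite(rgb_path, scene.rgb)
        iio.imwrite(depth_path,
                    np.clip(scene.depth, 0, 65535).round().astype(np.uint16))
        write_voc_xml(scene, xml_path, filename=rgb_path.name)
        manifest.append(dict(rgb_path=str(rgb_path),
                             depth_path=str(depth_path),
                             xml_path=str(xml_path)))
    with open(out_dir / "manifest.tsv", "w") as fh:
        fh.write("rgb_path\tdepth_path\txml_path\n")
        for row in manifest:
            fh.write(f"{row['rgb_path']}\t{row['depth_path']}\t"
                     f"{row['xml_path']}\n")
    return manifest
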