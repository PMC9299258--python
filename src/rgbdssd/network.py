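"""Dual-branch single-shot detector: feature pyramids, detection heads,
and the fused RGB-D forward pass.

Each branch is a VGG16-style trunk (conv1..conv5, the dilated fc6/fc7
convolutions, and the conv8..conv11 extras) emitting six feature maps of
spatial sizes 38, 19, 10, 5, 3, 1 for a 300x300 input; the depth branch
differs from the color branch only in its first layer's input channels.
Per-layer 3x3 heads regress 4 offsets and 7 class scores (6 fruit
classes + background) for every prior; the two branches' predictions are
concatenated (RGB first) over the fused prior set, a late decision-level
fusion.  A ``width_multiplier`` scales every channel count so the same
architecture runs at desk scale on a CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import anchors
from .autodiff import Conv2d, Module, Tensor, concat

__all__ = [
    "FeaturePyramid",
    "InceptionBlockConfig",
    "InceptionBlock",
    "Detections",
    "SSDBranch",
    "build_branch",
    "receptive_field",
    "DetectionHeads",
    "RDSSD",
    "build_model",
]

PYRAMID_SIZES = (38, 19, 10, 5, 3, 1)
NUM_CLASSES = 7  # 6 fruit classes + background (index 0)


@dataclass
class FeaturePyramid:
    """Six per-branch feature maps; each map is f(previous), starting
    from the input image."""

    maps: list                       # list of Tensor, NCHW
    branch: str

    def __post_init__(self):
        if len(self.maps) != 6:
            raise ValueError("a pyramid has exactly six maps")

    @property
    def spatial_sizes(self) -> tuple:
        return tuple(m.shape[2] for m in self.maps)


@dataclass
class Detections:
    """Flat per-prior predictions over the referenced prior set."""

    loc: Tensor                       # (B, N_prior, 4)
    conf: Tensor                      # (B, N_prior, NUM_CLASSES)
    priors: anchors.PriorBoxSet


def _ch(base: int, mult: float) -> int:
    return max(2, int(round(base * mult)))


class _ConvRelu(Module):
    def __init__(self, cin, cout, k, stride=1, padding=0, dilation=1, rng=None):
        self.conv = Conv2d(cin, cout, k, stride, padding, dilation, rng=rng)

    def forward(self, x):
        return self.conv(x).relu()


class L2Norm(Module):
    """Channelwise L2 normalization with a learnable scale (applied to the
    high-resolution 38x38 source, whose activations run hot)."""

    def __init__(self, channels: int, scale: float = 20.0):
        self.scale = Tensor(np.full((1, channels, 1, 1), scale,
                                    dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        norm = ((x * x).sum(axis=1, keepdims=True) + 1e-10) ** -0.5
        return x * norm * self.scale


class SSDBranch(Module):
    """One feature-extraction branch (color: 3 input channels, depth: 1)."""

    def __init__(self, in_channels: int, width_multiplier: float = 1.0,
                 rng: np.random.Generator | None = None,
                 use_inception_extras: bool = False):
        if in_channels not in (1, 3):
            raise ValueError("in_channels must be 1 (depth) or 3 (color)")
        if width_multiplier <= 0:
            raise ValueError("width_multiplier must be positive")
        rng = rng or np.random.default_rng()
        m = width_multiplier
        c64, c128, c256, c512 = (_ch(64, m), _ch(128, m), _ch(256, m),
                                 _ch(512, m))
        c1024 = _ch(1024, m)
        self.in_channels = in_channels
        # conv1..conv4_3 (source 1 at 38x38 after three 2x pools)
        self.stage1 = [
            _ConvRelu(in_channels, c64, 3, padding=1, rng=rng),
            _ConvRelu(c64, c64, 3, padding=1, rng=rng),
        ]
        self.stage2 = [
            _ConvRelu(c64, c128, 3, padding=1, rng=rng),
            _ConvRelu(c128, c128, 3, padding=1, rng=rng),
        ]
        self.stage3 = [
            _ConvRelu(c128, c256, 3, padding=1, rng=rng),
            _ConvRelu(c256, c256, 3, padding=1, rng=rng),
            _ConvRelu(c256, c256, 3, padding=1, rng=rng),
        ]
        self.stage4 = [
            _ConvRelu(c256, c512, 3, padding=1, rng=rng),
            _ConvRelu(c512, c512, 3, padding=1, rng=rng),
            _ConvRelu(c512, c512, 3, padding=1, rng=rng),
        ]
        self.l2norm = L2Norm(c512)
        # conv5 + dilated fc6/fc7 (source 2 at 19x19)
        self.stage5 = [
            _ConvRelu(c512, c512, 3, padding=1, rng=rng),
            _ConvRelu(c512, c512, 3, padding=1, rng=rng),
            _ConvRelu(c512, c512, 3, padding=1, rng=rng),
        ]
        self.fc6 = _ConvRelu(c512, c1024, 3, padding=6, dilation=6, rng=rng)
        self.fc7 = _ConvRelu(c1024, c1024, 1, rng=rng)
        # extras: conv8..conv11 (sources 3..6 at 10, 5, 3, 1)
        if use_inception_extras:
            def down_block(cin, cmid, cout, stride, padding):
                return Sequential_(
                    InceptionBlock(cin, InceptionBlockConfig.balanced(cmid),
                                   rng=rng),
                    _ConvRelu(4 * cmid, cout, 3, stride=stride,
                              padding=padding, rng=rng))
        else:
            def down_block(cin, cmid, cout, stride, padding):
                return Sequential_(
                    _ConvRelu(cin, cmid, 1, rng=rng),
                    _ConvRelu(cmid, cout, 3, stride=stride, padding=padding,
                              rng=rng))
        self.conv8 = down_block(c1024, _ch(256, m), _ch(512, m), 2, 1)
        self.conv9 = down_block(_ch(512, m), _ch(128, m), c256, 2, 1)
        self.conv10 = down_block(c256, _ch(128, m), c256, 1, 0)
        self.conv11 = down_block(c256, _ch(128, m), c256, 1, 0)
        self.source_channels = (c512, c1024, _ch(512, m), c256, c256, c256)
        self.branch = "rgb" if in_channels == 3 else "depth"

    def forward(self, x: Tensor) -> FeaturePyramid:
        for layer in self.stage1:
            x = layer(x)
        x = x.max_pool2d(2)
        for layer in self.stage2:
            x = layer(x)
        x = x.max_pool2d(2)
        for layer in self.stage3:
            x = layer(x)
        x = x.max_pool2d(2, ceil_mode=True)           # 75 -> 38
        for layer in self.stage4:
            x = layer(x)
        src1 = self.l2norm(x)
        x = x.max_pool2d(2)                           # 38 -> 19
        for layer in self.stage5:
            x = layer(x)
        x = x.max_pool2d(3, stride=1, padding=1)      # keeps 19
        x = self.fc6(x)
        src2 = self.fc7(x)
        src3 = self.conv8(src2)
        src4 = self.conv9(src3)
        src5 = self.conv10(src4)
        src6 = self.conv11(src5)
        return FeaturePyramid([src1, src2, src3, src4, src5, src6],
                              self.branch)


class Sequential_(Module):
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


def build_branch(in_channels: int, width_multiplier: float = 1.0,
                 rng: np.random.Generator | None = None) -> SSDBranch:
    """Feature extractor mapping a C x 300 x 300 image to six maps of
    spatial sizes (38, 19, 10, 5, 3, 1)."""
    return SSDBranch(in_channels, width_multiplier, rng)


@dataclass(frozen=True)
class InceptionBlockConfig:
    """Parallel-branch widths of the multi-scale block: a 1x1 path, a
    factorized 1x3-then-3x1 path (receptive field 3, fewer weights than a
    full 3x3), and a 3x3 path whose dilation widens the receptive field
    without extra parameters."""

    width_1x1: int
    width_1x3_3x1: int
    width_3x3: int
    dilation_3x3: int = 2
    width_pool: int = 0              # optional pool-projection path

    def __post_init__(self):
        if self.dilation_3x3 not in (1, 2):
            raise ValueError("dilation rate must be 1 or 2")

    @property
    def out_channels(self) -> int:
        return (self.width_1x1 + self.width_1x3_3x1 + self.width_3x3
                + self.width_pool)

    @staticmethod
    def balanced(width: int) -> "InceptionBlockConfig":
        return InceptionBlockConfig(width, width, width, 2, width)


class InceptionBlock(Module):
    """Shape-preserving multi-scale block; branches concatenate
    channelwise."""

    def __init__(self, in_channels: int, cfg: InceptionBlockConfig,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.cfg = cfg
        self.path1 = Conv2d(in_channels, cfg.width_1x1, 1, rng=rng)
        # factorized 3x3: 1x3 then 3x1 (asymmetric padding via two convs)
        self.path2a = Conv2d(in_channels, cfg.width_1x3_3x1, 1, rng=rng)
        self.path2b = _AsymConv(cfg.width_1x3_3x1, cfg.width_1x3_3x1,
                                horizontal=True, rng=rng)
        self.path2c = _AsymConv(cfg.width_1x3_3x1, cfg.width_1x3_3x1,
                                horizontal=False, rng=rng)
        d = cfg.dilation_3x3
        self.path3a = Conv2d(in_channels, cfg.width_3x3, 1, rng=rng)
        self.path3b = Conv2d(cfg.width_3x3, cfg.width_3x3, 3, padding=d,
                             dilation=d, rng=rng)
        self.path4 = (Conv2d(in_channels, cfg.width_pool, 1, rng=rng)
                      if cfg.width_pool else None)

    def forward(self, x: Tensor) -> Tensor:
        outs = [self.path1(x).relu(),
                self.path2c(self.path2b(self.path2a(x).relu())).relu(),
                self.path3b(self.path3a(x).relu()).relu()]
        if self.path4 is not None:
            outs.append(self.path4(x.max_pool2d(3, 1, padding=1)).relu())
        return concat(outs, axis=1)


class _AsymConv(Module):
    """1x3 (horizontal) or 3x1 (vertical) convolution with same padding."""

    def __init__(self, cin, cout, horizontal: bool, rng=None):
        rng = rng or np.random.default_rng()
        k = (1, 3) if horizontal else (3, 1)
        fan_in = cin * 3
        w = rng.normal(0, np.sqrt(2.0 / fan_in),
                       (cout, cin, k[0], k[1])).astype(np.float32)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(cout, dtype=np.float32),
                           requires_grad=True)
        self.horizontal = horizontal

    def forward(self, x: Tensor) -> Tensor:
        # pad only along the kernel's long axis
        if self.horizontal:
            padded = _pad2d(x, 0, 1)
        else:
            padded = _pad2d(x, 1, 0)
        return padded.conv2d(self.weight, self.bias)


def _pad2d(x: Tensor, ph: int, pw: int) -> Tensor:
    if ph == 0 and pw == 0:
        return x
    B, C, H, W = x.shape
    data = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))

    def backward(g):
        x._accum(g[:, :, ph:ph + H, pw:pw + W])

    return Tensor._make(data, (x,), backward)


def receptive_field(stack: list[tuple]) -> int:
    """Analytic receptive-field side of a convolution stack.

    ``stack`` lists (kernel, stride, dilation) in forward order:
    rf grows by dilation*(kernel-1) times the product of earlier strides.
    """
    rf, jump = 1, 1
    for kernel, stride, dilation in stack:
        rf += dilation * (kernel - 1) * jump
        jump *= stride
    return int(rf)


class DetectionHeads(Module):
    """Per-layer 3x3 convolution heads emitting 4k offsets and
    ``num_classes``*k scores per cell, flattened in prior order."""

    def __init__(self, source_channels: tuple, boxes_per_location: tuple,
                 num_classes: int = NUM_CLASSES,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        if len(source_channels) != len(boxes_per_location):
            raise ValueError("one head per pyramid level")
        self.num_classes = num_classes
        self.loc_heads = [Conv2d(c, 4 * k, 3, padding=1, rng=rng)
                          for c, k in zip(source_channels,
                                          boxes_per_location)]
        self.conf_heads = [Conv2d(c, num_classes * k, 3, padding=1, rng=rng)
                           for c, k in zip(source_channels,
                                           boxes_per_location)]

    def forward(self, pyramid: FeaturePyramid) -> tuple:
        locs, confs = [], []
        for fmap, lh, ch in zip(pyramid.maps, self.loc_heads,
                                self.conf_heads):
            B = fmap.shape[0]
            lo = lh(fmap)      # (B, 4k, H, W)
            co = ch(fmap)
            # (B, H, W, 4k) -> rows ordered cell-major then box-major,
            # matching anchors.generate_priors
            locs.append(lo.transpose(0, 2, 3, 1).reshape(B, -1, 4))
            confs.append(co.transpose(0, 2, 3, 1).reshape(
                B, -1, self.num_classes))
        return concat(locs, axis=1), concat(confs, axis=1)


@dataclass
class ModelConfig:
    mode: str = "fused"              # 'rgb' | 'depth' | 'fused'
    width_multiplier: float = 1.0
    use_inception_extras: bool = False
    image_size: int = 300
    seed: int = 0
    specs: list = field(default_factory=anchors.layer_specs_300)


class RDSSD(Module):
    """The fused detector: two parallel branches, late prediction fusion.

    ``mode`` 'rgb' or 'depth' builds the corresponding single branch
    (8,732 priors); 'fused' runs both and concatenates predictions over
    the fused prior set (17,464 priors), RGB first.
    """

    def __init__(self, config: ModelConfig | None = None):
        cfg = config or ModelConfig()
        self.config = cfg
        rng = np.random.default_rng(cfg.seed)
        boxes_per_loc = tuple(s.boxes_per_location for s in cfg.specs)
        self.rgb_branch = self.depth_branch = None
        self.rgb_heads = self.depth_heads = None
        if cfg.mode in ("rgb", "fused"):
            self.rgb_branch = SSDBranch(3, cfg.width_multiplier, rng,
                                        cfg.use_inception_extras)
            self.rgb_heads = DetectionHeads(
                self.rgb_branch.source_channels, boxes_per_loc, rng=rng)
        if cfg.mode in ("depth", "fused"):
            self.depth_branch = SSDBranch(1, cfg.width_multiplier, rng,
                                          cfg.use_inception_extras)
            self.depth_heads = DetectionHeads(
                self.depth_branch.source_channels, boxes_per_loc, rng=rng)
        if cfg.mode not in ("rgb", "depth", "fused"):
            raise ValueError(f"unknown mode {cfg.mode!r}")
        rgb_priors = anchors.generate_priors(cfg.specs, cfg.image_size,
                                             "rgb")
        depth_priors = anchors.generate_priors(cfg.specs, cfg.image_size,
                                               "depth")
        if cfg.mode == "rgb":
            self.priors = rgb_priors
        elif cfg.mode == "depth":
            self.priors = depth_priors
        else:
            self.priors = anchors.fuse(rgb_priors, depth_priors)

    def forward(self, rgb: Tensor | None,
                depth: Tensor | None) -> Detections:
        locs, confs = [], []
        size = self.config.image_size
        if self.rgb_branch is not None:
            if rgb is None:
                raise ValueError("model requires an RGB input")
            rgb = rgb if isinstance(rgb, Tensor) else Tensor(rgb)
            if rgb.shape[1:] != (3, size, size):
                raise ValueError(f"expected RGB shape (B, 3, {size}, {size}),"
                                 f" got {rgb.shape}")
            lo, co = self.rgb_heads(self.rgb_branch(rgb))
            locs.append(lo)
            confs.append(co)
        if self.depth_branch is not None:
            if depth is None:
                raise ValueError("model requires a depth input")
            depth = depth if isinstance(depth, Tensor) else Tensor(depth)
            if depth.shape[1:] != (1, size, size):
                raise ValueError(f"expected depth shape (B, 1, {size}, "
                                 f"{size}), got {depth.shape}")
            lo, co = self.depth_heads(self.depth_branch(depth))
            locs.append(lo)
            confs.append(co)
        loc = locs[0] if len(locs) == 1 else concat(locs, axis=1)
        conf = confs[0] if len(confs) == 1 else concat(confs, axis=1)
        return Detections(loc, conf, self.priors)

    def rd_ssd_forward(self, rgb, depth) -> Detections:
        return self.forward(rgb, depth)


def build_model(mode: str = "fused", width_multiplier: float = 1.0,
                seed: int = 0, use_inception_extras: bool = False) -> RDSSD:
    return RDSSD(ModelConfig(mode=mode, width_multiplier=width_multiplier,
                             seed=seed,
                             use_inception_extras=use_inception_extras))


def rd_ssd_forward(rgb, depth, model: RDSSD) -> Detections:
    """Run both branches and concatenate predictions over the fused set."""
    return model.forward(rgb, depth)
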