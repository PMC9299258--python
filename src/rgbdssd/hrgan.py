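"""Highlight removal by a recurrent-attention GAN.

A generator repeatedly attends to specular regions: each recursive block
consumes the input image together with the previous attention map
(initialized to 0.5 everywhere), passes features through a residual
stem and a convolutional LSTM with peephole connections, and emits a
refined highlight-intensity mask in [0, 1]; a removal head then
reconstructs the highlight-free image.  Training combines an
attention-supervision loss L_M (per-block MSE against ground-truth
masks, weighted beta_i = 0.5^(N-i+1) so late blocks dominate), a
perceptual loss L_P (feature-space MSE under an injected fixed
extractor), and the adversarial loss L_Adv of a real/fake discriminator:
L_T = L_M + L_P + L_Adv.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Adam, Conv2d, Module, Tensor, clip_global_norm, concat

__all__ = [
    "ConvLSTMCell",
    "lstm_step",
    "HighlightSupervision",
    "beta_weights",
    "HighlightRemover",
    "Discriminator",
    "attention_recurrence",
    "mask_loss",
    "perceptual_loss",
    "adversarial_loss",
    "total_loss",
    "make_feature_extractor",
    "HRGANConfig",
    "train_hrgan",
]

_LOG_EPS = 1e-7


class ConvLSTMCell(Module):
    """Convolutional LSTM with elementwise (Hadamard) peephole terms.

    Input and hidden transforms are convolutions; the cell-state
    peepholes W_c* act per channel.  Gates are sigmoid, the candidate and
    output squash through tanh.
    """

    def __init__(self, in_channels: int, hidden_channels: int,
                 kernel: int = 3, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        pad = kernel // 2
        def conv(cin):
            return Conv2d(cin, hidden_channels, kernel, padding=pad, rng=rng)
        self.w_xi, self.w_hi = conv(in_channels), conv(hidden_channels)
        self.w_xf, self.w_hf = conv(in_channels), conv(hidden_channels)
        self.w_xc, self.w_hc = conv(in_channels), conv(hidden_channels)
        self.w_xo, self.w_ho = conv(in_channels), conv(hidden_channels)
        shape = (1, hidden_channels, 1, 1)
        self.w_ci = Tensor(np.zeros(shape, dtype=np.float32),
                           requires_grad=True)
        self.w_cf = Tensor(np.zeros(shape, dtype=np.float32),
                           requires_grad=True)
        self.w_co = Tensor(np.zeros(shape, dtype=np.float32),
                           requires_grad=True)
        self.hidden_channels = hidden_channels

    def forward(self, x: Tensor, h_prev: Tensor, c_prev: Tensor) -> tuple:
        return lstm_step(x, h_prev, c_prev, self)

    def zero_state(self, batch: int, h: int, w: int) -> tuple:
        z = np.zeros((batch, self.hidden_channels, h, w), dtype=np.float32)
        return Tensor(z), Tensor(z.copy())


def lstm_step(x_t: Tensor, h_prev: Tensor, c_prev: Tensor,
              params: ConvLSTMCell) -> tuple:
    """One recurrence step; returns (H_t, C_t).

    i_t = sigma(W_xi X_t + W_hi H_{t-1} + W_ci . C_{t-1} + b_i)
    f_t = sigma(W_xf X_t + W_hf H_{t-1} + W_cf . C_{t-1} + b_f)
    C_t = f_t . C_{t-1} + i_t . tanh(W_xc X_t + W_hc H_{t-1} + b_c)
    o_t = sigma(W_xo X_t + W_ho H_{t-1} + W_co . C_t + b_o)
    H_t = o_t . tanh(C_t)
    """
    x_t = x_t if isinstance(x_t, Tensor) else Tensor(x_t)
    h_prev = h_prev if isinstance(h_prev, Tensor) else Tensor(h_prev)
    c_prev = c_prev if isinstance(c_prev, Tensor) else Tensor(c_prev)
    if x_t.shape[0] != h_prev.shape[0] or h_prev.shape != c_prev.shape:
        raise ValueError("state shapes do not match the input batch")
    p = params
    i_t = (p.w_xi(x_t) + p.w_hi(h_prev) + p.w_ci * c_prev).sigmoid()
    f_t = (p.w_xf(x_t) + p.w_hf(h_prev) + p.w_cf * c_prev).sigmoid()
    c_t = f_t * c_prev + i_t * (p.w_xc(x_t) + p.w_hc(h_prev)).tanh()
    o_t = (p.w_xo(x_t) + p.w_ho(h_prev) + p.w_co * c_t).sigmoid()
    h_t = o_t * c_t.tanh()
    return h_t, c_t


def beta_weights(n_blocks: int) -> np.ndarray:
    """Supervision weights beta_i = 0.5^(N-i+1), i = 1..N (beta_N = 0.5)."""
    if n_blocks < 1:
        raise ValueError("need at least one recursive block")
    i = np.arange(1, n_blocks + 1)
    return 0.5 ** (n_blocks - i + 1)


@dataclass
class HighlightSupervision:
    """Per-block attention maps and their ground truths."""

    masks: list                       # N Tensors, (B, 1, h_i, w_i)
    truths: list                      # N arrays, matching sizes
    n_blocks: int = 0

    def __post_init__(self):
        if not self.n_blocks:
            self.n_blocks = len(self.masks)
        if len(self.masks) != self.n_blocks or \
                len(self.truths) != self.n_blocks:
            raise ValueError("one truth per mask per block")

    @property
    def betas(self) -> np.ndarray:
        return beta_weights(self.n_blocks)


def _resize_mask(truth: np.ndarray, h: int, w: int) -> np.ndarray:
    """Block-mean downsample of a full-resolution truth mask."""
    th, tw = truth.shape[-2:]
    if (th, tw) == (h, w):
        return truth
    if th % h or tw % w:
        from skimage.transform import resize as sk_resize
        return sk_resize(truth, truth.shape[:-2] + (h, w), order=1,
                         preserve_range=True, anti_aliasing=False)
    fh, fw = th // h, tw // w
    return truth.reshape(*truth.shape[:-2], h, fh, w, fw).mean(axis=(-3, -1))


def mask_loss(sup: HighlightSupervision) -> Tensor:
    """L_M = sum_i beta_i * MSE(M_i, T_i), truths resized per block."""
    total = Tensor(np.zeros(()))
    for beta, mask, truth in zip(sup.betas, sup.masks, sup.truths):
        mask = mask if isinstance(mask, Tensor) else Tensor(mask)
        t = _resize_mask(np.asarray(truth, dtype=np.float64),
                         mask.shape[-2], mask.shape[-1])
        t = np.broadcast_to(t, mask.shape)
        total = total + float(beta) * ((mask - Tensor(t)) ** 2.0).mean()
    return total


def perceptual_loss(pred_image, truth_image, feature_fn) -> Tensor:
    """MSE between fixed-extractor features of the two images."""
    fp = feature_fn(pred_image if isinstance(pred_image, Tensor)
                    else Tensor(pred_image))
    ft = feature_fn(truth_image if isinstance(truth_image, Tensor)
                    else Tensor(truth_image))
    return ((fp - ft.detach()) ** 2.0).mean()


def adversarial_loss(d_real, d_fake) -> Tensor:
    """L_Adv = E[log D(real)] + E[log(1 - D(fake))].

    This is the discriminator's objective (maximized by a discriminator
    that outputs 1 on real and 0 on generated images; the optimum is 0).
    """
    d_real = d_real if isinstance(d_real, Tensor) else Tensor(d_real)
    d_fake = d_fake if isinstance(d_fake, Tensor) else Tensor(d_fake)
    return (d_real.log(eps=_LOG_EPS).mean()
            + (1.0 - d_fake).log(eps=_LOG_EPS).mean())


def total_loss(l_m, l_p, l_adv):
    """L_T = L_M + L_P + L_Adv (unweighted)."""
    return l_m + l_p + l_adv


class _ResBlock(Module):
    def __init__(self, channels: int, rng):
        self.c1 = Conv2d(channels, channels, 3, padding=1, rng=rng)
        self.c2 = Conv2d(channels, channels, 3, padding=1, rng=rng)

    def forward(self, x):
        return x + self.c2(self.c1(x).relu()) * 0.1


class HighlightRemover(Module):
    """Generator: recurrent attention over N blocks + a removal head.

    Works on images in [0, 1], NCHW.  ``forward`` returns
    (restored_image, masks): the highlight-free estimate and the stack
    of per-block attention maps M_1..M_N.
    """

    def __init__(self, n_blocks: int = 4, channels: int = 8,
                 rng: np.random.Generator | None = None):
        if n_blocks < 1:
            raise ValueError("need at least one recursive block")
        rng = rng or np.random.default_rng()
        self.n_blocks = n_blocks
        self.stem = Conv2d(4, channels, 3, padding=1, rng=rng)
        self.res = _ResBlock(channels, rng)
        self.lstm = ConvLSTMCell(channels, channels, rng=rng)
        self.mask_head = Conv2d(channels, 1, 3, padding=1, rng=rng)
        self.rm1 = Conv2d(4, channels, 3, padding=1, rng=rng)
        self.rm_res = _ResBlock(channels, rng)
        self.rm2 = Conv2d(channels, 3, 3, padding=1, rng=rng)

    def attend(self, image: Tensor) -> list:
        """Run the recurrence; returns [M_1 .. M_N], each in [0, 1]."""
        image = image if isinstance(image, Tensor) else Tensor(image)
        b, _, h, w = image.shape
        mask = Tensor(np.full((b, 1, h, w), 0.5, dtype=np.float32))
        h_t, c_t = self.lstm.zero_state(b, h, w)
        masks = []
        for _ in range(self.n_blocks):
            x_t = self.res(self.stem(concat([image, mask], axis=1)).relu())
            h_t, c_t = self.lstm(x_t, h_t, c_t)
            mask = self.mask_head(h_t).sigmoid()
            masks.append(mask)
        return masks

    def forward(self, image: Tensor) -> tuple:
        image = image if isinstance(image, Tensor) else Tensor(image)
        masks = self.attend(image)
        z = self.rm1(concat([image, masks[-1]], axis=1)).relu()
        restored = (self.rm2(self.rm_res(z))).sigmoid()
        return restored, masks


def attention_recurrence(image, generator: HighlightRemover,
                         n_steps: int | None = None) -> list:
    """Expose the mask stack M_1..M_N for a (possibly overridden) N."""
    if n_steps is not None and n_steps != generator.n_blocks:
        old = generator.n_blocks
        generator.n_blocks = n_steps
        try:
            return generator.attend(image)
        finally:
            generator.n_blocks = old
    return generator.attend(image)


class Discriminator(Module):
    """Strided convnet scoring images real (1) vs generated (0)."""

    def __init__(self, channels: int = 8,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.c1 = Conv2d(3, channels, 3, stride=2, padding=1, rng=rng)
        self.c2 = Conv2d(channels, channels * 2, 3, stride=2, padding=1,
                         rng=rng)
        self.c3 = Conv2d(channels * 2, channels * 4, 3, stride=2, padding=1,
                         rng=rng)
        self.head = Conv2d(channels * 4, 1, 1, rng=rng)

    def forward(self, image: Tensor) -> Tensor:
        image = image if isinstance(image, Tensor) else Tensor(image)
        z = self.c1(image).relu()
        z = self.c2(z).relu()
        z = self.c3(z).relu()
        score = self.head(z).mean(axis=(1, 2, 3))
        return score.sigmoid()


def make_feature_extractor(seed: int = 0, channels: int = 8):
    """A fixed (frozen) random convnet used as the perceptual-feature
    function in tests; a pretrained extractor can be injected instead."""
    rng = np.random.default_rng(seed)
    convs = [Conv2d(3, channels, 3, stride=2, padding=1, rng=rng),
             Conv2d(channels, channels * 2, 3, stride=2, padding=1, rng=rng)]
    for conv in convs:
        conv.weight.requires_grad = False
        conv.bias.requires_grad = False

    def features(image: Tensor) -> Tensor:
        z = image if isinstance(image, Tensor) else Tensor(image)
        for conv in convs:
            z = conv(z).relu()
        return z

    return features


@dataclass
class HRGANConfig:
    n_blocks: int = 4
    channels: int = 8
    lr: float = 1e-3
    batch_size: int = 4
    steps: int = 200
    adv_weight: float = 1.0
    grad_clip: float = 5.0
    feature_seed: int = 0


def train_hrgan(pairs: list, config: HRGANConfig | None = None,
                seed: int = 0) -> tuple:
    """Alternating D/G training on (highlight, clean, mask) image triples.

    ``pairs`` holds uint8 (or [0,1] float) RGB images (H, W, 3) and the
    ground-truth highlight-intensity masks (H, W) in [0, 1].  Returns
    (generator, discriminator, trace); the trace records per-step L_M,
    L_P, L_Adv, L_T and the discriminator objective.  Deterministic
    given (config, seed).
    """
    cfg = config or HRGANConfig()
    if not pairs:
        raise ValueError("training requires at least one image pair")
    rng = np.random.default_rng(seed)

    def to01(img):
        arr = np.asarray(img, dtype=np.float32)
        if arr.max() > 1.5:
            arr = arr / 255.0
        return arr

    highlights = np.stack([to01(p[0]).transpose(2, 0, 1) for p in pairs])
    cleans = np.stack([to01(p[1]).transpose(2, 0, 1) for p in pairs])
    masks = np.stack([np.asarray(p[2], dtype=np.float32)[None]
                      for p in pairs])

    gen = HighlightRemover(cfg.n_blocks, cfg.channels,
                           rng=np.random.default_rng(rng.integers(2 ** 31)))
    disc = Discriminator(cfg.channels,
                         rng=np.random.default_rng(rng.integers(2 ** 31)))
    feature_fn = make_feature_extractor(cfg.feature_seed, cfg.channels)
    opt_g = Adam(gen.parameters(), lr=cfg.lr)
    opt_d = Adam(disc.parameters(), lr=cfg.lr)
    trace = []
    n = len(pairs)
    for step in range(cfg.steps):
        idx = rng.choice(n, size=min(cfg.batch_size, n), replace=False)
        h_img = Tensor(highlights[idx])
        f_img = Tensor(cleans[idx])
        t_mask = masks[idx]

        # --- discriminator: maximize E[log D(real)] + E[log(1-D(fake))]
        restored, _ = gen(h_img)
        fake = restored.detach()
        l_adv_d = adversarial_loss(disc(f_img), disc(fake))
        d_obj = -l_adv_d
        opt_d.zero_grad()
        d_obj.backward()
        clip_global_norm(opt_d.params, cfg.grad_clip)
        opt_d.step()

        # --- generator: L_M + L_P + adversarial (non-saturating)
        restored, mask_stack = gen(h_img)
        sup = HighlightSupervision(
            mask_stack, [t_mask for _ in mask_stack])
        l_m = mask_loss(sup)
        l_p = perceptual_loss(restored, f_img, feature_fn)
        d_fake = disc(restored)
        g_adv = -(d_fake.log(eps=_LOG_EPS).mean())
        g_obj = l_m + l_p + cfg.adv_weight * g_adv
        opt_g.zero_grad()
        g_obj.backward()
        clip_global_norm(opt_g.params, cfg.grad_clip)
        opt_g.step()

        l_adv = float(adversarial_loss(disc(f_img).detach(),
                                       d_fake.detach()).data)
        trace.append(dict(step=step, l_m=float(l_m.data),
                          l_p=float(l_p.data), l_adv=l_adv,
                          l_t=float(l_m.data + l_p.data + l_adv),
                          d_objective=float(d_obj.data)))
    return gen, disc, trace
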