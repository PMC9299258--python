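"""Detector training loop and inference for the RGB-D single-shot model.

Training follows the usual single-shot recipe: each image's ground
truths are matched to the (fused) prior set, the multibox objective is
averaged over the batch, and Adam updates the weights.  Default
hyperparameters (batch 8, learning rate 1e-3, Adam, periodic
evaluation) match the reference experiment settings; desk-scale presets
shrink the width and iteration count so the whole loop runs on one CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from . import augment as aug
from . import evaluation, geometry
from .autodiff import Adam, SGD, Tensor, clip_global_norm
from .loss import multibox_loss
from .network import ModelConfig, RDSSD

__all__ = [
    "TrainConfig",
    "prepare_samples",
    "train_detector",
    "detect",
    "make_detect_fn",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class TrainConfig:
    iterations: int = 500
    batch_size: int = 8
    lr: float = 1e-3
    optimizer: str = "adam"              # 'adam' | 'sgd'
    neg_pos_ratio: float = 3.0
    match_iou: float = 0.5
    grad_clip: float = 20.0
    eval_every: int = 500
    use_augment: bool = True             # stochastic stages on/off
    target_map: float | None = None      # early stop on training mAP
    conf_threshold: float = 0.05
    nms_iou: float = 0.45
    top_k: int = 200


def prepare_samples(scenes: list, depth_range: tuple,
                    aug_cfg: aug.AugmentConfig | None = None) -> tuple:
    """ToSensor every scene and compute dataset channel means.

    Returns (samples, AugmentConfig with the measured means filled in).
    """
    samples = [aug.to_sensor(s.rgb, s.depth, s.boxes, s.labels, depth_range)
               for s in scenes]
    rgb_means, depth_mean = aug.channel_means(samples)
    cfg = aug_cfg or aug.AugmentConfig()
    cfg = replace(cfg, rgb_means=rgb_means, depth_mean=depth_mean)
    return samples, cfg


def _batch_arrays(samples: list) -> tuple:
    rgb = np.stack([s.rgb_chw for s in samples]).astype(np.float32)
    depth = np.stack([s.depth_chw for s in samples]).astype(np.float32)
    return rgb, depth


def train_detector(scenes: list, model: RDSSD,
                   config: TrainConfig | None = None,
                   aug_cfg: aug.AugmentConfig | None = None,
                   depth_range: tuple = (500.0, 4500.0),
                   seed: int = 0) -> tuple:
    """Train in place; returns (model, log).

    The log is a list of per-iteration dicts (iteration, f_loss, c_loss,
    l_all_loss, n_positive) with training mAP recorded every
    ``eval_every`` iterations; reaching ``target_map`` stops early.
    """
    cfg = config or TrainConfig()
    rng = np.random.default_rng(seed)
    samples, aug_cfg = prepare_samples(scenes, depth_range, aug_cfg)

    fixed = None
    if not cfg.use_augment:
        # deterministic preset: preprocess and match once
        fixed = []
        for s in samples:
            t = aug.augment(s, rng, aug_cfg, deterministic=True)
            m = geometry.match(model.priors, t.boxes, t.labels,
                               threshold=cfg.match_iou)
            fixed.append((t, m))

    params = model.parameters()
    opt = (Adam(params, lr=cfg.lr) if cfg.optimizer == "adam"
           else SGD(params, lr=cfg.lr, momentum=0.9))
    log = []
    n = len(samples)
    for it in range(1, cfg.iterations + 1):
        idx = rng.choice(n, size=min(cfg.batch_size, n), replace=False)
        if fixed is None:
            batch = []
            for i in idx:
                t = aug.augment(samples[i], rng, aug_cfg)
                m = geometry.match(model.priors, t.boxes, t.labels,
                                   threshold=cfg.match_iou)
                batch.append((t, m))
        else:
            batch = [fixed[i] for i in idx]
        rgb, depth = _batch_arrays([t for t, _ in batch])
        det = model.forward(Tensor(rgb) if model.rgb_branch else None,
                            Tensor(depth) if model.depth_branch else None)
        total = None
        f_sum = c_sum = l_sum = 0.0
        n_pos = 0
        for b, (_, m) in enumerate(batch):
            breakdown, node = multibox_loss(det.conf[b], det.loc[b], m,
                                            cfg.neg_pos_ratio)
            total = node if total is None else total + node
            f_sum += breakdown.f_loss
            c_sum += breakdown.c_loss
            l_sum += breakdown.l_all_loss
            n_pos += breakdown.n_positive
        total = total * (1.0 / len(batch))
        opt.zero_grad()
        total.backward()
        clip_global_norm(params, cfg.grad_clip)
        opt.step()
        entry = dict(iteration=it, f_loss=f_sum / len(batch),
                     c_loss=c_sum, l_all_loss=l_sum, n_positive=n_pos)
        if cfg.eval_every and (it % cfg.eval_every == 0
                               or it == cfg.iterations):
            detect_fn = make_detect_fn(model, aug_cfg, depth_range,
                                       cfg.conf_threshold, cfg.nms_iou,
                                       cfg.top_k)
            result = evaluation.evaluate(detect_fn, scenes)
            entry["train_map"] = result.map
            log.append(entry)
            if cfg.target_map is not None and result.map >= cfg.target_map:
                break
        else:
            log.append(entry)
    return model, log


def _softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def detect(model: RDSSD, scene, aug_cfg: aug.AugmentConfig,
           depth_range: tuple = (500.0, 4500.0),
           conf_threshold: float = 0.05, nms_iou: float = 0.45,
           top_k: int = 200) -> list:
    """Detect fruits in one scene.

    Forward pass -> offset decoding -> per-class NMS -> confidence
    filter; returns (class_id, score, box) triples with boxes in the
    scene's pixel coordinates.
    """
    sample = aug.to_sensor(scene.rgb, scene.depth, scene.boxes,
                           scene.labels, depth_range)
    h, w = sample.depth.shape
    rng = np.random.default_rng(0)      # unused: deterministic path
    t = aug.augment(sample, rng, aug_cfg, deterministic=True)
    rgb, depth = _batch_arrays([t])
    det = model.forward(Tensor(rgb) if model.rgb_branch else None,
                        Tensor(depth) if model.depth_branch else None)
    loc = det.loc.data[0]
    conf = _softmax(det.conf.data[0])
    boxes01 = geometry.decode(loc, det.priors.boxes)
    boxes01 = np.clip(boxes01, 0.0, 1.0)
    valid = (boxes01[:, 2] > boxes01[:, 0]) & (boxes01[:, 3] > boxes01[:, 1])
    out = []
    for cls in range(1, conf.shape[1]):
        scores = conf[:, cls]
        mask = (scores > conf_threshold) & valid
        if not mask.any():
            continue
        keep = geometry.nms(boxes01[mask], scores[mask], nms_iou, top_k)
        sel_boxes = boxes01[mask][keep] * np.array([w, h, w, h])
        for score, box in zip(scores[mask][keep], sel_boxes):
            out.append((cls, float(score), box))
    return out


def make_detect_fn(model: RDSSD, aug_cfg: aug.AugmentConfig,
                   depth_range: tuple = (500.0, 4500.0),
                   conf_threshold: float = 0.05, nms_iou: float = 0.45,
                   top_k: int = 200):
    def fn(scene):
        return detect(model, scene, aug_cfg, depth_range, conf_threshold,
                      nms_iou, top_k)
    return fn


def save_checkpoint(model: RDSSD, path, aug_cfg: aug.AugmentConfig) -> None:
    """Single-file weights + config (model mode/width/seed, channel means)."""
    meta = dict(mode=model.config.mode,
                width_multiplier=model.config.width_multiplier,
                use_inception_extras=model.config.use_inception_extras,
                image_size=model.config.image_size,
                seed=model.config.seed,
                rgb_means=list(aug_cfg.rgb_means),
                depth_mean=aug_cfg.depth_mean)
    state = model.state_dict()
    state["__meta__"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **state)


def load_checkpoint(path) -> tuple:
    """Inverse of :func:`save_checkpoint`; returns (model, AugmentConfig)."""
    with np.load(path) as f:
        state = {k: f[k] for k in f.files}
    meta = json.loads(bytes(state.pop("__meta__")).decode())
    model = RDSSD(ModelConfig(mode=meta["mode"],
                              width_multiplier=meta["width_multiplier"],
                              use_inception_extras=meta[
                                  "use_inception_extras"],
                              image_size=meta["image_size"],
                              seed=meta["seed"]))
    model.load_state_dict(state)
    cfg = replace(aug.AugmentConfig(), rgb_means=tuple(meta["rgb_means"]),
                  depth_mean=meta["depth_mean"])
    return model, cfg
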