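"""Box geometry: IoU, prior-to-ground-truth matching, offset codes, NMS.

All boxes are continuous corner-form (x_min, y_min, x_max, y_max); areas
are (x_max - x_min) * (y_max - y_min) with no +1 pixel convention.
Matching uses the single-shot detector rule: every ground truth claims
its best-overlap prior unconditionally, and any prior overlapping some
ground truth above the threshold is also positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "iou",
    "iou_matrix",
    "MatchResult",
    "match",
    "encode",
    "decode",
    "nms",
]

#: Offset-code variances of the localization parameterization: center
#: deltas are divided by 0.1, log size ratios by 0.2.
VARIANCES = (0.1, 0.2)


def _validate(box: np.ndarray, name: str) -> np.ndarray:
    box = np.asarray(box, dtype=float)
    if box.shape[-1] != 4:
        raise ValueError(f"{name} must have 4 coordinates")
    if np.any(box[..., 2] <= box[..., 0]) or np.any(box[..., 3] <= box[..., 1]):
        raise ValueError(f"{name} is degenerate (needs x_max > x_min and "
                         "y_max > y_min)")
    return box


def iou(box_a, box_b) -> float:
    """Intersection-over-union of two corner-form boxes; 0 when disjoint."""
    a = _validate(np.asarray(box_a), "box_a")
    b = _validate(np.asarray(box_b), "box_b")
    iw = min(a[2], b[2]) - max(a[0], b[0])
    ih = min(a[3], b[3]) - max(a[1], b[1])
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    return float(inter / (area_a + area_b - inter))


def iou_matrix(boxes_a: np.ndarray, boxes_b: np.ndarray) -> np.ndarray:
    """Pairwise IoU, (len(a), len(b))."""
    a = np.asarray(boxes_a, dtype=float).reshape(-1, 4)
    b = np.asarray(boxes_b, dtype=float).reshape(-1, 4)
    iw = (np.minimum(a[:, None, 2], b[None, :, 2])
          - np.maximum(a[:, None, 0], b[None, :, 0])).clip(min=0)
    ih = (np.minimum(a[:, None, 3], b[None, :, 3])
          - np.maximum(a[:, None, 1], b[None, :, 1])).clip(min=0)
    inter = iw * ih
    area_a = ((a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1]))[:, None]
    area_b = ((b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1]))[None, :]
    union = area_a + area_b - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(union > 0, inter / union, 0.0)
    return out


def _center_form(corner: np.ndarray) -> np.ndarray:
    corner = np.asarray(corner, dtype=float)
    wh = corner[..., 2:] - corner[..., :2]
    c = corner[..., :2] + wh / 2
    return np.concatenate([c, wh], axis=-1)


def _corner_form(center: np.ndarray) -> np.ndarray:
    center = np.asarray(center, dtype=float)
    half = center[..., 2:] / 2
    return np.concatenate([center[..., :2] - half,
                           center[..., :2] + half], axis=-1)


def encode(gt_box: np.ndarray, prior: np.ndarray,
           variances=VARIANCES) -> np.ndarray:
    """Offset code of a corner-form ground truth w.r.t. a center-form prior.

    (dcx, dcy) are center deltas in prior-size units over variance 0.1;
    (dw, dh) are log size ratios over variance 0.2.
    """
    g = _center_form(np.asarray(gt_box, dtype=float))
    p = np.asarray(prior, dtype=float)
    v0, v1 = variances
    d_center = (g[..., :2] - p[..., :2]) / (p[..., 2:] * v0)
    d_size = np.log(g[..., 2:] / p[..., 2:]) / v1
    return np.concatenate([d_center, d_size], axis=-1)


def decode(offsets: np.ndarray, prior: np.ndarray,
           variances=VARIANCES) -> np.ndarray:
    """Invert :func:`encode`: offsets + prior -> corner-form box."""
    o = np.asarray(offsets, dtype=float)
    p = np.asarray(prior, dtype=float)
    v0, v1 = variances
    center = p[..., :2] + o[..., :2] * v0 * p[..., 2:]
    size = p[..., 2:] * np.exp(o[..., 2:] * v1)
    return _corner_form(np.concatenate([center, size], axis=-1))


@dataclass
class MatchResult:
    """Per-prior assignment of ground truths with encoded targets."""

    gt_index: np.ndarray       # (N_prior,) int, -1 = background
    class_targets: np.ndarray  # (N_prior,) int, 0 = background, 1..6 = fruit
    loc_targets: np.ndarray    # (N_prior, 4) encoded offsets (zeros for bg)
    positive_mask: np.ndarray  # (N_prior,) bool

    @property
    def n_positive(self) -> int:
        return int(self.positive_mask.sum())


def match(priors, gt_boxes, gt_labels, threshold: float = 0.5,
          variances=VARIANCES) -> MatchResult:
    """Assign priors to ground truths by overlap.

    Two rules compose: (i) every ground truth forces its best-IoU prior
    positive, so no object is left unsupervised; (ii) every prior whose
    best overlap with some ground truth exceeds ``threshold`` (strictly)
    is positive and assigned to its argmax ground truth.
    """
    prior_center = np.asarray(getattr(priors, "boxes", priors), dtype=float)
    if prior_center.size == 0:
        raise ValueError("priors must be non-empty")
    prior_corner = _corner_form(prior_center)
    n = len(prior_center)
    gt_boxes = np.asarray(gt_boxes, dtype=float).reshape(-1, 4)
    gt_labels = np.asarray(gt_labels, dtype=np.intp)

    if len(gt_boxes) == 0:
        return MatchResult(np.full(n, -1, dtype=np.intp),
                           np.zeros(n, dtype=np.intp),
                           np.zeros((n, 4)), np.zeros(n, dtype=bool))

    overlaps = iou_matrix(prior_corner, gt_boxes)        # (N, G)
    best_gt = overlaps.argmax(axis=1)
    best_gt_iou = overlaps[np.arange(n), best_gt]
    positive = best_gt_iou > threshold

    # each ground truth claims its best still-unclaimed prior, overriding
    # the threshold; exclusive claiming keeps every object supervised even
    # when two ground truths share a best prior
    claimed: list[int] = []
    for g in range(len(gt_boxes)):
        col = overlaps[:, g].copy()
        col[claimed] = -1.0
        p = int(col.argmax())
        if col[p] < 0:
            continue                      # more ground truths than priors
        claimed.append(p)
        best_gt[p] = g
        positive[p] = True

    gt_index = np.where(positive, best_gt, -1)
    class_targets = np.where(positive, gt_labels[best_gt], 0)
    loc_targets = np.zeros((n, 4))
    if positive.any():
        loc_targets[positive] = encode(gt_boxes[best_gt[positive]],
                                       prior_center[positive], variances)
    return MatchResult(gt_index.astype(np.intp),
                       class_targets.astype(np.intp), loc_targets, positive)


def nms(boxes: np.ndarray, scores: np.ndarray, iou_threshold: float = 0.45,
        top_k: int = 200) -> np.ndarray:
    """Greedy descending-score suppression; returns kept indices.

    A box is kept iff its IoU with every higher-scored kept box is at
    most ``iou_threshold``; at most ``top_k`` indices are returned.
    Ties in score break toward the lower index (stable).
    """
    boxes = np.asarray(boxes, dtype=float).reshape(-1, 4)
    scores = np.asarray(scores, dtype=float)
    if len(boxes) == 0:
        return np.array([], dtype=np.intp)
    order = np.argsort(-scores, kind="stable")
    keep: list[int] = []
    while len(order) and len(keep) < top_k:
        i = order[0]
        keep.append(int(i))
        if len(order) == 1:
            break
        rest = order[1:]
        ious = iou_matrix(boxes[i], boxes[rest])[0]
        order = rest[ious <= iou_threshold]
    return np.asarray(keep, dtype=np.intp)
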