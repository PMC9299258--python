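"""VOC-style average precision over the six fruit classes, with
maturity-group and occlusion-group aggregation.

Classes 1..6 are maturity (green/orange/red) crossed with occlusion:
odd ids are non-occluded, even ids occluded; ids (1,2), (3,4), (5,6)
share the immature / semi-mature / mature maturity stages.  Group
metrics default to means of the member-class APs; a merged-label
re-evaluation mode is also provided.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .geometry import iou_matrix

__all__ = [
    "average_precision",
    "EvalResult",
    "evaluate",
    "evaluate_detections",
    "group_means",
]

MATURITY_GROUPS = {"immature": (1, 2), "semimature": (3, 4),
                   "mature": (5, 6)}
OCCLUSION_GROUPS = {"nonocclusion": (1, 3, 5), "occlusion": (2, 4, 6)}


def average_precision(detections: list, ground_truths: dict,
                      iou_threshold: float = 0.5,
                      eleven_point: bool = False) -> float | None:
    """AP of one class.

    ``detections`` is a list of (image_id, score, box); ``ground_truths``
    maps image_id -> array of boxes.  Score-ranked detections greedily
    claim the best unmatched ground truth at IoU >= threshold (first
    claim wins; duplicates are false positives).  Returns the all-point
    interpolated area under precision-recall, the VOC-2007 11-point
    variant when requested, or None when the class has no ground truth.
    """
    n_gt = sum(len(b) for b in ground_truths.values())
    if n_gt == 0:
        return None
    if not detections:
        return 0.0
    order = sorted(range(len(detections)),
                   key=lambda i: (-detections[i][1], i))
    claimed = {img: np.zeros(len(b), dtype=bool)
               for img, b in ground_truths.items()}
    tp = np.zeros(len(order))
    for rank, i in enumerate(order):
        img, _, box = detections[i]
        gts = np.asarray(ground_truths.get(img, ()), dtype=float)
        if len(gts) == 0:
            continue
        ious = iou_matrix(np.asarray(box, dtype=float), gts)[0]
        ious[claimed[img]] = -1.0
        j = int(np.argmax(ious))
        if ious[j] >= iou_threshold:
            claimed[img][j] = True
            tp[rank] = 1.0
    cum_tp = np.cumsum(tp)
    recall = cum_tp / n_gt
    precision = cum_tp / np.arange(1, len(tp) + 1)
    if eleven_point:
        ap = 0.0
        for r in np.linspace(0, 1, 11):
            mask = recall >= r
            ap += (precision[mask].max() if mask.any() else 0.0) / 11.0
        return float(ap)
    # all-point: integrate the monotone (from the right) precision envelope
    mrec = np.concatenate([[0.0], recall, [1.0]])
    mpre = np.concatenate([[0.0], precision, [0.0]])
    mpre = np.maximum.accumulate(mpre[::-1])[::-1]
    idx = np.flatnonzero(mrec[1:] != mrec[:-1])
    return float(np.sum((mrec[idx + 1] - mrec[idx]) * mpre[idx + 1]))


def group_means(per_class_ap: dict, groups: dict) -> dict:
    """Mean AP of each group's member classes (absent classes skipped)."""
    out = {}
    for name, members in groups.items():
        vals = [per_class_ap[c] for c in members
                if per_class_ap.get(c) is not None]
        out[name] = float(np.mean(vals)) if vals else None
    return out


@dataclass
class EvalResult:
    """Per-class APs, their mean, and the two group breakdowns."""

    per_class_ap: dict                # class id -> AP (None if absent)
    map: float
    maturity: dict                    # immature / semimature / mature
    occlusion: dict                   # nonocclusion / occlusion

    def to_json(self, path=None) -> str:
        payload = {
            "per_class_ap": {f"tomato{c}": v
                             for c, v in self.per_class_ap.items()},
            "mAP": self.map,
            "maturity": self.maturity,
            "occlusion": self.occlusion,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def format_table(self) -> str:
        """Plain-text table: one row of mAP + the six class columns."""
        header = ("Model\tmAP\t" +
                  "\t".join(f"Tomato{c}" for c in range(1, 7)))
        def fmt(v):
            return "-" if v is None else f"{v:.4f}"
        row = ("eval\t" + fmt(self.map) + "\t"
               + "\t".join(fmt(self.per_class_ap.get(c))
                           for c in range(1, 7)))
        return header + "\n" + row


def evaluate_detections(per_image_detections: list, scenes: list,
                        iou_threshold: float = 0.5,
                        eleven_point: bool = False,
                        group_mode: str = "mean") -> EvalResult:
    """Score pre-computed detections against scene ground truth.

    ``per_image_detections[i]`` lists (class_id, score, box) for scene i;
    ``scenes`` provide ``boxes`` and ``labels``.  ``group_mode`` 'mean'
    averages member-class APs; 'merged' relabels classes into each group
    and re-runs the AP machinery on the merged problem.
    """
    per_class_ap = {}
    for cls in range(1, 7):
        dets = [(i, score, box)
                for i, dets_i in enumerate(per_image_detections)
                for c, score, box in dets_i if c == cls]
        gts = {i: np.asarray(s.boxes, dtype=float)[
            np.asarray(s.labels) == cls] for i, s in enumerate(scenes)}
        per_class_ap[cls] = average_precision(dets, gts, iou_threshold,
                                              eleven_point)
    present = [v for v in per_class_ap.values() if v is not None]
    mean_ap = float(np.mean(present)) if present else 0.0

    if group_mode == "mean":
        maturity = group_means(per_class_ap, MATURITY_GROUPS)
        occlusion = group_means(per_class_ap, OCCLUSION_GROUPS)
    elif group_mode == "merged":
        def merged(groups):
            out = {}
            for name, members in groups.items():
                dets = [(i, score, box)
                        for i, dets_i in enumerate(per_image_detections)
                        for c, score, box in dets_i if c in members]
                gts = {i: np.asarray(s.boxes, dtype=float)[
                    np.isin(np.asarray(s.labels), members)]
                    for i, s in enumerate(scenes)}
                out[name] = average_precision(dets, gts, iou_threshold,
                                              eleven_point)
            return out
        maturity = merged(MATURITY_GROUPS)
        occlusion = merged(OCCLUSION_GROUPS)
    else:
        raise ValueError("group_mode must be 'mean' or 'merged'")
    return EvalResult(per_class_ap, mean_ap, maturity, occlusion)


def evaluate(detect_fn, scenes: list, iou_threshold: float = 0.5,
             eleven_point: bool = False,
             group_mode: str = "mean") -> EvalResult:
    """Run a detector over scenes and score it.

    ``detect_fn(scene)`` returns a list of (class_id, score, box) with
    boxes in the scene's absolute pixel coordinates.
    """
    per_image = [detect_fn(s) for s in scenes]
    return evaluate_detections(per_image, scenes, iou_threshold,
                               eleven_point, group_mode)
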