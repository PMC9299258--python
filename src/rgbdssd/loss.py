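"""Composite multibox objective over the fused prior set.

F_loss = (C_loss + L_all_loss) / N: softmax cross-entropy over positive
priors plus hard-mined negatives, smooth-L1 localization over positives
only, normalized by the matched-prior count N.  With no positives the
loss is defined as zero (the batch carries no supervision).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .geometry import MatchResult

__all__ = [
    "LossBreakdown",
    "confidence_loss",
    "localization_loss",
    "multibox_loss",
]


@dataclass
class LossBreakdown:
    """Scalar components of the objective plus the matched count."""

    f_loss: float
    c_loss: float
    l_all_loss: float
    n_positive: int

    def __post_init__(self):
        if self.n_positive > 0:
            expected = (self.c_loss + self.l_all_loss) / self.n_positive
            if not np.isclose(self.f_loss, expected, rtol=1e-6, atol=1e-9):
                raise ValueError("F_loss must equal (C + L)/N")


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def confidence_loss(conf, match: MatchResult,
                    neg_pos_ratio: float = 3.0) -> Tensor:
    """Classification term with hard negative mining.

    Cross-entropy over all positive priors plus the highest-loss
    background priors, at most ``neg_pos_ratio`` negatives per positive.
    Returns the summed (unnormalized) loss as a graph node.
    """
    conf = _as_tensor(conf)
    if conf.ndim != 2:
        raise ValueError("conf must be (N_prior, num_classes)")
    pos = match.positive_mask
    n_pos = int(pos.sum())
    # rank negatives by their background cross-entropy, off the tape
    z = conf.data
    zmax = z.max(axis=1, keepdims=True)
    logp = z - zmax - np.log(np.exp(z - zmax).sum(axis=1, keepdims=True))
    neg_candidates = np.flatnonzero(~pos)
    n_neg = min(int(neg_pos_ratio * n_pos), len(neg_candidates))
    if n_pos == 0:
        return Tensor(np.zeros(()))
    bg_loss = -logp[neg_candidates, 0]
    hard = neg_candidates[np.argsort(-bg_loss, kind="stable")[:n_neg]]
    idx = np.concatenate([np.flatnonzero(pos), hard])
    targets = np.concatenate([match.class_targets[pos],
                              np.zeros(len(hard), dtype=np.intp)])
    return conf[idx].softmax_cross_entropy(targets).sum()


def localization_loss(loc, match: MatchResult) -> Tensor:
    """Smooth-L1 between predicted offsets and encoded targets,
    positives only (summed, unnormalized)."""
    loc = _as_tensor(loc)
    if loc.ndim != 2 or loc.shape[1] != 4:
        raise ValueError("loc must be (N_prior, 4)")
    pos = np.flatnonzero(match.positive_mask)
    if len(pos) == 0:
        return Tensor(np.zeros(()))
    target = match.loc_targets[pos]
    return loc[pos].smooth_l1(target).sum()


def multibox_loss(conf, loc, match: MatchResult,
                  neg_pos_ratio: float = 3.0,
                  loc_weight: float = 1.0) -> tuple:
    """The full objective: returns (LossBreakdown, loss graph node).

    ``loc_weight`` is an optional weight on the localization term
    (default 1: the plain unweighted sum of the two components).
    """
    c = confidence_loss(conf, match, neg_pos_ratio)
    l = localization_loss(loc, match)
    n = match.n_positive
    if n == 0:
        total = Tensor(np.zeros(()))
        return LossBreakdown(0.0, 0.0, 0.0, 0), total
    total = (c + l * loc_weight) * (1.0 / n)
    return (LossBreakdown(float(total.data), float(c.data),
                          float(l.data) * loc_weight, n), total)
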