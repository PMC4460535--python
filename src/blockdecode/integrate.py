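"""Block-level decision rules exploiting the 15-s stimulus block structure.

All frames within a block share one true label, so per-frame decisions can
be pooled: averaging the input frames into one example, majority voting on
frame labels, confidence-weighted voting, or summing the per-class
posterior outputs across the block.  All four rules are invariant to frame
order within a block and return the unanimous label when frames agree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BlockDecision", "input_average", "block_vote", "median_vote",
           "confidence_vote", "output_average", "METHODS"]

METHODS = ("frame", "input_average", "block_vote", "confidence_vote",
           "output_average")


@dataclass(frozen=True)
class BlockDecision:
    block_id: int
    label: object
    method: str
    frame_labels: tuple
    frame_posteriors: np.ndarray | None = None


def input_average(frames: np.ndarray) -> np.ndarray:
    """Column-wise mean of the block's frames -> one example (1 x I)."""
    frames = np.atleast_2d(np.asarray(frames, dtype=float))
    if frames.shape[0] < 1 or frames.size == 0:
        raise ValueError("need at least one frame")
    return frames.mean(axis=0, keepdims=True)


def block_vote(frame_labels, frame_confidences=None):
    """Majority label of the block's frames.

    Ties break by greater summed confidence when confidences are supplied,
    else by the smallest label.
    """
    labels = list(frame_labels)
    if not labels:
        raise ValueError("need at least one frame label")
    if frame_confidences is None:
        frame_confidences = np.ones(len(labels))
    counts: dict = {}
    weights: dict = {}
    for lab, w in zip(labels, frame_confidences):
        counts[lab] = counts.get(lab, 0) + 1
        weights[lab] = weights.get(lab, 0.0) + float(w)
    top = max(counts.values())
    tied = [lab for lab, n in counts.items() if n == top]
    if len(tied) == 1:
        return tied[0]
    best_w = max(weights[lab] for lab in tied)
    tied = [lab for lab in tied if weights[lab] >= best_w - 1e-12]
    return min(tied)


def median_vote(frame_labels):
    """Median of the sorted ordinal labels (round-half-down); the literal
    "median filter" reading of block voting for ordinal classes."""
    labels = sorted(frame_labels)
    if not labels:
        raise ValueError("need at least one frame label")
    n = len(labels)
    return labels[(n - 1) // 2]


def confidence_vote(frame_labels, weights):
    """Label maximizing the summed frame weights voting for it:
    argmax_c sum_i w_i * 1_c(c_i); ties -> smallest label."""
    labels = list(frame_labels)
    weights = np.asarray(weights, dtype=float)
    if len(labels) != len(weights):
        raise ValueError("labels and weights must have equal length")
    if np.any(weights < 0):
        raise ValueError("weights must be nonnegative")
    sums: dict = {}
    for lab, w in zip(labels, weights):
        sums[lab] = sums.get(lab, 0.0) + float(w)
    best = max(sums.values())
    return min(lab for lab, s in sums.items() if s >= best - 1e-12)


def output_average(frame_posteriors: np.ndarray, class_order=None):
    """Class with the greatest per-class posterior sum across the block;
    ties -> smallest label.  Returns the class_order entry when given,
    else the column index."""
    P = np.atleast_2d(np.asarray(frame_posteriors, dtype=float))
    if P.shape[0] < 1 or P.size == 0:
        raise ValueError("need at least one frame")
    if np.any(P < 0):
        raise ValueError("posteriors must be nonnegative")
    sums = P.sum(axis=0)
    best = sums.max()
    idx = int(np.flatnonzero(sums >= best - 1e-12)[0])
    if class_order is None:
        return idx
    order = np.asarray(class_order)
    tied = order[sums >= best - 1e-12]
    return tied.min()
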