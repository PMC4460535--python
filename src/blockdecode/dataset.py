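"""The ExampleSet container and builders from runs + schedule."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .schedule import EventSchedule
from .simulate import BoldRun

__all__ = ["ExampleSet", "build_examples"]


@dataclass
class ExampleSet:
    """Frames x features matrix with labels and temporal bookkeeping.

    One row per frame; ``block_id`` groups rows belonging to the same
    stimulus block (every block maps to exactly one label) and ``run_id``
    groups blocks into runs.  ``feature_index`` maps columns of X back to
    voxel indices in the source volume.
    """

    X: np.ndarray
    y: np.ndarray
    block_id: np.ndarray
    run_id: np.ndarray
    feature_index: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y)
        self.block_id = np.asarray(self.block_id, dtype=int)
        self.run_id = np.asarray(self.run_id, dtype=int)
        if self.feature_index is None:
            self.feature_index = np.arange(self.X.shape[1])
        self.feature_index = np.asarray(self.feature_index, dtype=int)
        n = self.X.shape[0]
        if not (len(self.y) == len(self.block_id) == len(self.run_id) == n):
            raise ValueError("X, y, block_id, run_id must have equal length")
        if len(self.feature_index) != self.X.shape[1]:
            raise ValueError("feature_index must have one entry per column")
        for b in np.unique(self.block_id):
            if len(np.unique(self.y[self.block_id == b])) != 1:
                raise ValueError(f"block {b} maps to more than one label")

    @property
    def n_examples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.y)

    def subset_rows(self, rows: np.ndarray) -> "ExampleSet":
        rows = np.asarray(rows)
        return ExampleSet(self.X[rows], self.y[rows], self.block_id[rows],
                          self.run_id[rows], self.feature_index)

    def subset_features(self, cols: np.ndarray) -> "ExampleSet":
        cols = np.asarray(cols)
        return ExampleSet(self.X[:, cols], self.y, self.block_id, self.run_id,
                          self.feature_index[cols])


def build_examples(runs: list[BoldRun], schedule: EventSchedule,
                   include_travel: bool = False) -> ExampleSet:
    """Assemble per-frame examples labeled by character count.

    Only character-present frames are kept unless ``include_travel``; with
    travel frames included the count-0 label is retained (used for
    task-activated feature selection).  Labels are balanced by design:
    every count 1-6 covers exactly 12 frames per run at TR 2.5 s.
    """
    Xs, ys, bids, rids = [], [], [], []
    for run in runs:
        counts = schedule.frame_counts(run.run_id)
        blocks = schedule.frame_block_ids(run.run_id)
        if len(counts) != run.n_frames:
            raise ValueError("run length does not match schedule; did you "
                             "shift the schedule after discard_initial?")
        keep = blocks >= 0 if include_travel else counts > 0
        Xs.append(run.data[:, keep].T)
        ys.append(counts[keep])
        bids.append(blocks[keep])
        rids.append(np.full(int(keep.sum()), run.run_id))
    return ExampleSet(np.vstack(Xs), np.concatenate(ys),
                      np.concatenate(bids), np.concatenate(rids))
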