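"""Block-design event schedules.

The paradigm alternates 15-s "travel" epochs (camera moving through the
scene, no characters, count 0) with 15-s character epochs in which 1-6
characters are shown.  Within one run every count 1-6 appears exactly
twice — the count sequence is the concatenation of two independent random
permutations of 1..6 — giving 12 character blocks interleaved with 12
travel blocks per 6-minute run.  The character type (soldier vs insurgent)
is constant within a run and alternates between consecutive runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CHAR_TYPES = ("soldier", "insurgent")

__all__ = ["Block", "EventSchedule", "make_schedule", "shift_schedule",
           "write_events_tsv", "read_events_tsv"]


@dataclass(frozen=True)
class Block:
    """One stimulus epoch: ``count`` is 0 for travel, 1-6 for characters."""

    run_id: int
    onset: float
    duration: float
    count: int
    char_type: str


@dataclass
class EventSchedule:
    """Per-block onsets/durations/labels for one or more runs.

    Invariants (checked on construction): blocks within a run are ordered
    and non-overlapping; each count 1-6 occurs exactly twice per run;
    travel blocks strictly alternate with character blocks; char_type is
    constant within a run and alternates across runs; durations are
    positive integer multiples of ``tr``.
    """

    blocks: list[Block]
    tr: float
    run_length: float

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        for run in self.run_ids:
            rb = self.run_blocks(run)
            onsets = np.array([b.onset for b in rb])
            if not np.all(np.diff(onsets) > 0):
                raise ValueError("blocks within a run must be ordered by onset")
            for a, b in zip(rb, rb[1:]):
                if a.onset + a.duration > b.onset + 1e-9:
                    raise ValueError("blocks within a run must not overlap")
            counts = [b.count for b in rb if b.count > 0]
            if sorted(counts) != sorted(list(range(1, 7)) * 2):
                raise ValueError("each count 1-6 must occur exactly twice per run")
            kinds = [b.count > 0 for b in rb]
            if any(k1 == k2 for k1, k2 in zip(kinds, kinds[1:])):
                raise ValueError("travel and character blocks must alternate")
            if len({b.char_type for b in rb}) != 1:
                raise ValueError("char_type must be constant within a run")
        types = [self.run_blocks(r)[0].char_type for r in self.run_ids]
        if any(t1 == t2 for t1, t2 in zip(types, types[1:])):
            raise ValueError("char_type must alternate between consecutive runs")
        for b in self.blocks:
            n = b.duration / self.tr
            if b.duration <= 0 or abs(n - round(n)) > 1e-9:
                raise ValueError("durations must be positive multiples of tr")

    @property
    def run_ids(self) -> list[int]:
        return sorted({b.run_id for b in self.blocks})

    @property
    def n_frames_per_run(self) -> int:
        return int(round(self.run_length / self.tr))

    def run_blocks(self, run_id: int) -> list[Block]:
        return [b for b in self.blocks if b.run_id == run_id]

    def frame_counts(self, run_id: int) -> np.ndarray:
        """Character count for every frame of a run (0 during travel)."""
        counts = np.zeros(self.n_frames_per_run, dtype=int)
        times = np.arange(self.n_frames_per_run) * self.tr
        for b in self.run_blocks(run_id):
            sel = (times >= b.onset - 1e-9) & (times < b.onset + b.duration - 1e-9)
            counts[sel] = b.count
        return counts

    def frame_block_ids(self, run_id: int) -> np.ndarray:
        """Index (within schedule.blocks) of the block covering each frame; -1 if none."""
        ids = np.full(self.n_frames_per_run, -1, dtype=int)
        times = np.arange(self.n_frames_per_run) * self.tr
        for i, b in enumerate(self.blocks):
            if b.run_id != run_id:
                continue
            sel = (times >= b.onset - 1e-9) & (times < b.onset + b.duration - 1e-9)
            ids[sel] = i
        return ids


def make_schedule(n_runs: int, tr: float = 2.5, block_s: float = 15.0,
                  seed: int = 0) -> EventSchedule:
    """Generate a randomized block schedule.

    Each run starts with a travel block, then strictly alternates travel /
    character blocks; the 12 character counts are two independent random
    permutations of 1..6, concatenated.

    Parameters
    ----------
    n_runs : number of runs (>= 1).
    tr : repetition time in seconds.
    block_s : block duration in seconds; must be a positive multiple of tr.
    seed : RNG seed; identical arguments and seed give an identical schedule.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    n = block_s / tr
    if block_s <= 0 or abs(n - round(n)) > 1e-9:
        raise ValueError("block_s must be a positive multiple of tr")
    rng = np.random.default_rng(seed)
    blocks: list[Block] = []
    for run in range(n_runs):
        char_type = CHAR_TYPES[run % 2]
        counts = np.concatenate([rng.permutation(np.arange(1, 7)),
                                 rng.permutation(np.arange(1, 7))])
        onset = 0.0
        for c in counts:
            blocks.append(Block(run, onset, block_s, 0, char_type))
            onset += block_s
            blocks.append(Block(run, onset, block_s, int(c), char_type))
            onset += block_s
        run_length = onset
    return EventSchedule(blocks=blocks, tr=tr, run_length=run_length)


def shift_schedule(schedule: EventSchedule, seconds: float) -> EventSchedule:
    """Shift all onsets earlier by ``seconds`` and drop blocks that end at or
    before the new time origin — the companion of initial-frame discard."""
    kept = []
    for b in schedule.blocks:
        end = b.onset + b.duration - seconds
        if end <= 1e-9:
            continue
        kept.append(Block(b.run_id, b.onset - seconds, b.duration, b.count, b.char_type))
    sched = EventSchedule.__new__(EventSchedule)
    sched.blocks = kept
    sched.tr = schedule.tr
    sched.run_length = schedule.run_length - seconds
    return sched


def write_events_tsv(schedule: EventSchedule, path: str | Path) -> None:
    """Write a BIDS-style events table: onset, duration, run, count, char_type."""
    df = pd.DataFrame(
        {"onset": [b.onset for b in schedule.blocks],
         "duration": [b.duration for b in schedule.blocks],
         "run": [b.run_id for b in schedule.blocks],
         "count": [b.count for b in schedule.blocks],
         "char_type": [b.char_type for b in schedule.blocks]})
    df.to_csv(path, sep="\t", index=False)


def read_events_tsv(path: str | Path, tr: float, run_length: float) -> EventSchedule:
    df = pd.read_csv(path, sep="\t")
    blocks = [Block(int(r["run"]), float(r["onset"]), float(r["duration"]),
                    int(r["count"]), str(r["char_type"])) for _, r in df.iterrows()]
    return EventSchedule(blocks=blocks, tr=tr, run_length=run_length)
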