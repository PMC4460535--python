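"""Synthetic BOLD and stimulus-contrast generation with known ground truth.

A subset of voxels ("informative") carries a class-specific neural
amplitude during character blocks; that boxcar signal is convolved with a
hemodynamic response kernel and buried in temporally autocorrelated noise.
Uninformative voxels carry noise only.  This planted-signal construction
lets recovery, bias, and mapping properties be tested exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .schedule import EventSchedule

__all__ = ["BoldRun", "GroundTruth", "make_ground_truth", "simulate_bold",
           "simulate_contrast_series"]

N_CLASSES = 6  # character counts 1..6


@dataclass
class BoldRun:
    """One run of voxels x frames BOLD data sampled every ``tr`` seconds."""

    data: np.ndarray          # (n_voxels, n_frames)
    tr: float
    run_id: int
    frame_times: np.ndarray   # (n_frames,), frame i at i*tr after re-zeroing

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BOLD data must be finite")
        steps = np.diff(self.frame_times)
        if len(steps) and not np.allclose(steps, self.tr):
            raise ValueError("frame_times must increase in steps of tr")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]


@dataclass
class GroundTruth:
    """Planted-signal description for a synthetic session.

    ``class_patterns`` holds one spatial pattern per count (rows: counts
    1..6, columns: the informative voxels); the neural amplitude of
    informative voxel j during a count-c block is
    ``effect_scale * class_patterns[c-1, j]``.
    """

    informative_voxels: np.ndarray           # sorted voxel indices
    class_patterns: np.ndarray               # (6, n_informative)
    noise_params: tuple[float, float] = (1.0, 0.4)   # (white_sd, ar1_coeff)
    effect_scale: float = 1.0

    def __post_init__(self) -> None:
        self.informative_voxels = np.asarray(self.informative_voxels, dtype=int)
        self.class_patterns = np.atleast_2d(np.asarray(self.class_patterns, dtype=float))
        if self.class_patterns.shape != (N_CLASSES, len(self.informative_voxels)):
            raise ValueError("class_patterns must be (6, n_informative)")


def make_ground_truth(n_voxels: int, n_informative: int, seed: int,
                      white_sd: float = 1.0, ar1_coeff: float = 0.4,
                      effect_scale: float = 1.0,
                      ordinal_similarity: bool = False) -> GroundTruth:
    """Draw a random planted signal.

    Patterns are standard normal per class.  With ``ordinal_similarity``
    the six patterns form a random walk across the count axis, so adjacent
    counts get more similar patterns — mimicking decoders whose confusions
    concentrate just off the main diagonal.
    """
    if n_informative > n_voxels:
        raise ValueError("n_informative cannot exceed n_voxels")
    rng = np.random.default_rng(seed)
    voxels = np.sort(rng.choice(n_voxels, size=n_informative, replace=False))
    if ordinal_similarity:
        steps = rng.standard_normal((N_CLASSES, n_informative))
        patterns = np.cumsum(steps, axis=0)
    else:
        patterns = rng.standard_normal((N_CLASSES, n_informative))
    return GroundTruth(voxels, patterns, (white_sd, ar1_coeff), effect_scale)


def _ar1_noise(rng: np.random.Generator, shape: tuple[int, int],
               white_sd: float, ar1_coeff: float) -> np.ndarray:
    """White Gaussian innovations of sd white_sd passed through an AR(1)
    filter; ar1_coeff=0 reduces to pure white noise."""
    if white_sd == 0:
        return np.zeros(shape)
    innov = rng.normal(0.0, white_sd, size=shape)
    if ar1_coeff == 0:
        return innov
    out = np.empty(shape)
    out[:, 0] = innov[:, 0]
    for t in range(1, shape[1]):
        out[:, t] = ar1_coeff * out[:, t - 1] + innov[:, t]
    return out


def simulate_bold(schedule: EventSchedule, n_voxels: int, truth: GroundTruth,
                  hrf: np.ndarray | None = None, seed: int = 0) -> list[BoldRun]:
    """Simulate one BOLD run per schedule run.

    The neural time series of each informative voxel is the class pattern
    amplitude during character blocks and zero during travel; it is
    causally convolved with ``hrf`` (a kernel sampled at tr; ``None`` or an
    impulse leaves the boxcar unchanged), truncated at run end, and summed
    with AR(1) noise.  Identical arguments and seed give identical output.
    """
    if n_voxels < len(truth.informative_voxels):
        raise ValueError("n_voxels must cover all informative voxels")
    if hrf is None:
        hrf = np.array([1.0])
    hrf = np.asarray(hrf, dtype=float)
    rng = np.random.default_rng(seed)
    white_sd, ar1_coeff = truth.noise_params
    runs = []
    n_frames = schedule.n_frames_per_run
    for run_id in schedule.run_ids:
        counts = schedule.frame_counts(run_id)
        neural = np.zeros((n_voxels, n_frames))
        for c in range(1, N_CLASSES + 1):
            sel = counts == c
            if sel.any():
                neural[np.ix_(truth.informative_voxels, np.flatnonzero(sel))] = (
                    truth.effect_scale * truth.class_patterns[c - 1][:, None])
        sig = np.apply_along_axis(lambda v: np.convolve(v, hrf)[:n_frames], 1, neural)
        noise = _ar1_noise(rng, (n_voxels, n_frames), white_sd, ar1_coeff)
        runs.append(BoldRun(data=sig + noise, tr=schedule.tr, run_id=run_id,
                            frame_times=np.arange(n_frames) * schedule.tr))
    return runs


def simulate_contrast_series(schedule: EventSchedule, base: float = 1.0,
                             slope: float = 0.0, jitter_sd: float = 0.0,
                             seed: int = 0) -> list[np.ndarray]:
    """Per-frame total scene contrast for every run.

    contrast[t] = base + slope * count[t] + jitter[t], with the Gaussian
    jitter drawn once per frame position and reused across runs, so runs
    with the same count sequence produce identical series.
    """
    if base <= 0:
        raise ValueError("base must be positive")
    rng = np.random.default_rng(seed)
    jitter = rng.normal(0.0, jitter_sd, size=schedule.n_frames_per_run) \
        if jitter_sd > 0 else np.zeros(schedule.n_frames_per_run)
    series = []
    for run_id in schedule.run_ids:
        counts = schedule.frame_counts(run_id)
        series.append(base + slope * counts + jitter)
    return series
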