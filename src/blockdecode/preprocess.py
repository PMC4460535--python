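"""Temporal preprocessing: initial-frame discard and Wiener deconvolution.

Deconvolving the recorded BOLD signal with a canonical difference-of-gamma
hemodynamic response function mainly re-aligns the peak response with its
stimulus block (the hemodynamic delay is several seconds, i.e. a couple of
frames at TR 2.5 s), and provides some noise reduction.  The Wiener filter
is the standard regularized inverse: X(f) = conj(H(f)) Y(f) / (|H|^2 + nsr).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .simulate import BoldRun

__all__ = ["HrfKernel", "glover_hrf", "discard_initial", "wiener_deconvolve",
           "deconvolve_run"]

#: canonical difference-of-gamma parameters:
#: (delay1, delay2, dispersion1, dispersion2, undershoot_ratio), seconds
CANONICAL_HRF_PARAMS = (6.0, 16.0, 0.9, 0.9, 0.35)


@dataclass
class HrfKernel:
    """A causal hemodynamic response kernel sampled at tr, peak scaled to 1."""

    samples: np.ndarray
    tr: float
    params: tuple[float, float, float, float, float]

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("kernel samples must be finite")

    def __len__(self) -> int:
        return len(self.samples)


def glover_hrf(tr: float, duration: float = 32.0,
               params: tuple[float, float, float, float, float] | None = None
               ) -> HrfKernel:
    """Difference-of-gamma HRF sampled at multiples of tr over [0, duration].

    h(t) = g(t; delay1, disp1) - undershoot_ratio * g(t; delay2, disp2)
    where g is a gamma density with shape delay/dispersion and scale
    dispersion; the result is scaled so its peak value is 1.  With the
    canonical parameters the kernel peaks near 5 s and shows a negative
    post-stimulus undershoot.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    if duration < tr:
        raise ValueError("duration must be at least tr")
    if params is None:
        params = CANONICAL_HRF_PARAMS
    delay1, delay2, disp1, disp2, ratio = params
    if disp1 <= 0 or disp2 <= 0:
        raise ValueError("dispersions must be positive")
    t = np.arange(0.0, duration + 1e-9, tr)
    h = (stats.gamma.pdf(t, delay1 / disp1, scale=disp1)
         - ratio * stats.gamma.pdf(t, delay2 / disp2, scale=disp2))
    h = h / np.max(h)
    return HrfKernel(samples=h, tr=tr, params=params)


def discard_initial(run: BoldRun, seconds: float) -> BoldRun:
    """Drop the first ``seconds`` of a run (transient suppression).

    ``seconds`` must be a nonnegative multiple of tr and less than the run
    length; frame times are re-zeroed.  Event onsets must be shifted by the
    caller (see :func:`blockdecode.schedule.shift_schedule`).
    """
    n = seconds / run.tr
    if seconds < 0 or abs(n - round(n)) > 1e-9:
        raise ValueError("seconds must be a nonnegative multiple of tr")
    n = int(round(n))
    if n >= run.n_frames:
        raise ValueError("cannot discard the entire run")
    return BoldRun(data=run.data[:, n:], tr=run.tr, run_id=run.run_id,
                   frame_times=np.arange(run.n_frames - n) * run.tr)


def _next_pow2(n: int) -> int:
    return 1 << (n - 1).bit_length()


def wiener_deconvolve(ts: np.ndarray, kernel: HrfKernel | np.ndarray,
                      nsr: float = 0.02) -> np.ndarray:
    """Wiener-filter deconvolution of a 1-D (or voxels x frames) series.

    Frequency-domain estimate X(f) = conj(H(f)) / (|H(f)|^2 + nsr) * Y(f),
    inverse-transformed; the signal is zero-padded to the next power of two
    at least twice its length to guard against circular wrap-around.  At
    nsr=0 this is the exact inverse of convolution with the kernel.
    """
    h = kernel.samples if isinstance(kernel, HrfKernel) else np.asarray(kernel, float)
    if not np.any(h):
        raise ValueError("kernel must not be all zero")
    if nsr < 0:
        raise ValueError("nsr must be nonnegative")
    ts = np.asarray(ts, dtype=float)
    one_d = ts.ndim == 1
    Y2 = np.atleast_2d(ts)
    n = Y2.shape[1]
    if n < len(h):
        raise ValueError("series must be at least as long as the kernel")
    nfft = _next_pow2(2 * n)
    H = np.fft.rfft(h, nfft)
    denom = np.abs(H) ** 2 + nsr
    gain = np.where(denom > 0, np.conj(H) / np.where(denom > 0, denom, 1.0), 0.0)
    X = np.fft.irfft(np.fft.rfft(Y2, nfft, axis=1) * gain[None, :], nfft, axis=1)[:, :n]
    return X[0] if one_d else X


def deconvolve_run(run: BoldRun, kernel: HrfKernel, nsr: float = 0.02) -> BoldRun:
    """Per-voxel Wiener deconvolution; each voxel's series is mean-centered
    first and its mean restored after, keeping DC behavior predictable."""
    mean = run.data.mean(axis=1, keepdims=True)
    dcv = wiener_deconvolve(run.data - mean, kernel, nsr) + mean
    return BoldRun(data=dcv, tr=run.tr, run_id=run.run_id,
                   frame_times=run.frame_times.copy())
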