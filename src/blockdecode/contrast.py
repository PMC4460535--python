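"""Stimulus-contrast confound control.

Total scene contrast could co-vary with character count and drive the
decoder through low-level luminance statistics rather than neural
pattern.  The control analysis (1) measures per-frame RMS contrast,
(2) fits a GLM with one indicator regressor per count and t-tests each
count's contrast level against the grand mean, reports the Pearson
correlation between contrast and count over character-present frames, and
(3) trains a classifier on the 1-D total-contrast feature alone with a
two-fold design split (the first and second permutation halves of each
run are the only unique folds containing every count).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .baselines import make_classifier
from .dataset import ExampleSet

__all__ = ["ContrastSeries", "rms_contrast", "contrast_glm",
           "contrast_only_control", "series_from_schedule"]


@dataclass
class ContrastSeries:
    """Per-frame total contrast with count and run bookkeeping."""

    values: np.ndarray
    frame_counts: np.ndarray
    run_id: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.frame_counts = np.asarray(self.frame_counts, dtype=int)
        self.run_id = np.asarray(self.run_id, dtype=int)
        if not (len(self.values) == len(self.frame_counts) == len(self.run_id)):
            raise ValueError("values, frame_counts, run_id must align")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("contrast values must be finite and nonnegative")

    def to_csv(self, path) -> None:
        pd.DataFrame({"frame": np.arange(len(self.values)),
                      "run": self.run_id, "count": self.frame_counts,
                      "contrast": self.values}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ContrastSeries":
        df = pd.read_csv(path)
        return cls(df["contrast"].to_numpy(), df["count"].to_numpy(),
                   df["run"].to_numpy())


def series_from_schedule(schedule, per_run_values: list[np.ndarray]) -> ContrastSeries:
    """Stack per-run contrast arrays into one bookkept series."""
    vals, counts, runs = [], [], []
    for run_id, v in zip(schedule.run_ids, per_run_values):
        vals.append(np.asarray(v, float))
        counts.append(schedule.frame_counts(run_id))
        runs.append(np.full(len(v), run_id))
    return ContrastSeries(np.concatenate(vals), np.concatenate(counts),
                          np.concatenate(runs))


def rms_contrast(image: np.ndarray) -> float:
    """Root-mean-square contrast: sd of luminance divided by mean luminance."""
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("image must be nonempty")
    mean = image.mean()
    if mean <= 0:
        raise ValueError("mean luminance must be positive")
    return float(image.std() / mean)


def contrast_glm(series: ContrastSeries) -> dict:
    """Indicator-design GLM of contrast on count plus Pearson correlation.

    One indicator regressor per observed count (no global intercept), so
    each coefficient is that count's mean contrast; each coefficient is
    t-tested two-sided against the grand mean.  The Pearson r between
    contrast and count is computed over count>0 frames.
    """
    counts = np.unique(series.frame_counts)
    for c in counts:
        if np.sum(series.frame_counts == c) < 2:
            raise ValueError(f"count {c} present in fewer than 2 frames")
    X = np.column_stack([(series.frame_counts == c).astype(float) for c in counts])
    model = sm.OLS(series.values, X).fit()
    n = len(series.values)
    group_n = X.sum(axis=0)
    weights = group_n / n            # grand mean = sum_c (n_c/n) beta_c
    per_count = {}
    for i, c in enumerate(counts):
        L = -weights.copy()
        L[i] += 1.0                  # tests beta_c - grand mean = 0
        est = float(L @ model.params)
        se = float(np.sqrt(L @ model.cov_params() @ L))
        if se < 1e-12:               # zero-residual degenerate fit
            t_val, p_val = (0.0, 1.0) if abs(est) < 1e-12 else (np.inf, 0.0)
        else:
            tt = model.t_test(L)
            t_val, p_val = float(np.squeeze(tt.tvalue)), float(np.squeeze(tt.pvalue))
        per_count[int(c)] = {"beta": float(model.params[i]),
                             "t": t_val, "p": p_val}
    char = series.frame_counts > 0
    if np.std(series.values[char]) == 0 or np.std(series.frame_counts[char]) == 0:
        r, rp = 0.0, 1.0          # correlation undefined for a constant side
    else:
        r, rp = stats.pearsonr(series.values[char], series.frame_counts[char])
    return {"per_count": per_count, "pearson_r": float(r),
            "pearson_p": float(rp)}


def contrast_only_control(series: ContrastSeries, classifier_spec=None,
                          seed: int = 0) -> float:
    """Two-fold CV accuracy of a classifier on total contrast alone.

    Folds are the two half-designs: within each run the first six
    character blocks (one full permutation of counts 1-6) form fold A and
    the last six form fold B, so exactly two folds exist regardless of run
    count and each contains every count.
    """
    if len(np.unique(series.run_id)) < 2:
        raise ValueError("need at least 2 runs")
    char = series.frame_counts > 0
    fold = np.zeros(len(series.values), dtype=int)
    block_id = np.zeros(len(series.values), dtype=int)
    next_block = 0
    for run in np.unique(series.run_id):
        rows = np.flatnonzero((series.run_id == run) & char)
        # successive character epochs within the run
        breaks = np.flatnonzero(np.diff(rows) > 1)
        starts = np.r_[0, breaks + 1]
        ends = np.r_[breaks, len(rows) - 1]
        n_blocks = len(starts)
        for bi, (s, e) in enumerate(zip(starts, ends)):
            block_id[rows[s:e + 1]] = next_block
            fold[rows[s:e + 1]] = 0 if bi < n_blocks // 2 else 1
            next_block += 1
    accs = []
    for test_fold in (0, 1):
        tr = char & (fold != test_fold)
        te = char & (fold == test_fold)
        if len(np.unique(series.frame_counts[tr])) < 6 or \
                len(np.unique(series.frame_counts[te])) < 6:
            raise ValueError("each half-design fold must contain every count")
        trainset = ExampleSet(series.values[tr, None], series.frame_counts[tr],
                              block_id[tr], series.run_id[tr])
        clf = make_classifier(classifier_spec)
        clf.fit(trainset, seed=seed)
        pred = clf.predict(series.values[te, None])
        accs.append(float(np.mean(pred == series.frame_counts[te])))
    return float(np.mean(accs))
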