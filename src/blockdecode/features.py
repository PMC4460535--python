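"""Univariate ANOVA voxel selection, nested inside cross-validation folds.

Two grouping modes mirror the two uses of ANOVA in block-design decoding:
``task_activated`` contrasts character-present vs travel frames (binary),
``classification_target`` contrasts the six count labels directly.
Selection must only ever see training-fold rows; the cross-validation
driver enforces that.
"""

from __future__ import annotations

import numpy as np
from scipy import special

from .dataset import ExampleSet

__all__ = ["anova_f", "select_features", "DEFAULT_K"]

#: default number of voxels kept by selection
DEFAULT_K = 2000


def anova_f(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-way ANOVA F statistic and upper-tail p-value per feature (column).

    Degenerate features with zero within- and between-class variance
    report F = 0, p = 1.  Requires >= 2 classes with >= 2 examples each.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    if np.any(counts < 2):
        raise ValueError("every class needs at least two examples")
    n = len(y)
    grand = X.mean(axis=0)
    ssb = np.zeros(X.shape[1])
    ssw = np.zeros(X.shape[1])
    for c, nc in zip(classes, counts):
        g = X[y == c]
        m = g.mean(axis=0)
        ssb += nc * (m - grand) ** 2
        ssw += ((g - m) ** 2).sum(axis=0)
    dfb = len(classes) - 1
    dfw = n - len(classes)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / dfb) / (ssw / dfw)
    p = special.fdtrc(dfb, dfw, np.where(np.isfinite(F), F, 0.0))
    degenerate = (ssb < 1e-300) & (ssw < 1e-300)
    F = np.where(degenerate, 0.0, F)
    p = np.where(degenerate, 1.0, p)
    # zero within-class variance but real between-class spread: infinitely
    # significant; report a large finite F so ranking stays well defined
    blown = ~np.isfinite(F)
    F = np.where(blown, np.finfo(float).max, F)
    p = np.where(blown, 0.0, p)
    return F, p


def select_features(trainset: ExampleSet, mode: str = "classification_target",
                    k: int = DEFAULT_K) -> np.ndarray:
    """Indices (columns of trainset.X) of the k largest-F features.

    mode ``task_activated`` groups frames by characters-present (count>0)
    vs travel; ``classification_target`` groups by the count label itself
    (travel frames, if present, are excluded).  Ties break by ascending
    feature index, and the selected set for k is always a subset of the
    set for any larger k.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > trainset.n_features:
        raise ValueError("k exceeds the number of features")
    if mode == "task_activated":
        labels = (np.asarray(trainset.y) != 0).astype(int)
        if len(np.unique(labels)) < 2:
            raise ValueError("task_activated mode requires travel (count-0) frames")
        F, _ = anova_f(trainset.X, labels)
    elif mode == "classification_target":
        keep = np.asarray(trainset.y) != 0
        F, _ = anova_f(trainset.X[keep], trainset.y[keep])
    else:
        raise ValueError(f"unknown selection mode: {mode!r}")
    order = np.lexsort((np.arange(len(F)), -F))
    return np.sort(order[:k])
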