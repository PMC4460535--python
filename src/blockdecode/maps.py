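"""Volumetric decoding maps: searchlight, GLM t-maps, percent coverage.

These are the reference mapping techniques the sensitivity map is
compared against.  The searchlight scores each voxel by the
cross-validated accuracy of a classifier restricted to a small (default
3x3x3) neighborhood; the GLM scores each voxel by the largest absolute t
statistic across per-count regressors of an ordinary least-squares fit.
Percent coverage summarizes a thresholded map as the fraction of its
supra-threshold voxels falling in each region of an anatomical partition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dataset import ExampleSet
from .evaluate import CHANCE_LEVEL, cross_validate

__all__ = ["VoxelMap", "searchlight", "glm_map", "percent_coverage"]


@dataclass
class VoxelMap:
    """Scalar per-voxel map with 0-based (i, j, k) coordinates (x-fastest
    flattening) and a display threshold."""

    values: np.ndarray          # (N,); NaN marks missing
    voxel_index: np.ndarray     # (N, 3) int
    threshold: float
    kind: str                   # sensitivity | searchlight_accuracy | glm_t
    shape: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.voxel_index = np.atleast_2d(np.asarray(self.voxel_index, dtype=int))
        if len(self.values) != self.voxel_index.shape[0]:
            raise ValueError("values and voxel_index must have equal length")
        if self.shape is not None:
            if np.any(self.voxel_index < 0) or \
                    np.any(self.voxel_index >= np.asarray(self.shape)):
                raise ValueError("voxel coordinates outside the volume")

    def to_volume(self) -> np.ndarray:
        if self.shape is None:
            raise ValueError("shape unknown")
        vol = np.full(self.shape, np.nan)
        vol[tuple(self.voxel_index.T)] = self.values
        return vol

    @property
    def supra_threshold(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.flatnonzero(self.values > self.threshold)


def _mask_coords(mask: np.ndarray) -> np.ndarray:
    # x-fastest flattening: iterate k, then j, then i innermost
    return np.argwhere(mask.transpose(2, 1, 0))[:, ::-1]


def searchlight(data4d: np.ndarray, y, block_id, run_id,
                mask: np.ndarray | None = None,
                kernel_shape: tuple[int, int, int] = (3, 3, 3),
                classifier_spec=None, cv_args: dict | None = None,
                seed: int = 0) -> VoxelMap:
    """Cross-validated accuracy of a local classifier at every voxel.

    ``data4d`` is (nx, ny, nz, n_frames); features at a center voxel are
    the in-mask voxels of the kernel neighborhood, truncated at volume and
    mask boundaries.  Default classifier is the linear SVM; the map is
    thresholded at twice chance accuracy.
    """
    data4d = np.asarray(data4d, dtype=float)
    if data4d.ndim != 4:
        raise ValueError("data4d must be 4-D")
    if any(s % 2 == 0 for s in kernel_shape):
        raise ValueError("kernel dimensions must be odd")
    shape = data4d.shape[:3]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    cv_args = dict(cv_args or {})
    cv_args.setdefault("split_unit", "block")
    cv_args.setdefault("k", 4)
    rng = np.random.default_rng(seed)
    radii = [s // 2 for s in kernel_shape]
    coords = _mask_coords(mask)
    values = np.empty(len(coords))
    for n, (i, j, kk) in enumerate(coords):
        sl = tuple(slice(max(0, c - r), min(s, c + r + 1))
                   for c, r, s in zip((i, j, kk), radii, shape))
        local_mask = np.zeros(shape, dtype=bool)
        local_mask[sl] = True
        local_mask &= mask
        feats = data4d[local_mask].T            # frames x neighborhood voxels
        if feats.shape[1] == 0:
            values[n] = np.nan
            continue
        sub = ExampleSet(feats, y, block_id, run_id)
        res = cross_validate(sub, classifier_spec=classifier_spec,
                             seed=int(rng.integers(2 ** 31)), **cv_args)
        values[n] = res.mean_accuracy
    return VoxelMap(values=values, voxel_index=coords,
                    threshold=2 * CHANCE_LEVEL, kind="searchlight_accuracy",
                    shape=shape)


def glm_map(data, design: np.ndarray, mask: np.ndarray | None = None,
            columns: np.ndarray | None = None) -> VoxelMap:
    """Per-voxel OLS fit; map value = max |t| across the given regressor
    columns (default: all).

    ``data`` may be 4-D (nx, ny, nz, frames) with an optional mask, or a
    2-D voxels x frames matrix.
    """
    design = np.atleast_2d(np.asarray(design, dtype=float))
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("design matrix must have full column rank")
    data = np.asarray(data, dtype=float)
    if data.ndim == 4:
        shape = data.shape[:3]
        if mask is None:
            mask = np.ones(shape, dtype=bool)
        coords = _mask_coords(mask)
        Y = data[tuple(coords.T)]               # voxels x frames
    elif data.ndim == 2:
        shape = None
        coords = np.column_stack([np.arange(data.shape[0]),
                                  np.zeros(data.shape[0], int),
                                  np.zeros(data.shape[0], int)])
        Y = data
    else:
        raise ValueError("data must be 2-D or 4-D")
    n, p = design.shape
    if Y.shape[1] != n:
        raise ValueError("frame count mismatch between data and design")
    pinv = np.linalg.pinv(design)
    beta = Y @ pinv.T                           # voxels x p
    resid = Y - beta @ design.T
    dof = n - p
    sigma2 = (resid ** 2).sum(axis=1) / max(dof, 1)
    var_b = np.diag(pinv @ pinv.T)              # (X'X)^-1 diagonal
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / np.sqrt(sigma2[:, None] * var_b[None, :])
    t = np.where(np.isfinite(t), t, 0.0)
    if columns is None:
        columns = np.arange(p)
    values = np.abs(t[:, columns]).max(axis=1)
    return VoxelMap(values=values, voxel_index=coords, threshold=0.0,
                    kind="glm_t", shape=shape)


def percent_coverage(vmap: VoxelMap, partition: np.ndarray) -> list[tuple[object, float]]:
    """Fraction of supra-threshold voxels in each partition label.

    ``partition`` is either a 3-D label volume indexed by the map's voxel
    coordinates or a 1-D per-voxel label array aligned with the map.
    Voxels with an empty/None label count toward "other".  Fractions sum
    to one; an empty supra-threshold set yields all-zero fractions (and a
    warning).
    """
    partition = np.asarray(partition)
    if partition.ndim == 3:
        labels = partition[tuple(vmap.voxel_index.T)]
    elif partition.ndim == 1:
        if len(partition) != len(vmap.values):
            raise ValueError("per-voxel partition length mismatch")
        labels = partition
    else:
        raise ValueError("partition must be 1-D or 3-D")
    labels = np.array(["other" if l is None or str(l) == "" else l
                       for l in labels.tolist()], dtype=object)
    supra = vmap.supra_threshold
    out_labels = sorted(set(labels.tolist()), key=str)
    if len(supra) == 0:
        warnings.warn("empty supra-threshold set; all fractions are zero")
        return [(l, 0.0) for l in out_labels]
    sub = labels[supra]
    return [(l, float(np.mean(sub == l))) for l in out_labels]
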