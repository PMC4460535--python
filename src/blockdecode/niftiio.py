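"""NIfTI reading/writing for runs, masks, and maps (via nibabel)."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .maps import VoxelMap
from .simulate import BoldRun

__all__ = ["write_run_nifti", "read_run_nifti", "write_map_nifti",
           "write_mask_nifti", "read_label_volume", "volume_from_run"]


def volume_from_run(run: BoldRun, shape: tuple[int, int, int] | None = None) -> np.ndarray:
    """Reshape a voxels x frames run into a 4-D volume (x-fastest order).

    Without an explicit shape, voxels are laid out along x as (n, 1, 1)."""
    if shape is None:
        shape = (run.n_voxels, 1, 1)
    if int(np.prod(shape)) != run.n_voxels:
        raise ValueError("shape does not match the voxel count")
    return run.data.reshape(*shape[::-1], run.n_frames).transpose(2, 1, 0, 3)


def write_run_nifti(run: BoldRun, path: str | Path,
                    shape: tuple[int, int, int] | None = None,
                    voxel_mm: float = 2.5) -> None:
    vol = volume_from_run(run, shape)
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    img = nib.Nifti1Image(vol.astype(np.float32), affine)
    img.header.set_zooms((voxel_mm, voxel_mm, voxel_mm, run.tr))
    nib.save(img, str(path))


def read_run_nifti(path: str | Path, run_id: int = 0,
                   tr: float | None = None) -> tuple[BoldRun, tuple[int, int, int]]:
    img = nib.load(str(path))
    vol = np.asarray(img.get_fdata())
    if vol.ndim != 4:
        raise ValueError("expected a 4-D NIfTI")
    if tr is None:
        tr = float(img.header.get_zooms()[3])
    shape = vol.shape[:3]
    data = vol.transpose(2, 1, 0, 3).reshape(-1, vol.shape[3])  # x-fastest
    run = BoldRun(data=data, tr=tr, run_id=run_id,
                  frame_times=np.arange(vol.shape[3]) * tr)
    return run, shape


def write_map_nifti(vmap: VoxelMap, path: str | Path, voxel_mm: float = 2.5) -> None:
    if vmap.shape is None:
        raise ValueError("map has no volume shape")
    vol = np.nan_to_num(vmap.to_volume(), nan=0.0)
    nib.save(nib.Nifti1Image(vol.astype(np.float32),
                             np.diag([voxel_mm] * 3 + [1.0])), str(path))


def write_mask_nifti(mask: np.ndarray, path: str | Path, voxel_mm: float = 2.5) -> None:
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8),
                             np.diag([voxel_mm] * 3 + [1.0])), str(path))


def read_label_volume(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata()).astype(int)
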