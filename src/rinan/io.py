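"""NIfTI input/output and masking.

Converts 4D NIfTI time series into :class:`~rinan.containers.BoldRun`
matrices (one column per in-mask voxel, Fortran voxel ordering) and writes
:class:`~rinan.containers.SpatialMap` objects back to disk with out-of-mask
voxels set to 0.  Every downstream module consumes only the in-memory
containers, never raw files.
"""

from __future__ import annotations

import logging
import os

import nibabel as nib
import numpy as np
import pandas as pd

from .containers import BoldRun, MaskIndex, SpatialMap, VolumeGrid

logger = logging.getLogger(__name__)


def _load_img(path_or_img):
    if isinstance(path_or_img, (str, os.PathLike)):
        return nib.load(os.fspath(path_or_img))
    return path_or_img


def read_mask(path_or_img, label: str = "mask") -> SpatialMap:
    """Read a 3D binary mask NIfTI into a SpatialMap of ones."""
    img = _load_img(path_or_img)
    arr = np.asanyarray(img.dataobj)
    if arr.ndim == 4 and arr.shape[3] == 1:
        arr = arr[..., 0]
    if arr.ndim != 3:
        raise ValueError(f"mask must be 3D, got shape {arr.shape}")
    grid = VolumeGrid(arr.shape, img.affine)
    idx = MaskIndex(arr != 0)
    return SpatialMap(np.ones(idx.n_voxels), idx, grid, label=label)


def read_bold(path_or_img, mask, drop_initial: int = 0,
              subject_id: str = "") -> BoldRun:
    """Read a 4D NIfTI run, drop leading volumes, and apply the brain mask.

    Parameters
    ----------
    mask : SpatialMap or path
        Binary mask on the same grid as the image.
    drop_initial : int
        Number of initial volumes to discard (magnetisation-equilibration
        scrubbing; e.g. the first 10 volumes of a 152-volume acquisition).
    """
    img = _load_img(path_or_img)
    if len(img.shape) != 4:
        raise ValueError(f"expected a 4D image, got shape {img.shape}")
    if not isinstance(mask, SpatialMap):
        mask = read_mask(mask)
    if tuple(img.shape[:3]) != tuple(mask.grid.dims):
        raise ValueError(
            f"grid mismatch: image {img.shape[:3]} vs mask {mask.grid.dims}"
        )
    if drop_initial < 0:
        raise ValueError("drop_initial must be nonnegative")
    data4d = np.asanyarray(img.dataobj)[..., drop_initial:]
    if data4d.shape[3] < 1:
        raise ValueError("drop_initial removed every volume")
    # (x,y,z,t) -> (t, voxels) through the mask index
    masked = mask.mask_index.mask_volume(np.moveaxis(data4d, -1, 0))
    return BoldRun(masked.astype(float), mask.mask_index, mask.grid,
                   subject_id=subject_id)


def center_and_scale(run: BoldRun, mode: str = "voxel_mean") -> BoldRun:
    """Remove each voxel's temporal mean, optionally scaling to unit variance.

    mode "voxel_mean" subtracts the per-column mean; "voxel_zscore"
    additionally divides by the per-column standard deviation.  Columns with
    zero variance become all-zero series (real masks contain flat voxels) and
    a warning is logged.
    """
    if run.n_time < 2:
        raise ValueError("need at least 2 time points to centre")
    if mode not in ("voxel_mean", "voxel_zscore"):
        raise ValueError(f"unknown mode {mode!r}")
    data = run.data - run.data.mean(axis=0, keepdims=True)
    if mode == "voxel_zscore":
        sd = data.std(axis=0, keepdims=True)
        flat = sd[0] == 0
        if flat.any():
            logger.warning("%d zero-variance voxels set to all-zero series",
                           int(flat.sum()))
        sd[0, flat] = 1.0
        data = data / sd
    return run.with_data(data)


def map_to_nifti(spatial_map: SpatialMap, path) -> None:
    """Write a SpatialMap as a 3D NIfTI; out-of-mask voxels are 0."""
    vol = spatial_map.to_volume(fill=0.0).astype(np.float32)
    nib.save(nib.Nifti1Image(vol, spatial_map.grid.affine), os.fspath(path))


def nifti_to_map(path_or_img, mask: SpatialMap, label: str = "") -> SpatialMap:
    """Read a 3D NIfTI into a SpatialMap on the given mask."""
    img = _load_img(path_or_img)
    arr = np.asanyarray(img.dataobj)
    if arr.ndim == 4 and arr.shape[3] == 1:
        arr = arr[..., 0]
    if arr.ndim != 3:
        raise ValueError(f"expected a 3D map, got shape {arr.shape}")
    if tuple(arr.shape) != tuple(mask.grid.dims):
        raise ValueError(
            f"grid mismatch: map {arr.shape} vs mask {mask.grid.dims}"
        )
    return SpatialMap(mask.mask_index.mask_volume(arr.astype(float)),
                      mask.mask_index, mask.grid, label=label)


def maps_to_nifti(maps: list[SpatialMap], path) -> None:
    """Write a stack of SpatialMaps as one 4D NIfTI (map axis last)."""
    vols = np.stack([m.to_volume() for m in maps], axis=-1).astype(np.float32)
    nib.save(nib.Nifti1Image(vols, maps[0].grid.affine), os.fspath(path))


def timecourses_to_tsv(tcs: np.ndarray, labels: list[str], path) -> None:
    """Write time courses (one column per component, labelled header) as TSV."""
    pd.DataFrame(np.asarray(tcs).T, columns=labels).to_csv(
        path, sep="\t", index=False)
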