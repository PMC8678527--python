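"""In-memory containers shared by every stage of the pipeline.

All algorithms operate on masked time-by-voxel matrices (:class:`BoldRun`) and
flat per-voxel vectors (:class:`SpatialMap`); NIfTI files are converted to and
from these containers at the edges (:mod:`rinan.io`) and nowhere else.

Voxel ordering is fixed and documented: in-mask voxels are enumerated in
column-major (Fortran) order over (x, y, z), i.e. x varies fastest.  The same
mask therefore always yields the same column ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass(frozen=True)
class VolumeGrid:
    """Geometry of a 3D sampling grid.

    Parameters
    ----------
    dims : tuple of int
        Number of voxels along (x, y, z).
    affine : (4, 4) ndarray
        Voxel-index -> world-mm mapping (NIfTI convention, 0-based indices).
    """

    dims: tuple[int, int, int]
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        dims = tuple(int(d) for d in self.dims)
        if len(dims) != 3 or any(d <= 0 for d in dims):
            raise ValueError(f"dims must be 3 positive integers, got {self.dims!r}")
        object.__setattr__(self, "dims", dims)
        aff = self.affine
        if aff is None:
            aff = np.eye(4)
        aff = np.asarray(aff, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValueError("affine must be invertible")
        object.__setattr__(self, "affine", aff)

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Voxel edge lengths in mm (column norms of the linear part)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_to_world(self, ijk) -> np.ndarray:
        """Map 0-based voxel indices to world-mm coordinates."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        homog = np.c_[ijk, np.ones(len(ijk))]
        return np.squeeze((self.affine @ homog.T).T[:, :3])


class MaskIndex:
    """Mapping between matrix columns and 3D voxel indices of a binary mask.

    Columns follow Fortran (x-fastest) order over the mask's nonzero voxels,
    so the ordering is a pure function of the mask array.
    """

    def __init__(self, mask: np.ndarray):
        mask = np.asarray(mask)
        if mask.ndim != 3:
            raise ValueError("mask must be a 3D array")
        self.shape = mask.shape
        self.flat_f = np.flatnonzero(mask.ravel(order="F") != 0)
        if self.flat_f.size == 0:
            raise ValueError("mask is empty (no nonzero voxels)")
        ix, iy, iz = np.unravel_index(self.flat_f, self.shape, order="F")
        self.voxels = np.column_stack([ix, iy, iz])

    @property
    def n_voxels(self) -> int:
        return int(self.flat_f.size)

    def unmask(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter a flat per-voxel vector back into a full 3D volume."""
        values = np.asarray(values)
        if values.shape[-1] != self.n_voxels:
            raise ValueError("value length does not match mask voxel count")
        vol = np.full(int(np.prod(self.shape)), fill, dtype=float)
        vol[self.flat_f] = values
        return vol.reshape(self.shape, order="F")

    def mask_volume(self, volume: np.ndarray) -> np.ndarray:
        """Extract in-mask values from a full 3D (or 4D, last-axes-3D) volume."""
        volume = np.asarray(volume)
        if volume.shape[-3:] != self.shape:
            raise ValueError(
                f"volume shape {volume.shape} does not match mask shape {self.shape}"
            )
        flat = volume.reshape(volume.shape[:-3] + (-1,), order="C")
        # re-derive Fortran flat indices as C flat indices
        ix, iy, iz = self.voxels.T
        c_flat = np.ravel_multi_index((ix, iy, iz), self.shape, order="C")
        return flat[..., c_flat]

    def __eq__(self, other):
        return (
            isinstance(other, MaskIndex)
            and self.shape == other.shape
            and np.array_equal(self.flat_f, other.flat_f)
        )


@dataclass
class SpatialMap:
    """A flat per-voxel statistical map over the in-mask voxels."""

    values: np.ndarray
    mask_index: MaskIndex
    grid: VolumeGrid
    label: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size != self.mask_index.n_voxels:
            raise ValueError("map length does not match mask voxel count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spatial map contains non-finite values")

    @property
    def n_voxels(self) -> int:
        return self.values.size

    def zscored(self, label: str | None = None) -> "SpatialMap":
        """Return a copy scaled to zero mean, unit variance over the mask."""
        v = self.values - self.values.mean()
        sd = v.std()
        if sd > 0:
            v = v / sd
        return SpatialMap(v, self.mask_index, self.grid,
                          self.label if label is None else label)

    def to_volume(self, fill: float = 0.0) -> np.ndarray:
        return self.mask_index.unmask(self.values, fill=fill)


@dataclass
class BoldRun:
    """One subject's masked fMRI run as an n_time x n_voxels matrix."""

    data: np.ndarray
    mask_index: MaskIndex
    grid: VolumeGrid
    subject_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("BoldRun data must be 2D (time x voxels)")
        if self.data.shape[1] != self.mask_index.n_voxels:
            raise ValueError("data column count does not match mask voxel count")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BoldRun contains non-finite values")

    @property
    def n_time(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray) -> "BoldRun":
        return replace(self, data=data)
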