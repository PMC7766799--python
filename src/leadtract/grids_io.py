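"""Volume data model and NIfTI-1 I/O shared by all imaging stages.

A :class:`VolumeGrid` is a 3-D scalar field together with a 4x4 affine
mapping 0-based voxel indices to world millimetre coordinates (RAS
convention; a voxel's world position is its centre).  It carries tract
probability maps, electric-field maps and binary stimulation-volume
masks, and provides world/voxel transforms and resampling between
grid geometries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "VolumeGrid",
    "TractProbabilityMap",
    "VTAMask",
    "read_volume",
    "write_volume",
    "world_to_voxel",
    "voxel_to_world",
    "resample_to",
]

_DET_EPS = 1e-12


@dataclass
class VolumeGrid:
    """3-D scalar field with a voxel-index -> world-mm affine.

    Parameters
    ----------
    data:
        3-D array.  Dimensionless (probabilities, masks) or V/mm
        (field maps), depending on role.
    affine:
        4x4 homogeneous transform taking 0-based voxel indices to
        world millimetre coordinates.  Must be invertible.
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got {self.data.ndim} dims")
        if min(self.data.shape) < 1:
            raise ValueError("every axis must have extent >= 1")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < _DET_EPS:
            raise ValueError("singular affine: voxel axes do not span 3-D space")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3 (|det| of the 3x3 affine block)."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        return world_to_voxel(self, points)

    def voxel_to_world(self, indices: np.ndarray) -> np.ndarray:
        return voxel_to_world(self, indices)

    def voxel_centers_world(self) -> np.ndarray:
        """World coordinates of every voxel centre, shape (nx, ny, nz, 3)."""
        idx = np.indices(self.shape, dtype=float)  # (3, nx, ny, nz)
        ijk = np.moveaxis(idx, 0, -1)
        return voxel_to_world(self, ijk.reshape(-1, 3)).reshape(*self.shape, 3)

    def like(self, data: np.ndarray) -> "VolumeGrid":
        """New grid with the same geometry and different data."""
        if data.shape != self.shape:
            raise ValueError("data shape does not match grid shape")
        return VolumeGrid(data=data, affine=self.affine.copy())


@dataclass
class TractProbabilityMap:
    """Track probability map: per-voxel probability a tract traverses it.

    Values are normalized streamline visitation frequencies in [0, 1];
    ``n_streamlines`` is the total number of streamline samples used as
    the normalizer.
    """

    grid: VolumeGrid
    n_streamlines: int

    def __post_init__(self) -> None:
        if self.n_streamlines < 1:
            raise ValueError("n_streamlines must be a positive integer")
        v = self.grid.data
        if v.min() < 0.0 or v.max() > 1.0 + 1e-9:
            raise ValueError("tract probabilities must lie in [0, 1]")
        if not (v > 0).any():
            raise ValueError("empty tract map: no voxel has positive probability")


@dataclass
class VTAMask:
    """Binary volume-of-tissue-activated mask with its stimulation provenance."""

    grid: VolumeGrid
    provenance: str = ""

    def __post_init__(self) -> None:
        vals = np.unique(self.grid.data)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("VTA mask must be strictly binary (0/1)")

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.grid.data))


def read_volume(path: str | Path) -> VolumeGrid:
    """Read a NIfTI-1 volume into a :class:`VolumeGrid`.

    Raises a descriptive error for missing files, non-3-D images and
    singular affines.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D image, got shape {data.shape}")
    return VolumeGrid(data=data, affine=np.asarray(img.affine, dtype=float))


def write_volume(grid: VolumeGrid, path: str | Path, *, as_mask: bool = False) -> Path:
    """Write a grid as NIfTI-1.

    Masks are stored as unsigned 8-bit, everything else as 32-bit float.
    """
    path = Path(path)
    dtype = np.uint8 if as_mask else np.float32
    img = nib.Nifti1Image(grid.data.astype(dtype), grid.affine)
    nib.save(img, str(path))
    return path


def world_to_voxel(grid: VolumeGrid, points: np.ndarray) -> np.ndarray:
    """Map world mm coordinates to continuous 0-based voxel indices.

    Out-of-bounds indices are returned unmodified, never clamped.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    inv = np.linalg.inv(grid.affine)
    homog = np.c_[pts, np.ones(len(pts))]
    out = homog @ inv.T
    res = out[:, :3]
    return res[0] if np.asarray(points).ndim == 1 else res


def voxel_to_world(grid: VolumeGrid, indices: np.ndarray) -> np.ndarray:
    """Map continuous voxel indices to world mm coordinates (voxel centres)."""
    idx = np.atleast_2d(np.asarray(indices, dtype=float))
    homog = np.c_[idx, np.ones(len(idx))]
    out = homog @ grid.affine.T
    res = out[:, :3]
    return res[0] if np.asarray(indices).ndim == 1 else res


def resample_to(grid: VolumeGrid, target: VolumeGrid, method: str = "trilinear") -> VolumeGrid:
    """Resample ``grid`` onto the geometry of ``target``.

    ``method`` is ``"nearest"`` or ``"trilinear"``.  Points outside the
    source extent fill with 0 (no tract / no field outside the mapped
    region).  The output shares ``target``'s shape and affine.
    """
    if method == "nearest":
        order = 0
    elif method == "trilinear":
        order = 1
    else:
        raise ValueError(f"unknown resampling method {method!r}; use 'nearest' or 'trilinear'")
    # target voxel index -> world -> source voxel index
    composite = np.linalg.inv(grid.affine) @ target.affine
    idx = np.indices(target.shape, dtype=float)
    ijk = np.moveaxis(idx, 0, -1).reshape(-1, 3)
    src = np.c_[ijk, np.ones(len(ijk))] @ composite.T
    coords = src[:, :3].T.reshape(3, *target.shape)
    out = ndimage.map_coordinates(
        grid.data.astype(float), coords, order=order, mode="constant", cval=0.0
    )
    return VolumeGrid(data=out, affine=target.affine.copy())


def grids_aligned(a: VolumeGrid, b: VolumeGrid, tol: float = 1e-6) -> bool:
    """True if two grids share shape and affine to within ``tol``."""
    return a.shape == b.shape and bool(np.allclose(a.affine, b.affine, atol=tol))
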