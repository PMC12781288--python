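"""Volume data model, NIfTI I/O, and voxel<->world coordinate arithmetic.

All world coordinates are RAS+ millimetres (the MNI convention).  Input
NIfTI volumes are reoriented to canonical RAS+ on load so that downstream
sphere placement and peak reporting never have to reason about axis flips.
Voxel indices are 0-based.  Out-of-mask voxels are stored as 0 and the mask
is carried separately; statistics only ever read in-mask voxels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

#: scalar volume semantics recognised by the pipeline
VOLUME_KINDS = ("z", "mean_z", "t", "count", "fraction", "binary", "contrast")

GRID_ATOL = 1e-6


class GridMismatchError(ValueError):
    """Two volumes that must share a grid do not."""


class VolumeDimensionError(ValueError):
    """A NIfTI file does not have the expected dimensionality."""


@dataclass(frozen=True)
class VolumeGrid:
    """A voxel lattice plus the affine mapping voxel indices to world mm.

    Parameters
    ----------
    shape
        Number of voxels along each of the three axes.
    affine
        4x4 matrix mapping homogeneous 0-based voxel indices to RAS+ world
        coordinates in millimetres.  Must be invertible.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValueError(f"grid shape must be 3 positive integers, got {self.shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {affine.shape}")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        affine = affine.copy()
        affine.setflags(write=False)
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Voxel edge lengths in mm (column norms of the affine)."""
        return np.linalg.norm(np.asarray(self.affine)[:3, :3], axis=0)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (continuous) voxel indices, shape (..., 3), to world mm."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ np.asarray(self.affine)[:3, :3].T + np.asarray(self.affine)[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Map world mm coordinates, shape (..., 3), to continuous voxel indices."""
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(np.asarray(self.affine))
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def world_to_nearest_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """As :meth:`world_to_voxel` but rounded half-away-from-zero to ints."""
        cont = self.world_to_voxel(xyz)
        return _round_half_away(cont).astype(np.int64)

    def contains_voxel(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.asarray(ijk)
        return np.all((ijk >= 0) & (ijk < np.asarray(self.shape)), axis=-1)

    def all_voxel_world_coords(self) -> np.ndarray:
        """World coordinates of every voxel center, shape ``shape + (3,)``."""
        idx = np.indices(self.shape).reshape(3, -1).T
        return self.voxel_to_world(idx).reshape(self.shape + (3,))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VolumeGrid):
            return NotImplemented
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=GRID_ATOL, rtol=0.0
        )

    def __hash__(self) -> int:  # frozen dataclass with approximate eq: hash on shape
        return hash(self.shape)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer with ties going away from zero (deterministic)."""
    x = np.asarray(x, dtype=float)
    return np.trunc(x + np.copysign(0.5, x))


def check_same_grid(a: VolumeGrid, b: VolumeGrid, what: str = "volumes") -> None:
    if a != b:
        raise GridMismatchError(
            f"{what} are not on the same grid: shapes {a.shape} vs {b.shape}; "
            "all pipeline volumes must share one grid (no silent resampling)"
        )


@dataclass
class BrainMask:
    """Binary analysis mask on the pipeline grid.

    ``n_voxels`` is the Bonferroni denominator of the voxelwise threshold
    (285,903 for the 2 mm MNI-space mask used in the original analysis).
    """

    grid: VolumeGrid
    data: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.shape != self.grid.shape:
            raise ValueError(f"mask shape {data.shape} != grid shape {self.grid.shape}")
        self.data = data.astype(bool)
        if self.n_voxels < 1:
            raise ValueError("brain mask is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def flat_indices(self) -> np.ndarray:
        """Flat (C-order) indices of in-mask voxels: the pipeline voxel ordering."""
        return np.flatnonzero(self.data.ravel())

    def world_coords(self) -> np.ndarray:
        """World mm coordinates of in-mask voxel centers, shape (n_voxels, 3)."""
        ijk = np.argwhere(self.data)
        return self.grid.voxel_to_world(ijk)


@dataclass
class ScalarVolume:
    """A real-valued volume on the pipeline grid with declared semantics."""

    grid: VolumeGrid
    data: np.ndarray
    kind: str = "z"

    def __post_init__(self) -> None:
        if self.kind not in VOLUME_KINDS:
            raise ValueError(f"unknown volume kind {self.kind!r}; expected one of {VOLUME_KINDS}")
        data = np.asarray(self.data, dtype=float)
        if data.shape != self.grid.shape:
            raise ValueError(f"data shape {data.shape} != grid shape {self.grid.shape}")
        self.data = data
        if self.kind == "binary":
            vals = np.unique(data)
            if not np.all(np.isin(vals, (0.0, 1.0))):
                raise ValueError("kind='binary' volume contains values outside {0, 1}")
        if self.kind == "fraction" and (np.nanmin(data) < 0 or np.nanmax(data) > 1):
            raise ValueError("kind='fraction' volume contains values outside [0, 1]")

    def values_in(self, mask: BrainMask) -> np.ndarray:
        """In-mask values in the pipeline voxel ordering."""
        check_same_grid(self.grid, mask.grid)
        return self.data[mask.data]


def volume_from_vector(
    values: np.ndarray, mask: BrainMask, kind: str = "z"
) -> ScalarVolume:
    """Scatter an in-mask value vector back into a full 3D volume (0 outside)."""
    values = np.asarray(values, dtype=float)
    if values.shape != (mask.n_voxels,):
        raise ValueError(f"expected {mask.n_voxels} values, got {values.shape}")
    data = np.zeros(mask.grid.shape, dtype=float)
    data[mask.data] = values
    return ScalarVolume(grid=mask.grid, data=data, kind=kind)


def _grid_from_img(img: nib.Nifti1Image) -> VolumeGrid:
    return VolumeGrid(shape=tuple(img.shape[:3]), affine=np.asarray(img.affine))


def read_volume(path) -> ScalarVolume | BrainMask:
    """Read a 3D NIfTI volume, reorienting to canonical RAS+.

    Returns a :class:`BrainMask` when all values are 0/1, else a
    :class:`ScalarVolume` (kind ``z`` by default; callers re-tag as needed).
    """
    img = nib.load(str(path))
    if img.ndim != 3:
        raise VolumeDimensionError(f"{path}: expected a 3D volume, got {img.ndim}D")
    canonical = nib.as_closest_canonical(img)
    if not np.allclose(canonical.affine, img.affine):
        logger.info("reoriented %s to canonical RAS+", path)
    data = np.asarray(canonical.get_fdata(), dtype=float)
    grid = _grid_from_img(canonical)
    if data.size and np.all(np.isin(np.unique(data), (0.0, 1.0))):
        return BrainMask(grid=grid, data=data.astype(bool))
    return ScalarVolume(grid=grid, data=data, kind="z")


def write_volume(vol: ScalarVolume | BrainMask, path) -> None:
    """Write a volume or mask as NIfTI-1; non-finite values are stored as 0."""
    if isinstance(vol, BrainMask):
        data = vol.data.astype(np.uint8)
    else:
        data = np.nan_to_num(vol.data, nan=0.0, posinf=0.0, neginf=0.0)
    img = nib.Nifti1Image(data, np.asarray(vol.grid.affine))
    nib.save(img, str(path))


def read_timeseries_4d(path) -> tuple[VolumeGrid, np.ndarray]:
    """Read a 4D NIfTI as (grid, data[x, y, z, t]) in canonical RAS+."""
    img = nib.load(str(path))
    if img.ndim != 4:
        raise VolumeDimensionError(f"{path}: expected a 4D time-series, got {img.ndim}D")
    canonical = nib.as_closest_canonical(img)
    return _grid_from_img(canonical), np.asarray(canonical.get_fdata(), dtype=float)


def write_timeseries_4d(grid: VolumeGrid, data: np.ndarray, path) -> None:
    if data.ndim != 4 or data.shape[:3] != grid.shape:
        raise ValueError("data must be 4D on the given grid")
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), np.asarray(grid.affine)), str(path))
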