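"""Volume data model and geometric primitives.

Every map in an analysis lives on a single shared :class:`VolumeGrid` (a voxel
lattice plus a 4x4 voxel-index -> millimetre affine, MNI-style).  Mixing grids
is an error raised before any computation; there is no implicit resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "GridMismatchError",
    "OutOfBoundsError",
    "VolumeGrid",
    "ScalarVolume",
    "MaskVolume",
    "mm_to_voxel",
    "voxel_to_mm",
    "sphere_mask",
    "read_volume",
    "write_volume",
]


class GridMismatchError(ValueError):
    """Two volumes with non-identical grids entered one computation."""


class OutOfBoundsError(ValueError):
    """A millimetre coordinate maps outside the voxel lattice."""


@dataclass(frozen=True)
class VolumeGrid:
    """A 3-D voxel lattice with a voxel-index -> mm affine.

    Parameters
    ----------
    dims : tuple of 3 int
        Voxels per axis.
    affine : (4, 4) ndarray
        Invertible voxel-index -> millimetre transform.  Voxel indices are
        0-based; index ``(i, j, k)`` maps to the *centre* of that voxel.
    """

    dims: tuple[int, int, int]
    affine: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        dims = tuple(int(d) for d in self.dims)
        if len(dims) != 3 or any(d <= 0 for d in dims):
            raise ValueError(f"dims must be 3 positive integers, got {self.dims}")
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        object.__setattr__(self, "dims", dims)
        object.__setattr__(self, "affine", aff)
        aff.setflags(write=False)

    @property
    def voxel_size(self) -> np.ndarray:
        """mm per axis (column norms of the affine's linear part)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VolumeGrid):
            return NotImplemented
        return self.dims == other.dims and np.array_equal(self.affine, other.affine)

    def __hash__(self) -> int:
        return hash((self.dims, self.affine.tobytes()))

    def check_same(self, other: "VolumeGrid", what: str = "volume") -> None:
        if self != other:
            raise GridMismatchError(
                f"{what}: grids differ (dims {self.dims} vs {other.dims} "
                "or non-identical affines); resample upstream, the analysis "
                "requires one common grid"
            )

    def voxel_centers_mm(self) -> np.ndarray:
        """(nx, ny, nz, 3) array of voxel-centre mm coordinates."""
        idx = np.indices(self.dims).reshape(3, -1)
        mm = self.affine[:3, :3] @ idx + self.affine[:3, 3:4]
        return mm.T.reshape(*self.dims, 3)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, halves away from zero."""
    return np.trunc(x + np.copysign(0.5, x))


def voxel_to_mm(index, grid: VolumeGrid) -> np.ndarray:
    """Millimetre coordinate of a voxel centre."""
    idx = np.asarray(index, dtype=float)
    return grid.affine[:3, :3] @ idx + grid.affine[:3, 3]


def mm_to_voxel(xyz_mm, grid: VolumeGrid) -> tuple[int, int, int]:
    """Nearest voxel index (0-based) for a mm coordinate.

    Rounds half away from zero.  Raises :class:`OutOfBoundsError` when the
    rounded index falls outside the lattice.
    """
    xyz = np.asarray(xyz_mm, dtype=float)
    cont = np.linalg.solve(grid.affine[:3, :3], xyz - grid.affine[:3, 3])
    idx = _round_half_away(cont).astype(int)
    if np.any(idx < 0) or np.any(idx >= np.asarray(grid.dims)):
        raise OutOfBoundsError(
            f"coordinate {tuple(xyz)} mm -> voxel {tuple(idx)} is outside "
            f"grid dims {grid.dims}"
        )
    return tuple(int(i) for i in idx)


@dataclass
class ScalarVolume:
    """A real-valued map on a :class:`VolumeGrid` (t-maps, frequency maps...)."""

    grid: VolumeGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != self.grid.dims:
            raise ValueError(
                f"values shape {vals.shape} does not match grid dims {self.grid.dims}"
            )
        if not np.all(np.isfinite(vals)):
            raise ValueError("ScalarVolume requires finite values (no NaN/inf)")
        self.values = vals


@dataclass
class MaskVolume:
    """A strictly binary {0,1} map on a :class:`VolumeGrid`."""

    grid: VolumeGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.shape != self.grid.dims:
            raise ValueError(
                f"mask shape {vals.shape} does not match grid dims {self.grid.dims}"
            )
        uniq = np.unique(vals)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"mask must be binary, found values {uniq[:10]}")
        self.values = vals.astype(bool)

    @property
    def n_true(self) -> int:
        return int(self.values.sum())

    def indices(self) -> np.ndarray:
        """(n, 3) voxel indices of the set voxels."""
        return np.argwhere(self.values)


def sphere_mask(center_mm, radius_mm: float, grid: VolumeGrid) -> MaskVolume:
    """Voxels whose centre lies within ``radius_mm`` of ``center_mm``.

    Radius 0 yields exactly the voxel containing the centre.  The centre must
    map inside the grid.
    """
    if radius_mm < 0:
        raise ValueError("radius_mm must be >= 0")
    center = np.asarray(center_mm, dtype=float)
    c_idx = mm_to_voxel(center, grid)  # validates the centre is in bounds
    mask = np.zeros(grid.dims, dtype=bool)
    if radius_mm == 0:
        mask[c_idx] = True
        return MaskVolume(grid, mask)
    # bounding box in index space: radius scaled through the inverse affine
    inv = np.linalg.inv(grid.affine[:3, :3])
    reach = np.ceil(radius_mm * np.linalg.norm(inv, axis=1)).astype(int) + 1
    lo = np.maximum(np.asarray(c_idx) - reach, 0)
    hi = np.minimum(np.asarray(c_idx) + reach + 1, grid.dims)
    ii, jj, kk = np.mgrid[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3).T
    mm = grid.affine[:3, :3] @ idx.astype(float) + grid.affine[:3, 3:4]
    dist = np.linalg.norm(mm - center[:, None], axis=0)
    inside = (dist <= radius_mm).reshape(ii.shape)
    mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = inside
    if not mask.any():  # pragma: no cover - precondition guarantees non-empty
        raise ValueError("sphere mask is empty")
    return MaskVolume(grid, mask)


def read_volume(path, grid: VolumeGrid | None = None):
    """Read a NIfTI volume; returns (values, VolumeGrid).

    When ``grid`` is given, the file's grid must match it bitwise.
    """
    img = nib.load(str(path))
    vals = np.asanyarray(img.dataobj, dtype=float)
    file_grid = VolumeGrid(vals.shape[:3], img.affine)
    if grid is not None:
        grid.check_same(file_grid, what=str(path))
    return vals, file_grid


def write_volume(path, values: np.ndarray, grid: VolumeGrid) -> None:
    """Write a NIfTI-1 volume with the grid's affine."""
    vals = np.asarray(values)
    if vals.shape[:3] != grid.dims:
        raise ValueError("values do not match grid dims")
    img = nib.Nifti1Image(vals.astype(np.float64), grid.affine)
    nib.save(img, str(path))
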