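"""Voxel grids and 4D BOLD containers.

A :class:`GridSpec` couples a 3D voxel array shape with an affine mapping
0-based voxel indices to RAS mm coordinates (MNI-style), plus the repetition
time.  :class:`Bold4D` is the unit of first-level analysis: one run (or a
concatenation of runs) of BOLD-like data on such a grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridSpec", "Bold4D", "default_mni_grid"]


@dataclass(frozen=True)
class GridSpec:
    """Shape + affine + TR of a simulation/analysis grid.

    The affine maps homogeneous voxel indices (i, j, k, 1) to mm (x, y, z, 1),
    NIfTI RAS convention.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray = field(repr=False)
    tr: float = 2.0

    def __post_init__(self) -> None:
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        object.__setattr__(self, "affine", aff)
        if len(self.shape) != 3 or any(int(s) <= 0 for s in self.shape):
            raise ValueError(f"shape must be three positive ints, got {self.shape}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_size(self) -> np.ndarray:
        """Edge length (mm) along each axis."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def voxel_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        """Map 0-based voxel indices (..., 3) to mm coordinates (..., 3)."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def mm_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`voxel_to_mm` (continuous indices)."""
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def contains_mm(self, xyz) -> bool:
        """True when the mm point maps into the voxel index ranges."""
        ijk = self.mm_to_voxel(np.asarray(xyz, dtype=float))
        return bool(np.all(ijk > -0.5) and np.all(ijk < np.array(self.shape) - 0.5))

    def voxel_centers_mm(self) -> np.ndarray:
        """(nx, ny, nz, 3) array of voxel-center mm coordinates."""
        grid = np.stack(
            np.meshgrid(*[np.arange(s) for s in self.shape], indexing="ij"), axis=-1
        )
        return self.voxel_to_mm(grid)


def default_mni_grid(tr: float = 2.0) -> GridSpec:
    """30 x 36 x 30 grid of 3-mm voxels centred so the seed atlas fits.

    The affine places voxel (0,0,0) at (-42, -36, -30) mm so x spans
    [-42, 45], y spans [-36, 69], z spans [-30, 57]: every default seed
    centre lies strictly inside.
    """
    affine = np.diag([3.0, 3.0, 3.0, 1.0])
    affine[:3, 3] = (-42.0, -36.0, -30.0)
    return GridSpec(shape=(30, 36, 30), affine=affine, tr=tr)


@dataclass
class Bold4D:
    """A 4D (x, y, z, t) BOLD-like volume on a :class:`GridSpec`."""

    data: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError("Bold4D data must be 4-dimensional (x, y, z, t)")
        if self.data.shape[:3] != self.grid.shape:
            raise ValueError(
                f"data spatial shape {self.data.shape[:3]} != grid shape {self.grid.shape}"
            )

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    def timeseries_matrix(self) -> np.ndarray:
        """(t, n_voxels) view of the data, voxels in C order."""
        return self.data.reshape(-1, self.n_volumes).T

    @classmethod
    def from_timeseries_matrix(cls, mat: np.ndarray, grid: GridSpec) -> "Bold4D":
        mat = np.asarray(mat, dtype=np.float64)
        data = mat.T.reshape(grid.shape + (mat.shape[0],))
        return cls(data=data, grid=grid)

    def concat(self, *others: "Bold4D") -> "Bold4D":
        for o in others:
            if o.grid.shape != self.grid.shape:
                raise ValueError("cannot concatenate runs on different grids")
        data = np.concatenate([self.data] + [o.data for o in others], axis=3)
        return Bold4D(data=data, grid=self.grid)
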