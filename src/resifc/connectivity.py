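"""Seed definition and per-run Fisher-z connectivity maps.

Each seed is a 4-mm sphere around an MNI-mm centre; the default atlas holds
the five fatigue-network seeds (DLPFC, vmPFC, dACC, insula, striatum).  The
seed's mean percent-signal-change residual series is correlated with every
voxel's residual series and the map is variance-stabilized with Fisher's
r-to-z transform.  Correlation is computed per run so that run can enter
the group model as a factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .glm import residual_percent_signal_change
from .grids import Bold4D, GridSpec

__all__ = [
    "SeedSpec",
    "SEED_ATLAS",
    "voxelize_seed",
    "seed_series",
    "connectivity_zmap",
    "ConnectivityMap",
]

DEFAULT_SEED_RADIUS_MM = 4.0

#: centre mm coordinates of the five fatigue-network seeds
SEED_COORDINATES_MM = {
    "DLPFC": (44.0, 32.0, 36.0),
    "vmPFC": (-6.0, 46.0, -6.0),
    "dACC": (-4.0, 20.0, 46.0),
    "Insula": (34.0, 22.0, 0.0),
    "Striatum": (18.0, 12.0, 0.0),
}

R_CLAMP = 1.0 - 1e-7


@dataclass(frozen=True)
class SeedSpec:
    name: str
    center_mm: tuple[float, float, float]
    radius_mm: float = DEFAULT_SEED_RADIUS_MM


SEED_ATLAS = tuple(SeedSpec(name, xyz) for name, xyz in SEED_COORDINATES_MM.items())


def voxelize_seed(seed: SeedSpec, grid_spec: GridSpec) -> np.ndarray:
    """(k, 3) voxel indices whose centres lie within the seed radius.

    Inclusion rule: Euclidean distance from voxel centre to seed centre
    (in mm, through the affine) <= radius.
    """
    center = np.asarray(seed.center_mm, dtype=float)
    if not grid_spec.contains_mm(center):
        raise ValueError(f"seed {seed.name!r} centre {tuple(center)} lies outside the grid")
    # search a bounding box around the centre rather than the whole grid
    ijk_c = grid_spec.mm_to_voxel(center)
    margin = seed.radius_mm / grid_spec.voxel_size + 1.0
    lo = np.maximum(np.floor(ijk_c - margin).astype(int), 0)
    hi = np.minimum(np.ceil(ijk_c + margin).astype(int) + 1, grid_spec.shape)
    axes = [np.arange(lo[d], hi[d]) for d in range(3)]
    box = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    d = np.linalg.norm(grid_spec.voxel_to_mm(box) - center, axis=1)
    voxels = box[d <= seed.radius_mm + 1e-9]
    if len(voxels) == 0:
        raise ValueError(f"seed {seed.name!r} captures no voxel centres at radius {seed.radius_mm} mm")
    return voxels


def seed_series(residuals: Bold4D, seed_voxels: np.ndarray, raw_bold: Bold4D) -> np.ndarray:
    """Mean residual PSC series over the seed voxels, one value per volume.

    Each voxel's residual series is first expressed as percent of that
    voxel's raw run mean, then the PSC series are averaged over the seed.
    """
    seed_voxels = np.asarray(seed_voxels, dtype=int)
    if seed_voxels.ndim != 2 or seed_voxels.shape[1] != 3:
        raise ValueError("seed_voxels must be a (k, 3) index array")
    if len(seed_voxels) == 0:
        raise ValueError("seed contains no voxels")
    i, j, k = seed_voxels.T
    resid = residuals.data[i, j, k]  # (k, t)
    raw_mean = raw_bold.data[i, j, k].mean(axis=1)
    return residual_percent_signal_change(resid, raw_mean).mean(axis=0)


@dataclass
class ConnectivityMap:
    subject_id: str
    condition: str
    run_index: int
    seed_name: str
    zmap: np.ndarray = field(repr=False)  # grid-shaped Fisher-z values
    grid: GridSpec = field(repr=False, default=None)


def connectivity_zmap(
    seed_ts: np.ndarray,
    residuals: Bold4D,
    *,
    subject_id: str = "",
    condition: str = "",
    run_index: int = 0,
    seed_name: str = "",
) -> ConnectivityMap:
    """Pearson r of the seed series with every voxel, Fisher transformed.

    r is clamped to +/-(1 - 1e-7) before z = atanh(r).  Voxels with zero
    temporal variance get z = 0 with a warning.
    """
    seed_ts = np.asarray(seed_ts, dtype=float)
    if seed_ts.ndim != 1 or len(seed_ts) != residuals.n_volumes:
        raise ValueError("seed series length must equal the number of volumes")
    s = seed_ts - seed_ts.mean()
    s_norm = np.linalg.norm(s)
    if s_norm == 0:
        raise ValueError("seed series has zero variance; correlation undefined")
    Y = residuals.timeseries_matrix()  # (t, v)
    Yc = Y - Y.mean(axis=0)
    norms = np.linalg.norm(Yc, axis=0)
    # relative tolerance: constant series leave rounding residue after demeaning
    flat = norms <= 1e-10 * (np.abs(Y).max(axis=0) + 1e-30)
    if flat.any():
        warnings.warn(f"{int(flat.sum())} zero-variance voxels set to z = 0", stacklevel=2)
    r = np.zeros(Y.shape[1])
    ok = ~flat
    r[ok] = (s @ Yc[:, ok]) / (s_norm * norms[ok])
    z = np.arctanh(np.clip(r, -R_CLAMP, R_CLAMP))
    z[flat] = 0.0
    return ConnectivityMap(
        subject_id=subject_id,
        condition=condition,
        run_index=run_index,
        seed_name=seed_name,
        zmap=z.reshape(residuals.grid.shape),
        grid=residuals.grid,
    )
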