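"""Per-volume nuisance regressors and motion quality metrics.

Implements the Power-style framewise displacement, standardized DVARS,
tissue mean signals, and the derivative/quadratic confound expansion used
by the first-level deconvolution.  Column names follow the fMRIPrep
convention (``trans_x`` ... ``rot_z``, ``*_derivative1``, ``*_power2``,
``framewise_displacement``, ``std_dvars``, ``csf``/``white_matter``/
``global_signal``, ``motion_outlier``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grids import Bold4D

__all__ = [
    "MOTION_COLUMNS",
    "framewise_displacement",
    "standardized_dvars",
    "tissue_mean_signals",
    "expand_confounds",
    "motion_regressor_columns",
    "tissue_regressor_columns",
]

MOTION_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")
TISSUE_COLUMNS = ("csf", "white_matter", "global_signal")

#: outlier rule thresholds: FD in mm, DVARS in standardized units
FD_THRESHOLD_MM = 0.5
DVARS_THRESHOLD = 1.5

DEFAULT_HEAD_RADIUS_MM = 50.0


def _as_motion_array(motion) -> np.ndarray:
    if isinstance(motion, pd.DataFrame):
        motion = motion[list(MOTION_COLUMNS)].to_numpy()
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion parameters must be (n_volumes, 6): 3 translations mm + 3 rotations rad")
    if motion.shape[0] < 1:
        raise ValueError("motion parameters must contain at least one volume")
    return motion


def framewise_displacement(motion, head_radius: float = DEFAULT_HEAD_RADIUS_MM) -> np.ndarray:
    """Framewise displacement per volume (mm).

    FD(t) = sum |d translation_i| + head_radius * sum |d rotation_i|, with
    rotations converted to arc length on a sphere of ``head_radius`` mm.
    FD(0) = 0 by convention.
    """
    motion = _as_motion_array(motion)
    diffs = np.abs(np.diff(motion, axis=0))
    fd = diffs[:, :3].sum(axis=1) + head_radius * diffs[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def standardized_dvars(bold: Bold4D, brain_mask, *, standardize: str = "median") -> np.ndarray:
    """Standardized DVARS: RMS of the temporally differenced signal over a mask.

    Raw DVARS(t) is the spatial root mean square of signal(t) - signal(t-1)
    within ``brain_mask``; the series is standardized by dividing by its
    within-run median (or mean, ``standardize="mean"``).  DVARS(0) = 0.
    """
    mask = np.asarray(brain_mask, dtype=bool)
    if mask.shape != bold.grid.shape:
        raise ValueError("mask shape does not match the grid")
    if not mask.any():
        raise ValueError("brain mask is empty")
    ts = bold.data[mask]  # (n_mask, t)
    raw = np.sqrt(np.mean(np.diff(ts, axis=1) ** 2, axis=0))
    raw = np.concatenate([[0.0], raw])
    if standardize == "median":
        scale = np.median(raw[1:]) if raw.size > 1 else 0.0
    elif standardize == "mean":
        scale = raw[1:].mean() if raw.size > 1 else 0.0
    else:
        raise ValueError(f"unknown standardization {standardize!r}")
    if scale <= 0:
        return np.zeros_like(raw)
    return raw / scale


def tissue_mean_signals(bold: Bold4D, csf_mask, wm_mask, whole_mask) -> pd.DataFrame:
    """Unweighted per-volume mean signal within CSF, WM and whole-brain masks."""
    out = {}
    for name, mask in zip(TISSUE_COLUMNS, (csf_mask, wm_mask, whole_mask)):
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != bold.grid.shape:
            raise ValueError(f"{name} mask shape does not match the grid")
        if not mask.any():
            raise ValueError(f"{name} mask is empty")
        out[name] = bold.data[mask].mean(axis=0)
    return pd.DataFrame(out)


def _derivative(series: np.ndarray) -> np.ndarray:
    """Backward temporal difference with the first row set to 0."""
    d = np.diff(series, axis=0)
    return np.concatenate([np.zeros((1,) + d.shape[1:]), d], axis=0)


def expand_confounds(motion, fd: np.ndarray, dvars: np.ndarray, tissue_signals: pd.DataFrame) -> pd.DataFrame:
    """Assemble the full per-volume confounds table.

    Motion block: 6 parameters + temporal derivatives + quadratics of both
    (24 columns).  Tissue block: CSF/WM/global means + derivatives.  Plus
    FD, standardized DVARS, and the boolean ``motion_outlier`` flag
    (FD > 0.5 mm or standardized DVARS > 1.5).
    """
    motion = _as_motion_array(motion)
    fd = np.asarray(fd, dtype=float)
    dvars = np.asarray(dvars, dtype=float)
    n = motion.shape[0]
    if not (len(fd) == len(dvars) == len(tissue_signals) == n):
        raise ValueError(
            "length mismatch: motion %d, fd %d, dvars %d, tissue %d"
            % (n, len(fd), len(dvars), len(tissue_signals))
        )
    cols: dict[str, np.ndarray] = {}
    for i, name in enumerate(MOTION_COLUMNS):
        cols[name] = motion[:, i]
    for name in MOTION_COLUMNS:
        cols[f"{name}_derivative1"] = _derivative(cols[name])
    for name in MOTION_COLUMNS:
        cols[f"{name}_power2"] = cols[name] ** 2
        cols[f"{name}_derivative1_power2"] = cols[f"{name}_derivative1"] ** 2
    for name in TISSUE_COLUMNS:
        sig = np.asarray(tissue_signals[name], dtype=float)
        cols[name] = sig
        cols[f"{name}_derivative1"] = _derivative(sig)
    cols["framewise_displacement"] = fd
    cols["std_dvars"] = dvars
    cols["motion_outlier"] = (fd > FD_THRESHOLD_MM) | (dvars > DVARS_THRESHOLD)
    return pd.DataFrame(cols)


def motion_regressor_columns() -> list[str]:
    """Motion columns entering the deconvolution: 6 params + derivatives."""
    return list(MOTION_COLUMNS) + [f"{c}_derivative1" for c in MOTION_COLUMNS]


def tissue_regressor_columns() -> list[str]:
    """Tissue/global columns entering the deconvolution: means + derivatives."""
    return [c for name in TISSUE_COLUMNS for c in (name, f"{name}_derivative1")]
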