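"""First-level deconvolution of the four runs of one n-back condition.

The design models only *stable* task activation: a single task regressor
with unit amplitude for every trial, built from the trial onsets convolved
with a canonical double-gamma HRF.  Signal drift (per-run Legendre
polynomials), the motion parameters and their derivatives, framewise
displacement, and the CSF/WM/global signals with their derivatives enter as
run-blocked regressors of no interest.  Any time-varying (fatigue-related)
activation is deliberately left in the error term; the residual series is
the substrate of all downstream connectivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial import legendre
from scipy.stats import gamma as gamma_dist

from . import confounds as cf
from .grids import Bold4D

__all__ = [
    "HRFSpec",
    "canonical_hrf",
    "DesignMatrix",
    "build_design",
    "fit_glm",
    "percent_signal_change",
    "residual_percent_signal_change",
    "GLMResult",
]


@dataclass(frozen=True)
class HRFSpec:
    """Double-gamma hemodynamic response (SPM-style canonical shape).

    ``response = pdf(Gamma(peak_delay/disp, disp)) - pdf(undershoot)/ratio``,
    zero at t = 0 and integrating to a finite value.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 6.0
    amplitude: float = 1.0
    oversampling: int = 16  # sub-TR sampling used when convolving events
    duration: float = 32.0  # support of the kernel in seconds


def canonical_hrf(t, spec: HRFSpec | None = None) -> np.ndarray:
    """Evaluate the double-gamma HRF at times ``t`` (seconds, >= 0)."""
    spec = spec or HRFSpec()
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("HRF is defined for t >= 0 only")
    peak = gamma_dist.pdf(t, spec.peak_delay / spec.peak_dispersion, scale=spec.peak_dispersion)
    under = gamma_dist.pdf(
        t, spec.undershoot_delay / spec.undershoot_dispersion, scale=spec.undershoot_dispersion
    )
    return spec.amplitude * (peak - under / spec.undershoot_ratio)


def hrf_convolve_events(onsets, durations, n_volumes: int, tr: float, spec: HRFSpec | None = None) -> np.ndarray:
    """Unit-amplitude event regressor sampled at volume times.

    Every trial contributes a boxcar of its duration with height 1 (no
    per-trial modulation), convolved with the canonical HRF on an
    oversampled time grid and decimated to the TR grid.
    """
    spec = spec or HRFSpec()
    onsets = np.asarray(onsets, dtype=float)
    durations = np.broadcast_to(np.asarray(durations, dtype=float), onsets.shape)
    dt = tr / spec.oversampling
    n_fine = int(np.ceil(n_volumes * tr / dt)) + 1
    fine = np.zeros(n_fine)
    for onset, dur in zip(onsets, durations):
        i0 = int(np.round(onset / dt))
        i1 = int(np.round((onset + dur) / dt))
        fine[i0 : max(i1, i0 + 1)] = 1.0
    kernel = canonical_hrf(np.arange(0, spec.duration, dt), spec) * dt
    conv = np.convolve(fine, kernel)[:n_fine]
    sample_idx = np.round(np.arange(n_volumes) * tr / dt).astype(int)
    return conv[sample_idx]


@dataclass
class DesignMatrix:
    """Labeled concatenated design with run bookkeeping."""

    frame: pd.DataFrame = field(repr=False)
    run_slices: list[slice]
    task_column: str = "task"

    @property
    def matrix(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def _legendre_drift(n: int, order: int) -> np.ndarray:
    """Columns P_0..P_order evaluated on [-1, 1] over n time points."""
    x = np.linspace(-1.0, 1.0, n)
    cols = [legendre.legval(x, [0] * k + [1]) for k in range(order + 1)]
    return np.column_stack(cols)


def build_design(
    schedules,
    confound_tables,
    drift_order: int = 3,
    hrf: HRFSpec | None = None,
    n_volumes: int = 140,
    tr: float = 2.0,
    include_spike_regressors: bool = False,
) -> DesignMatrix:
    """Concatenated design over the four runs of one condition.

    One unit-amplitude task regressor spans all runs; drift (Legendre
    polynomials up to ``drift_order``, including the per-run intercept) and
    nuisance regressors are run-blocked: zero outside their own run.
    """
    if len(schedules) != len(confound_tables):
        raise ValueError("need one confounds table per schedule")
    conditions = {s.condition for s in schedules}
    if len(conditions) != 1:
        raise ValueError(f"schedules mix conditions {sorted(conditions)}; model one condition at a time")
    n_runs = len(schedules)
    total = n_runs * n_volumes
    pieces: dict[str, np.ndarray] = {}

    task = np.zeros(total)
    for r, sched in enumerate(schedules):
        task[r * n_volumes : (r + 1) * n_volumes] = hrf_convolve_events(
            sched.onsets, sched.durations, n_volumes, tr, hrf
        )
    pieces["task"] = task

    nuisance_cols = (
        cf.motion_regressor_columns() + ["framewise_displacement"] + cf.tissue_regressor_columns()
    )
    for r, table in enumerate(confound_tables):
        if len(table) != n_volumes:
            raise ValueError(f"confounds for run {r + 1} have {len(table)} rows, expected {n_volumes}")
        block = slice(r * n_volumes, (r + 1) * n_volumes)
        drift = _legendre_drift(n_volumes, drift_order)
        for k in range(drift_order + 1):
            name = f"run{r + 1}_intercept" if k == 0 else f"run{r + 1}_drift{k}"
            col = np.zeros(total)
            col[block] = drift[:, k]
            pieces[name] = col
        for cname in nuisance_cols:
            col = np.zeros(total)
            values = np.asarray(table[cname], dtype=float)
            # demean within run so nuisance columns do not alias the intercept
            col[block] = values - values.mean()
            if np.allclose(col, 0.0):
                continue  # constant-in-run regressor carries no information
            pieces[f"run{r + 1}_{cname}"] = col
        if include_spike_regressors and "motion_outlier" in table:
            flags = np.flatnonzero(np.asarray(table["motion_outlier"], dtype=bool))
            for t_idx in flags:
                col = np.zeros(total)
                col[r * n_volumes + t_idx] = 1.0
                pieces[f"run{r + 1}_spike{t_idx}"] = col

    frame = pd.DataFrame(pieces)
    if (frame.to_numpy() == 0).all(axis=0).any():
        raise ValueError("design contains an all-zero column")
    frame = _prune_collinear(frame)
    run_slices = [slice(r * n_volumes, (r + 1) * n_volumes) for r in range(n_runs)]
    return DesignMatrix(frame=frame, run_slices=run_slices)


def _prune_collinear(frame: pd.DataFrame, rtol: float = 1e-8) -> pd.DataFrame:
    """Greedily drop nuisance columns already spanned by earlier columns.

    Degenerate (e.g. noiseless synthetic) runs can make a tissue regressor an
    exact copy of the task regressor; dropping the redundant later column
    keeps the model estimable without touching the columns of interest.
    """
    X = frame.to_numpy(dtype=float)
    n = X.shape[0]
    Q = np.empty((n, 0))
    keep: list[int] = []
    dropped: list[str] = []
    for j in range(X.shape[1]):
        col = X[:, j]
        resid = col - Q @ (Q.T @ col)
        if np.linalg.norm(resid) <= rtol * max(np.linalg.norm(col), 1.0):
            dropped.append(frame.columns[j])
            continue
        Q = np.column_stack([Q, resid / np.linalg.norm(resid)])
        keep.append(j)
    if dropped:
        warnings.warn(f"dropped collinear design columns: {dropped}", stacklevel=3)
    return frame.iloc[:, keep]


@dataclass
class GLMResult:
    beta: np.ndarray  # (p, n_voxels)
    residuals: Bold4D
    design: DesignMatrix

    def beta_map(self, column: str) -> np.ndarray:
        i = self.design.columns.index(column)
        return self.beta[i].reshape(self.residuals.grid.shape)


RANK_RTOL = 1e-10


def fit_glm(bold_concat: Bold4D, design: DesignMatrix) -> GLMResult:
    """Ordinary least squares per voxel; residual = data - design @ beta.

    Raises on a rank-deficient design, naming the collinear columns.
    """
    X = design.matrix
    if X.shape[0] != bold_concat.n_volumes:
        raise ValueError(f"design has {X.shape[0]} rows but data has {bold_concat.n_volumes} volumes")
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    tol = s[0] * RANK_RTOL
    if np.any(s < tol):
        null_mask = s < tol
        weights = np.abs(vt[null_mask]).sum(axis=0)
        involved = [design.columns[i] for i in np.flatnonzero(weights > 1e-8 * weights.max())]
        raise np.linalg.LinAlgError(f"rank-deficient design; collinear columns: {involved}")
    Y = bold_concat.timeseries_matrix()  # (t, v)
    beta = vt.T @ ((u.T @ Y) / s[:, None])
    resid = Y - X @ beta
    return GLMResult(
        beta=beta,
        residuals=Bold4D.from_timeseries_matrix(resid, bold_concat.grid),
        design=design,
    )


def percent_signal_change(series: np.ndarray, reference_mean: float | np.ndarray | None = None) -> np.ndarray:
    """100 * (x - mean) / mean with the mean over the raw series by default."""
    series = np.asarray(series, dtype=float)
    ref = np.asarray(series.mean(axis=-1) if reference_mean is None else reference_mean, dtype=float)
    if np.any(ref <= 0):
        raise ValueError("PSC reference mean must be positive")
    return 100.0 * (series - ref[..., None]) / ref[..., None]


def residual_percent_signal_change(residual_series: np.ndarray, raw_mean: float | np.ndarray) -> np.ndarray:
    """Residuals expressed as percent of the raw per-voxel run mean.

    Residuals are already deviations (mean ~ 0 by construction), so the PSC
    convention reduces to scaling by 100 / raw mean.
    """
    raw_mean = np.asarray(raw_mean, dtype=float)
    if np.any(raw_mean <= 0):
        raise ValueError("PSC reference mean must be positive")
    return 100.0 * np.asarray(residual_series, dtype=float) / raw_mean[..., None]
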