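"""Synthetic cohorts, task schedules, fatigue ratings, behavior and BOLD runs.

The generator emulates the study design this package analyzes: two groups
(MS n=26, HC n=14), an n-back task with two conditions (0-back, 2-back),
four runs per condition of 260 s each (65 trials of 1.5 s + 0.5 s base ITI,
six jittered null events), 140 volumes at TR = 2 s per run, and five VAS-F
fatigue ratings per subject x condition (one before the first run, one
after each run).

The fMRI signal is built so the downstream pipeline has a known truth to
recover: task activation is *invariant* across trials (unit amplitude), so
the first-level deconvolution absorbs it completely, while a latent
fluctuation shared between a seed and a target region is injected with a
mixing weight that depends on condition and the run's fatigue level.  That
fatigue-modulated coupling lives only in the GLM error term - exactly the
signal residual functional connectivity is designed to measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from . import confounds as cf
from .grids import Bold4D, GridSpec, default_mni_grid

__all__ = [
    "Subject",
    "CohortSpec",
    "TrialSchedule",
    "VasfEffectParams",
    "BehavioralParams",
    "PlantSpec",
    "generate_cohort",
    "generate_task_schedule",
    "generate_vasf",
    "generate_behavior",
    "simulate_bold",
    "default_tissue_masks",
]

GROUPS = ("MS", "HC")
CONDITIONS = ("0-back", "2-back")
N_RUNS = 4
N_TRIALS = 65
TRIAL_STIM_S = 1.5
TRIAL_ITI_S = 0.5
TRIAL_LEN_S = TRIAL_STIM_S + TRIAL_ITI_S  # 2 s slot per trial
RUN_LENGTH_S = 260.0
N_NULL_EVENTS = 6
N_VOLUMES = 140
TR_S = 2.0
N_RATINGS = 5

#: the 17 high-discriminability letters used as stimuli
LETTERS = tuple("ABCDFHJKMNPQRSTVZ")


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Subject:
    subject_id: str
    group: str
    subject_intercept: float


@dataclass(frozen=True)
class CohortSpec:
    subjects: tuple[Subject, ...]

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("subject_ids must be unique")
        for s in self.subjects:
            if s.group not in GROUPS:
                raise ValueError(f"unknown group {s.group!r}")

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in self.subjects],
                "group": [s.group for s in self.subjects],
                "subject_intercept": [s.subject_intercept for s in self.subjects],
            }
        )

    def by_group(self, group: str) -> list[Subject]:
        return [s for s in self.subjects if s.group == group]


def generate_cohort(
    n_ms: int = 26, n_hc: int = 14, between_subject_sd: float = 0.5, rng_seed: int = 0
) -> CohortSpec:
    """Draw a cohort with Gaussian per-subject intercepts (latent fatigue scale)."""
    if n_ms < 0 or n_hc < 0:
        raise ValueError("group counts must be non-negative")
    rng = np.random.default_rng(rng_seed)
    subjects = []
    for group, n in (("MS", n_ms), ("HC", n_hc)):
        intercepts = rng.normal(0.0, between_subject_sd, size=n)
        for i in range(n):
            subjects.append(Subject(f"{group.lower()}{i + 1:03d}", group, float(intercepts[i])))
    return CohortSpec(subjects=tuple(subjects))


# ---------------------------------------------------------------------------
# task schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrialSchedule:
    condition: str
    run_index: int
    onsets: np.ndarray = field(repr=False)
    durations: np.ndarray = field(repr=False)
    target_flags: np.ndarray = field(repr=False)
    letters: tuple[str, ...] = field(repr=False)
    run_length: float = RUN_LENGTH_S

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets, dtype=float)
        durations = np.asarray(self.durations, dtype=float)
        if np.any(np.diff(onsets) <= 0) or np.any(onsets < 0):
            raise ValueError("onsets must be sorted and non-negative")
        if np.any(onsets + durations > self.run_length + 1e-9):
            raise ValueError("a trial extends beyond the run")
        object.__setattr__(self, "onsets", onsets)
        object.__setattr__(self, "durations", durations)
        object.__setattr__(self, "target_flags", np.asarray(self.target_flags, dtype=bool))

    @property
    def n_trials(self) -> int:
        return len(self.onsets)

    def events_frame(self) -> pd.DataFrame:
        """BIDS-style events table (onset, duration, trial_type)."""
        return pd.DataFrame(
            {
                "onset": self.onsets,
                "duration": self.durations,
                "trial_type": [
                    f"{self.condition}_{'target' if t else 'nontarget'}" for t in self.target_flags
                ],
                "stimulus": list(self.letters),
            }
        )


def _letter_stream(condition: str, rng: np.random.Generator) -> tuple[tuple[str, ...], np.ndarray]:
    letters = tuple(rng.choice(LETTERS, size=N_TRIALS))
    if condition == "0-back":
        flags = np.array([c == "K" for c in letters])
    else:
        flags = np.array([i >= 2 and letters[i] == letters[i - 2] for i in range(N_TRIALS)])
    return letters, flags


def generate_task_schedule(
    condition: str,
    run_index: int,
    rng_seed: int = 0,
    n_null_events: int = N_NULL_EVENTS,
    run_length: float = RUN_LENGTH_S,
) -> TrialSchedule:
    """One jittered run: 65 trials plus null events closing the 260-s budget.

    Each trial occupies a 2-s slot (1.5 s stimulus + 0.5 s base ITI).  The
    jitter inserts ``n_null_events`` null events between trials; each null
    duration is a multiple of the 2-s trial length and together they close
    the run-length budget exactly.  With ``n_null_events=0`` the budget must
    equal 130 s and onsets are strictly periodic at 2 s.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}, got {condition!r}")
    trial_time = N_TRIALS * TRIAL_LEN_S
    null_budget = run_length - trial_time
    null_slots = int(round(null_budget / TRIAL_LEN_S))
    if abs(null_slots * TRIAL_LEN_S - null_budget) > 1e-9 or null_slots < 0:
        raise ValueError(
            f"run_length {run_length} s leaves a null budget of {null_budget} s, "
            f"not a multiple of the {TRIAL_LEN_S}-s trial length"
        )
    if n_null_events == 0:
        if null_slots != 0:
            raise ValueError("zero null events cannot close a nonzero null budget")
        parts = np.array([], dtype=int)
        gap_positions = np.array([], dtype=int)
    else:
        if null_slots < n_null_events:
            raise ValueError(
                f"null budget of {null_slots} trial slots cannot feed {n_null_events} null events"
            )
        rng = np.random.default_rng(rng_seed)
        # random composition of null_slots into n_null_events positive parts
        cuts = np.sort(rng.choice(np.arange(1, null_slots), size=n_null_events - 1, replace=False))
        parts = np.diff(np.concatenate([[0], cuts, [null_slots]])).astype(int)
        gap_positions = np.sort(
            rng.choice(np.arange(1, N_TRIALS), size=n_null_events, replace=False)
        )
    null_at = dict(zip(gap_positions, parts))
    onsets = np.empty(N_TRIALS)
    t = 0.0
    for i in range(N_TRIALS):
        if i in null_at:
            t += null_at[i] * TRIAL_LEN_S
        onsets[i] = t
        t += TRIAL_LEN_S
    letters, flags = _letter_stream(
        condition, np.random.default_rng(np.random.SeedSequence([rng_seed, run_index, 7]))
    )
    return TrialSchedule(
        condition=condition,
        run_index=run_index,
        onsets=onsets,
        durations=np.full(N_TRIALS, TRIAL_STIM_S),
        target_flags=flags,
        letters=letters,
        run_length=run_length,
    )


# ---------------------------------------------------------------------------
# VAS-F ratings
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VasfEffectParams:
    """Latent-scale effects for the 0-100 VAS-F generator.

    Defaults approximate the study's descriptives: HC median ~12, MS median
    ~38, fatigue accumulating across runs, and a small MS-specific excess in
    the 0-back condition (the direction the behavioral arm reports).
    """

    baseline: float = 12.0
    group_offset: float = 26.0  # added for MS on the latent scale
    condition_offset: float = 0.0  # added for 2-back, both groups
    ms_condition_offset: float = -2.7  # extra 2-back offset, MS only
    rating_trend: float = 2.0  # per rating index (fatigue accumulation)
    intercept_scale: float = 10.0  # VAS-F units per cohort intercept unit
    noise_sd: float = 8.0


def generate_vasf(
    cohort: CohortSpec, effect_params: VasfEffectParams | None = None, rng_seed: int = 0
) -> pd.DataFrame:
    """Five ratings per subject x condition; latent effects applied then clipped to [0, 100]."""
    p = effect_params or VasfEffectParams()
    rng = np.random.default_rng(rng_seed)
    rows = []
    for subj in cohort.subjects:
        for condition in CONDITIONS:
            for k in range(N_RATINGS):
                latent = (
                    p.baseline
                    + p.intercept_scale * subj.subject_intercept
                    + (p.group_offset if subj.group == "MS" else 0.0)
                    + (p.condition_offset if condition == "2-back" else 0.0)
                    + (p.ms_condition_offset if subj.group == "MS" and condition == "2-back" else 0.0)
                    + p.rating_trend * k
                    + (rng.normal(0.0, p.noise_sd) if p.noise_sd > 0 else 0.0)
                )
                rows.append(
                    {
                        "subject_id": subj.subject_id,
                        "group": subj.group,
                        "condition": condition,
                        "rating_index": k,
                        "score": float(np.clip(latent, 0.0, 100.0)),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# behavioral performance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BehavioralParams:
    """Accuracy / response-time generator with fatigue-dependent slopes.

    Slope defaults follow the directions and magnitudes the behavioral arm
    estimates: accuracy rises with fatigue for HC in the 2-back (+0.021 per
    transformed-fatigue unit) and falls for MS (-0.016), with no 0-back
    fatigue dependence; response time is ~148 ms slower in the 2-back.
    """

    accuracy_base: float = 0.97
    accuracy_load_cost: float = -0.09  # 2-back accuracy cost
    accuracy_group_offset: float = -0.02  # MS offset
    accuracy_slopes: dict = field(
        default_factory=lambda: {
            ("HC", "0-back"): 0.0,
            ("HC", "2-back"): 0.021,
            ("MS", "0-back"): 0.0,
            ("MS", "2-back"): -0.016,
        }
    )
    accuracy_noise_sd: float = 0.03
    rt_base_ms: float = 520.0
    rt_load_cost_ms: float = 148.0
    rt_group_offset_ms: float = 30.0
    rt_noise_sd_ms: float = 60.0


def fatigue_covariate(run_mean_scores: np.ndarray) -> np.ndarray:
    """The generator's own transformed-fatigue scale: standardized log1p.

    Downstream analysis estimates its own Box-Cox transform from the data;
    this fixed monotone transform is what planted slopes are expressed
    against, so ground truth does not depend on a fitted quantity.
    """
    return (np.log1p(np.asarray(run_mean_scores, dtype=float)) - np.log1p(30.0)) / 0.8


def run_mean_vasf(vasf: pd.DataFrame) -> pd.DataFrame:
    """Per subject x condition x run mean of the pre/post ratings (run k: ratings k-1, k)."""
    rows = []
    for (sid, grp, cond), sub in vasf.groupby(["subject_id", "group", "condition"], sort=True):
        scores = sub.sort_values("rating_index")["score"].to_numpy()
        for r in range(1, N_RUNS + 1):
            rows.append(
                {
                    "subject_id": sid,
                    "group": grp,
                    "condition": cond,
                    "run_index": r,
                    "run_mean": (scores[r - 1] + scores[r]) / 2.0,
                }
            )
    return pd.DataFrame(rows)


def generate_behavior(
    cohort: CohortSpec,
    vasf: pd.DataFrame,
    params: BehavioralParams | None = None,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Accuracy and mean RT per subject x condition x run, tied to fatigue."""
    p = params or BehavioralParams()
    rng = np.random.default_rng(rng_seed)
    runs = run_mean_vasf(vasf)
    runs["fatigue_t"] = fatigue_covariate(runs["run_mean"])
    acc = (
        p.accuracy_base
        + np.where(runs["condition"] == "2-back", p.accuracy_load_cost, 0.0)
        + np.where(runs["group"] == "MS", p.accuracy_group_offset, 0.0)
        + np.array(
            [p.accuracy_slopes[(g, c)] for g, c in zip(runs["group"], runs["condition"])]
        )
        * runs["fatigue_t"].to_numpy()
        + rng.normal(0.0, p.accuracy_noise_sd, size=len(runs))
    )
    rt = (
        p.rt_base_ms
        + np.where(runs["condition"] == "2-back", p.rt_load_cost_ms, 0.0)
        + np.where(runs["group"] == "MS", p.rt_group_offset_ms, 0.0)
        + rng.normal(0.0, p.rt_noise_sd_ms, size=len(runs))
    )
    out = runs.drop(columns=["fatigue_t"])
    out["accuracy"] = np.clip(acc, 0.0, 1.0)
    out["mean_rt"] = np.maximum(rt, 1.0)
    return out


# ---------------------------------------------------------------------------
# BOLD simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantSpec:
    """Ground truth planted into simulated runs.

    ``coupling_*`` set the seed-target correlation of the latent residual
    fluctuation: r = coupling_intercept + coupling_slope(condition) * fatigue,
    with fatigue on the transformed scale of :func:`fatigue_covariate`.
    The generator refuses any configuration where |r| >= 1.
    """

    seed_region: np.ndarray = field(repr=False)  # boolean mask on the grid
    target_region: np.ndarray = field(repr=False)
    coupling_intercept: float = 0.2
    coupling_slope_2back: float = 0.15
    coupling_slope_0back: float = 0.0
    task_amplitude: float = 1.0
    latent_amplitude: float = 1.0
    #: shared physiological fluctuation added to every voxel; this is the
    #: component the global-signal regressor exists to remove, and it keeps
    #: that regressor from acting as a proxy for the planted latents on
    #: desk-scale grids
    global_amplitude: float = 0.5
    noise_sd: float = 1.0
    smoothing_fwhm: float = 6.0  # mm, applied to the noise field
    drift_coeffs: tuple[float, ...] = (0.0, 0.5, 0.3)  # polynomial in scaled run time
    baseline: float = 100.0
    motion_coupling: float = 0.0  # signal units per mm of translation
    motion_step_sd: tuple[float, float] = (0.02, 0.0004)  # mm, rad random-walk steps
    motion_spike_prob: float = 0.02
    motion_spike_size: tuple[float, float] = (0.4, 0.008)

    def coupling(self, condition: str, fatigue: float) -> float:
        slope = self.coupling_slope_2back if condition == "2-back" else self.coupling_slope_0back
        r = self.coupling_intercept + slope * fatigue
        if abs(r) >= 1.0:
            raise ValueError(
                f"planted correlation {r:.3f} not attainable (|r| must be < 1); "
                f"condition={condition}, fatigue={fatigue}"
            )
        return r

    def without_effects(self) -> "PlantSpec":
        """Fully explained-signal variant: no latent, noise or drift."""
        return replace(
            self,
            coupling_intercept=0.0,
            coupling_slope_2back=0.0,
            coupling_slope_0back=0.0,
            latent_amplitude=0.0,
            noise_sd=0.0,
            drift_coeffs=(0.0,),
            motion_coupling=0.0,
        )


def default_tissue_masks(grid: GridSpec) -> dict[str, np.ndarray]:
    """Nominal CSF / WM / whole-brain masks for an anatomy-free grid.

    Small blocks in opposite corners stand in for CSF and WM; the whole
    mask covers the grid.
    """
    nx, ny, nz = grid.shape
    csf = np.zeros(grid.shape, dtype=bool)
    wm = np.zeros(grid.shape, dtype=bool)
    b = max(2, min(nx, ny, nz) // 8)
    csf[:b, :b, :b] = True
    wm[-b:, -b:, -b:] = True
    whole = np.ones(grid.shape, dtype=bool)
    return {"csf": csf, "wm": wm, "whole": whole}


def _smooth_unit_series(rng: np.random.Generator, n: int, sigma_samples: float = 1.5) -> np.ndarray:
    x = gaussian_filter1d(rng.standard_normal(n), sigma_samples)
    sd = x.std()
    return x / sd if sd > 0 else x


def _simulate_motion(rng: np.random.Generator, n: int, plant: PlantSpec) -> np.ndarray:
    t_sd, r_sd = plant.motion_step_sd
    steps = rng.normal(0.0, [t_sd] * 3 + [r_sd] * 3, size=(n, 6))
    spikes = rng.random(n) < plant.motion_spike_prob
    t_sp, r_sp = plant.motion_spike_size
    steps[spikes] += rng.normal(0.0, [t_sp] * 3 + [r_sp] * 3, size=(spikes.sum(), 6))
    motion = np.cumsum(steps, axis=0)
    motion[0] = 0.0
    return motion


def _fwhm_to_sigma_voxels(fwhm_mm: float, voxel_size: np.ndarray) -> np.ndarray:
    return fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size


def simulate_bold(
    subject: Subject,
    schedule: TrialSchedule,
    run_fatigue_value: float,
    plant: PlantSpec,
    grid_spec: GridSpec | None = None,
    rng_seed: int = 0,
    tissue_masks: dict[str, np.ndarray] | None = None,
    n_volumes: int = N_VOLUMES,
) -> tuple[Bold4D, pd.DataFrame]:
    """One 140-volume run with planted, fatigue-modulated residual coupling.

    The scanner acquires ``n_volumes`` images at the grid's TR (140 x 2 s by
    default), slightly outlasting the 260-s task timeline.

    signal = baseline + invariant task activation (unit-amplitude trials
    convolved with the canonical HRF) + per-run polynomial drift + optional
    motion-coupled component + latent seed/target fluctuation with mixing
    weight r(condition, fatigue) + spatially smoothed independent noise.
    Returns the run and its confounds table built from the *true* motion.
    """
    from .glm import hrf_convolve_events  # local import to avoid a cycle

    grid = grid_spec or default_mni_grid()
    for name, region in (("seed", plant.seed_region), ("target", plant.target_region)):
        region = np.asarray(region, dtype=bool)
        if region.shape != grid.shape:
            raise ValueError(f"{name} region shape {region.shape} does not match grid {grid.shape}")
        if not region.any():
            raise ValueError(f"{name} region is empty on this grid")
    r = plant.coupling(schedule.condition, run_fatigue_value)

    rng = np.random.default_rng(rng_seed)
    n_vol = int(n_volumes)
    if n_vol * grid.tr < schedule.run_length:
        raise ValueError(
            f"{n_vol} volumes at TR {grid.tr} s do not cover the {schedule.run_length}-s task"
        )
    t_scaled = np.linspace(-1.0, 1.0, n_vol)

    task = plant.task_amplitude * hrf_convolve_events(
        schedule.onsets, schedule.durations, n_vol, grid.tr
    )
    drift = np.polynomial.polynomial.polyval(t_scaled, np.asarray(plant.drift_coeffs, dtype=float))
    motion = _simulate_motion(rng, n_vol, plant)
    physio = (
        plant.global_amplitude * _smooth_unit_series(rng, n_vol)
        if plant.global_amplitude != 0.0
        else 0.0
    )
    global_ts = (
        plant.baseline + task + drift + physio
        + plant.motion_coupling * motion[:, :3].sum(axis=1)
    )

    data = np.broadcast_to(global_ts, grid.shape + (n_vol,)).copy()

    if plant.latent_amplitude != 0.0:
        latent = _smooth_unit_series(rng, n_vol)
        other = _smooth_unit_series(rng, n_vol)
        seed_ts = plant.latent_amplitude * latent
        target_ts = plant.latent_amplitude * (r * latent + np.sqrt(1.0 - r**2) * other)
        data[np.asarray(plant.seed_region, dtype=bool)] += seed_ts
        data[np.asarray(plant.target_region, dtype=bool)] += target_ts

    if plant.noise_sd > 0:
        noise = rng.standard_normal(grid.shape + (n_vol,))
        if plant.smoothing_fwhm > 0:
            sigma = _fwhm_to_sigma_voxels(plant.smoothing_fwhm, grid.voxel_size)
            noise = gaussian_filter(noise, sigma=tuple(sigma) + (0.0,), mode="nearest")
            noise /= noise.std()  # restore unit variance after smoothing
        data += plant.noise_sd * noise

    bold = Bold4D(data=data, grid=grid)
    masks = tissue_masks or default_tissue_masks(grid)
    fd = cf.framewise_displacement(motion)
    dvars = cf.standardized_dvars(bold, masks["whole"])
    tissues = cf.tissue_mean_signals(bold, masks["csf"], masks["wm"], masks["whole"])
    table = cf.expand_confounds(motion, fd, dvars, tissues)
    return bold, table
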