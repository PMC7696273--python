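"""Self-contained validation studies: FWE calibration and parameter recovery.

These run the package end to end under fixed, desk-scale study designs and
return the quantities that certify the method: the empirical familywise
error of the cluster-extent correction, and recovery of a planted
fatigue-coupling slope through the full simulate -> deconvolve ->
connectivity -> group-model chain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from . import behavior as bh
from . import clusters as cl
from . import connectivity as cn
from . import glm
from . import group as gp
from . import synthetic as syn
from .grids import GridSpec
from .lme import RandomInterceptLME

__all__ = [
    "protocol_constants",
    "fwe_calibration_study",
    "RecoveryReplicate",
    "recovery_study",
    "behavioral_recovery_study",
]


def protocol_constants(rng_seed: int = 0) -> dict:
    """Design constants measured from freshly generated study objects."""
    sched = syn.generate_task_schedule("2-back", 1, rng_seed=rng_seed)
    grid = GridSpec(shape=(8, 8, 8), affine=np.diag([3.0, 3.0, 3.0, 1.0]), tr=syn.TR_S)
    plant = syn.PlantSpec(
        seed_region=np.ones(grid.shape, bool), target_region=np.ones(grid.shape, bool),
        noise_sd=0.1, smoothing_fwhm=0.0,
    )
    subj = syn.Subject("ms001", "MS", 0.0)
    bold, _ = syn.simulate_bold(subj, sched, 0.0, plant, grid, rng_seed=rng_seed)
    cohort = syn.generate_cohort(2, 2, 0.5, rng_seed=rng_seed)
    vasf = syn.generate_vasf(cohort, rng_seed=rng_seed)
    ratings_per_cell = vasf.groupby(["subject_id", "condition"]).size()
    return {
        "trials_per_run": int(sched.n_trials),
        "run_length_s": float(sched.run_length),
        "volumes_per_run": int(bold.n_volumes),
        "tr_s": float(grid.tr),
        "vasf_ratings_per_condition": int(ratings_per_cell.iloc[0])
        if ratings_per_cell.nunique() == 1
        else -1,
    }


def fwe_calibration_study(
    rng_seed: int = 0,
    grid_shape: tuple[int, int, int] = (24, 24, 24),
    voxel_size_mm: float = 3.0,
    fwhm_mm: float = 6.0,
    voxel_p: float = 0.001,
    alpha: float = 0.05,
    n_calibration: int = 1000,
    n_evaluation: int = 1000,
    connectivity: str = "faces",
) -> dict:
    """Calibrate the extent threshold, then measure FWE on independent nulls.

    Returns the threshold k and the fraction of ``n_evaluation`` fresh null
    fields (same smoothness, independent seed stream) containing at least
    one surviving cluster - the empirical familywise error.
    """
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    grid = GridSpec(shape=grid_shape, affine=affine)
    k, null = cl.montecarlo_extent_threshold(
        grid,
        fwhm_mm,
        voxel_p=voxel_p,
        alpha=alpha,
        n_sims=n_calibration,
        connectivity=connectivity,
        rng_seed=rng_seed,
    )
    structure = ndimage.generate_binary_structure(3, cl.CONNECTIVITY_RULES[connectivity])
    z_thresh = stats.norm.isf(voxel_p / 2.0)
    sigma_vox = cl._fwhm_to_sigma(np.broadcast_to(fwhm_mm, 3), grid.voxel_size)
    rng = np.random.default_rng(np.random.SeedSequence([rng_seed, 104729]))
    hits = 0
    for _ in range(n_evaluation):
        field = cl._simulate_null_field(rng, grid.shape, sigma_vox)
        if cl._max_cluster_extent(field, z_thresh, structure) >= k:
            hits += 1
    fwe = hits / n_evaluation
    return {
        "extent_k": int(k),
        "empirical_fwe": float(fwe),
        "mc_standard_error": float(np.sqrt(alpha * (1 - alpha) / n_evaluation)),
        "n_evaluation": int(n_evaluation),
        "alpha": alpha,
    }


# ---------------------------------------------------------------------------
# planted-coupling recovery through the full pipeline
# ---------------------------------------------------------------------------

def _recovery_grid() -> GridSpec:
    affine = np.diag([3.0, 3.0, 3.0, 1.0])
    affine[:3, 3] = (-19.5, -19.5, -19.5)
    return GridSpec(shape=(14, 14, 14), affine=affine, tr=syn.TR_S)


#: recovery study design: seed and target spheres on voxel centres, low
#: measurement noise so correlation attenuation is negligible against the SE
RECOVERY_SEED = cn.SeedSpec("plant_seed", (-10.5, 1.5, 1.5), radius_mm=4.0)
RECOVERY_TARGET = cn.SeedSpec("plant_target", (10.5, 1.5, 1.5), radius_mm=6.0)
RECOVERY_PLANT_KW = dict(
    coupling_intercept=0.15,
    coupling_slope_2back=0.5,
    coupling_slope_0back=0.0,
    latent_amplitude=1.0,
    noise_sd=0.2,
    smoothing_fwhm=4.0,
)

#: a steep, reliable within-session fatigue ramp: the study must separate
#: the fatigue slope from run effects, so the covariate needs spread within
#: subject relative to its noise
RECOVERY_VASF_PARAMS = syn.VasfEffectParams(
    baseline=20.0, group_offset=15.0, condition_offset=0.0, ms_condition_offset=0.0,
    rating_trend=6.0, intercept_scale=8.0, noise_sd=5.0,
)


@dataclass
class RecoveryReplicate:
    peak_in_target: bool
    slope_estimate: float
    ci_low: float
    ci_high: float
    implied_slope: float

    @property
    def slope_in_ci(self) -> bool:
        return self.ci_low <= self.implied_slope <= self.ci_high


def _mask_from_seed(seed: cn.SeedSpec, grid: GridSpec) -> np.ndarray:
    mask = np.zeros(grid.shape, dtype=bool)
    mask[tuple(cn.voxelize_seed(seed, grid).T)] = True
    return mask


def recovery_study(rng_seed: int = 0, n_subjects: int = 20, n_replicates: int = 20) -> list[RecoveryReplicate]:
    """Recover a 2-back-only fatigue-coupling slope with the full pipeline.

    Each replicate simulates ``n_subjects`` MS subjects (2 conditions x 4
    runs), runs the first-level deconvolution, builds per-run seed z-maps,
    and fits the group condition-by-fatigue model.  Success criteria per
    replicate: the interaction map's peak lies in the planted target
    region, and the 95% CI of the target-mean interaction slope covers the
    implied Fisher-z-scale estimand of the plant.
    """
    return [
        _one_recovery_replicate(np.random.SeedSequence([rng_seed, 7919, rep]), n_subjects)
        for rep in range(n_replicates)
    ]


def _one_recovery_replicate(seed_seq: np.random.SeedSequence, n_subjects: int) -> RecoveryReplicate:
    grid = _recovery_grid()
    seed_mask = _mask_from_seed(RECOVERY_SEED, grid)
    target_mask = _mask_from_seed(RECOVERY_TARGET, grid)
    plant = syn.PlantSpec(seed_region=seed_mask, target_region=target_mask, **RECOVERY_PLANT_KW)
    seeds = seed_seq.generate_state(4 + n_subjects * 16).astype(np.int64) % (2**31)
    cohort = syn.generate_cohort(n_subjects, 0, 0.5, rng_seed=int(seeds[0]))
    vasf = syn.generate_vasf(cohort, RECOVERY_VASF_PARAMS, rng_seed=int(seeds[1]))

    # generator-scale fatigue driving the plant
    runs = syn.run_mean_vasf(vasf)
    runs["fatigue_gen"] = syn.fatigue_covariate(runs["run_mean"])
    fat_gen = runs.set_index(["subject_id", "condition", "run_index"])["fatigue_gen"]

    # analysis-scale fatigue (Box-Cox + group mean centering), as in the pipeline
    run_fatigue = bh.compute_run_fatigue(vasf)
    run_fatigue, _ = bh.add_transformed_fatigue(run_fatigue)
    run_fatigue = gp.mean_center_by_group(run_fatigue)

    seed_vox = cn.voxelize_seed(RECOVERY_SEED, grid)
    zmaps = []
    s_idx = 4
    for subj in cohort.subjects:
        for condition in syn.CONDITIONS:
            scheds, bolds, confs = [], [], []
            for run in range(1, syn.N_RUNS + 1):
                sched = syn.generate_task_schedule(condition, run, rng_seed=int(seeds[s_idx]))
                fat = float(fat_gen.loc[(subj.subject_id, condition, run)])
                bold, conf = syn.simulate_bold(
                    subj, sched, fat, plant, grid, rng_seed=int(seeds[s_idx + 1])
                )
                s_idx += 2
                scheds.append(sched)
                bolds.append(bold)
                confs.append(conf)
            design = glm.build_design(scheds, confs, drift_order=3)
            result = glm.fit_glm(bolds[0].concat(*bolds[1:]), design)
            for run in range(1, syn.N_RUNS + 1):
                block = slice((run - 1) * syn.N_VOLUMES, run * syn.N_VOLUMES)
                run_resid = type(result.residuals)(result.residuals.data[..., block], grid)
                ts = cn.seed_series(run_resid, seed_vox, bolds[run - 1])
                zmaps.append(
                    cn.connectivity_zmap(
                        ts, run_resid,
                        subject_id=subj.subject_id, condition=condition,
                        run_index=run, seed_name="plant_seed",
                    )
                )
    stat = gp.voxelwise_fatigue_lme(zmaps, run_fatigue, "plant_seed", "MS")
    peak = np.unravel_index(np.argmax(np.abs(stat.estimate)), stat.estimate.shape)
    peak_in_target = bool(target_mask[peak])

    # single-response fit on the target-mean z for an accurate CI
    meta_rows, y = [], []
    fat_c = run_fatigue.set_index(["subject_id", "condition", "run_index"])["fatigue_c"]
    for m in zmaps:
        key = (m.subject_id, m.condition, m.run_index)
        if key not in fat_c.index or not np.isfinite(fat_c.loc[key]):
            continue
        meta_rows.append(
            {"subject_id": m.subject_id, "condition": m.condition,
             "run_index": m.run_index, "fatigue_c": float(fat_c.loc[key])}
        )
        y.append(m.zmap[target_mask].mean())
    meta = pd.DataFrame(meta_rows)
    X, names = gp._build_group_design(meta)
    fit = RandomInterceptLME(X, meta["subject_id"].to_numpy(), columns=names).fit(np.asarray(y))
    c = np.zeros(len(names))
    c[names.index("condition[2-back]:fatigue_c")] = 1.0
    res = fit.contrast(c)
    tcrit = stats.t.ppf(0.975, float(res.df))
    est, se = float(res.estimate), float(res.se)

    # implied estimand: OLS projection of atanh(planted r) onto the same design
    w_true = np.array(
        [
            plant.coupling(r.condition, float(fat_gen.loc[(r.subject_id, r.condition, r.run_index)]))
            for r in meta.itertuples()
        ]
    )
    beta_true = np.linalg.lstsq(X, np.arctanh(w_true), rcond=None)[0]
    implied = float(beta_true[names.index("condition[2-back]:fatigue_c")])
    return RecoveryReplicate(
        peak_in_target=peak_in_target,
        slope_estimate=est,
        ci_low=est - tcrit * se,
        ci_high=est + tcrit * se,
        implied_slope=implied,
    )


# ---------------------------------------------------------------------------
# behavioral recovery
# ---------------------------------------------------------------------------

def behavioral_recovery_study(rng_seed: int = 0, n_per_group: int = 200) -> dict:
    """Recover the planted group effect and 2-back fatigue-slope difference.

    Fits accuracy ~ group * condition * fatigue + (1 | subject) on a cohort
    generated with the default behavioral parameters, using the generator's
    own fatigue scale as the covariate so the planted slopes are the exact
    estimands.
    """
    seeds = np.random.SeedSequence([rng_seed, 65537]).generate_state(3) % (2**31)
    cohort = syn.generate_cohort(n_per_group, n_per_group, 0.5, rng_seed=int(seeds[0]))
    vasf = syn.generate_vasf(cohort, rng_seed=int(seeds[1]))
    params = syn.BehavioralParams()
    behav = syn.generate_behavior(cohort, vasf, params, rng_seed=int(seeds[2]))
    behav = behav.assign(fatigue_gen=syn.fatigue_covariate(behav["run_mean"]))
    fit = bh.fit_behavior_lme(behav, "accuracy", "group*condition*fatigue_gen")
    summ = fit.summary().set_index("term")
    slopes = bh.pairwise_contrasts(fit, "group:condition", slopes_of="fatigue_gen")
    row = slopes[slopes.contrast == "(HC, 2-back) - (MS, 2-back)"].iloc[0]
    true_diff = params.accuracy_slopes[("HC", "2-back")] - params.accuracy_slopes[("MS", "2-back")]
    tcrit_g = stats.t.ppf(0.975, float(summ.loc["group[MS]", "df"]))
    tcrit_s = stats.t.ppf(0.975, float(row.df))
    return {
        "group_effect_true": params.accuracy_group_offset,
        "group_effect_estimate": float(summ.loc["group[MS]", "estimate"]),
        "group_effect_ci": (
            float(summ.loc["group[MS]", "estimate"] - tcrit_g * summ.loc["group[MS]", "se"]),
            float(summ.loc["group[MS]", "estimate"] + tcrit_g * summ.loc["group[MS]", "se"]),
        ),
        "slope_diff_true": float(true_diff),
        "slope_diff_estimate": float(row.estimate),
        "slope_diff_ci": (float(row.estimate - tcrit_s * row.se), float(row.estimate + tcrit_s * row.se)),
        "slope_diff_p_tukey": float(row.p_tukey),
    }
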