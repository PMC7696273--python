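"""Stage orchestration: simulate -> first-level -> connectivity -> behavior
-> group -> clusters, with hashed, auditable artifacts at every stage."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as bh
from . import clusters as cl
from . import connectivity as cn
from . import glm
from . import group as gp
from . import io
from . import synthetic as syn
from .config import PipelineConfig
from .grids import Bold4D

__all__ = ["run_pipeline", "STAGES"]

STAGES = ("simulate", "first-level", "connectivity", "behavior", "group", "clusters")

log = logging.getLogger("resifc")


def _seed_specs(config: PipelineConfig) -> list[cn.SeedSpec]:
    if config.seeds is None:
        return list(cn.SEED_ATLAS)
    return [
        cn.SeedSpec(s["name"], tuple(s["center_mm"]), s.get("radius_mm", cn.DEFAULT_SEED_RADIUS_MM))
        for s in config.seeds
    ]


def _plant(config: PipelineConfig) -> syn.PlantSpec:
    grid = config.grid()
    seeds = {s.name: s for s in _seed_specs(config)}
    if config.plant_seed_name not in seeds:
        raise ValueError(f"plant_seed_name {config.plant_seed_name!r} is not a configured seed")
    seed_vox = cn.voxelize_seed(seeds[config.plant_seed_name], grid)
    seed_mask = np.zeros(grid.shape, dtype=bool)
    seed_mask[tuple(seed_vox.T)] = True
    target_vox = cn.voxelize_seed(
        cn.SeedSpec("plant_target", config.plant_target_center_mm, config.plant_target_radius_mm),
        grid,
    )
    target_mask = np.zeros(grid.shape, dtype=bool)
    target_mask[tuple(target_vox.T)] = True
    return syn.PlantSpec(
        seed_region=seed_mask,
        target_region=target_mask,
        coupling_intercept=config.coupling_intercept,
        coupling_slope_2back=config.coupling_slope_2back,
        coupling_slope_0back=config.coupling_slope_0back,
        latent_amplitude=config.latent_amplitude,
        noise_sd=config.noise_sd,
        smoothing_fwhm=config.smoothing_fwhm_mm,
        task_amplitude=config.task_amplitude,
    )


def _check_hash(meta_path: Path, config: PipelineConfig, needed_by: str) -> None:
    if not meta_path.exists():
        stage = meta_path.parent.name.replace("_", "-")
        raise FileNotFoundError(
            f"stage {needed_by!r} needs artifacts from stage {stage!r}; run it first"
        )
    meta = io.read_json(meta_path)
    if meta.get("config_hash") != config.config_hash():
        raise ValueError(
            f"{meta_path} was produced under config hash {meta.get('config_hash')}, "
            f"current config hash is {config.config_hash()}; refusing to mix artifacts"
        )


def _write_meta(stage_dir: Path, config: PipelineConfig, **extra) -> None:
    io.write_json(stage_dir / "meta.json", {"config_hash": config.config_hash(), **extra})


def _run_key(subject_id: str, condition: str, run_index: int) -> str:
    return f"{subject_id}_{condition.replace('-', '')}_run{run_index}"


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig, out: Path) -> None:
    d = out / "simulate"
    d.mkdir(parents=True, exist_ok=True)
    grid = config.grid()
    plant = _plant(config)
    cohort = syn.generate_cohort(
        config.n_ms, config.n_hc, config.between_subject_sd, rng_seed=config.rng_seed
    )
    vasf = syn.generate_vasf(cohort, rng_seed=config.rng_seed + 1)
    behavior = syn.generate_behavior(cohort, vasf, rng_seed=config.rng_seed + 2)
    io.write_table(cohort.frame, d / "cohort.tsv")
    io.write_table(vasf, d / "vasf.tsv")
    io.write_table(behavior, d / "behavior.tsv")
    runs = syn.run_mean_vasf(vasf)
    runs["fatigue_t"] = syn.fatigue_covariate(runs["run_mean"])
    fat = runs.set_index(["subject_id", "condition", "run_index"])["fatigue_t"]
    for si, subj in enumerate(cohort.subjects):
        for ci, condition in enumerate(syn.CONDITIONS):
            for run in range(1, syn.N_RUNS + 1):
                sched_seed = int(
                    np.random.SeedSequence([config.rng_seed, 11, si, ci, run]).generate_state(1)[0]
                    % (2**31)
                )
                bold_seed = int(
                    np.random.SeedSequence([config.rng_seed, 13, si, ci, run]).generate_state(1)[0]
                    % (2**31)
                )
                sched = syn.generate_task_schedule(condition, run, rng_seed=sched_seed)
                fatigue = float(fat.loc[(subj.subject_id, condition, run)])
                bold, conf = syn.simulate_bold(
                    subj, sched, fatigue, plant, grid, rng_seed=bold_seed
                )
                key = _run_key(subj.subject_id, condition, run)
                io.save_volume(d / f"bold_{key}.nii.gz", bold)
                io.write_table(sched.events_frame(), d / f"events_{key}.tsv")
                io.write_table(conf, d / f"confounds_{key}.tsv")
        log.info("simulated subject %s (%d/%d)", subj.subject_id, si + 1, len(cohort.subjects))
    _write_meta(d, config, rng_seed=config.rng_seed, n_subjects=len(cohort.subjects))


def _load_run(sim_dir: Path, subject_id: str, condition: str, run: int):
    key = _run_key(subject_id, condition, run)
    bold = io.load_volume(sim_dir / f"bold_{key}.nii.gz")
    events = io.read_table(sim_dir / f"events_{key}.tsv")
    conf = io.read_table(sim_dir / f"confounds_{key}.tsv")
    sched = syn.TrialSchedule(
        condition=condition,
        run_index=run,
        onsets=events["onset"].to_numpy(),
        durations=events["duration"].to_numpy(),
        target_flags=events["trial_type"].str.endswith("target").to_numpy(),
        letters=tuple(events["stimulus"]),
    )
    return bold, sched, conf


def stage_first_level(config: PipelineConfig, out: Path) -> None:
    sim = out / "simulate"
    _check_hash(sim / "meta.json", config, "first-level")
    d = out / "first_level"
    d.mkdir(parents=True, exist_ok=True)
    cohort = io.read_table(sim / "cohort.tsv")
    n_vol = syn.N_VOLUMES
    for _, subj in cohort.iterrows():
        for condition in syn.CONDITIONS:
            runs = [_load_run(sim, subj.subject_id, condition, r) for r in range(1, syn.N_RUNS + 1)]
            bold = runs[0][0].concat(*[r[0] for r in runs[1:]])
            design = glm.build_design(
                [r[1] for r in runs],
                [r[2] for r in runs],
                drift_order=config.drift_order,
                n_volumes=n_vol,
                tr=config.tr_s,
            )
            result = glm.fit_glm(bold, design)
            key = f"{subj.subject_id}_{condition.replace('-', '')}"
            io.save_volume(d / f"residuals_{key}.nii.gz", result.residuals)
            design.to_tsv(d / f"design_{key}.tsv")
        log.info("first-level model fitted for %s", subj.subject_id)
    _write_meta(d, config, n_volumes_per_run=n_vol)


def stage_connectivity(config: PipelineConfig, out: Path) -> None:
    sim, fl = out / "simulate", out / "first_level"
    _check_hash(fl / "meta.json", config, "connectivity")
    d = out / "connectivity"
    d.mkdir(parents=True, exist_ok=True)
    grid = config.grid()
    seeds = _seed_specs(config)
    seed_voxels = {s.name: cn.voxelize_seed(s, grid) for s in seeds}
    cohort = io.read_table(sim / "cohort.tsv")
    n_vol = syn.N_VOLUMES
    manifest = []
    for _, subj in cohort.iterrows():
        for condition in syn.CONDITIONS:
            key = f"{subj.subject_id}_{condition.replace('-', '')}"
            residuals = io.load_volume(fl / f"residuals_{key}.nii.gz")
            for run in range(1, syn.N_RUNS + 1):
                raw = io.load_volume(sim / f"bold_{_run_key(subj.subject_id, condition, run)}.nii.gz")
                block = slice((run - 1) * n_vol, run * n_vol)
                run_resid = Bold4D(residuals.data[..., block], grid)
                for seed in seeds:
                    ts = cn.seed_series(run_resid, seed_voxels[seed.name], raw)
                    cmap = cn.connectivity_zmap(
                        ts,
                        run_resid,
                        subject_id=subj.subject_id,
                        condition=condition,
                        run_index=run,
                        seed_name=seed.name,
                    )
                    fname = f"zmap_{_run_key(subj.subject_id, condition, run)}_{seed.name}.nii.gz"
                    io.save_map(d / fname, cmap.zmap, grid)
                    manifest.append(
                        {
                            "subject_id": subj.subject_id,
                            "group": subj.group,
                            "condition": condition,
                            "run_index": run,
                            "seed": seed.name,
                            "file": fname,
                        }
                    )
    io.write_table(pd.DataFrame(manifest), d / "manifest.tsv")
    _write_meta(d, config, n_maps=len(manifest))


def stage_behavior(config: PipelineConfig, out: Path) -> None:
    sim = out / "simulate"
    _check_hash(sim / "meta.json", config, "behavior")
    d = out / "behavior"
    d.mkdir(parents=True, exist_ok=True)
    vasf = io.read_table(sim / "vasf.tsv")
    behav = io.read_table(sim / "behavior.tsv")
    run_fatigue = bh.compute_run_fatigue(vasf)
    run_fatigue, bc = bh.add_transformed_fatigue(run_fatigue)
    run_fatigue = gp.mean_center_by_group(run_fatigue)
    io.write_table(run_fatigue, d / "run_fatigue.tsv")
    n_excluded = int(run_fatigue["excluded"].sum())
    log.info("behavior: %d runs excluded by the zero-fatigue rule", n_excluded)
    models = {"boxcox_lambda": bc.lmbda, "n_excluded_runs": n_excluded}
    vasf_fit = bh.fit_behavior_lme(run_fatigue, "transformed", "group*condition*run_index")
    models["vasf"] = vasf_fit.to_dict()
    merged = behav.merge(
        run_fatigue[["subject_id", "condition", "run_index", "fatigue_c", "excluded"]],
        on=["subject_id", "condition", "run_index"],
    )
    merged = merged.loc[~merged["excluded"]]
    for response in ("accuracy", "mean_rt"):
        fit = bh.fit_behavior_lme(merged, response, "group*condition*fatigue_c")
        entry = fit.to_dict()
        entry["tukey_slopes_by_group_condition"] = bh.pairwise_contrasts(
            fit, "group:condition", slopes_of="fatigue_c"
        ).to_dict(orient="records")
        models[response] = entry
    io.write_json(d / "models.json", models)
    _write_meta(d, config, n_excluded_runs=n_excluded)


def stage_group(config: PipelineConfig, out: Path) -> None:
    conn, beh = out / "connectivity", out / "behavior"
    _check_hash(conn / "meta.json", config, "group")
    _check_hash(beh / "meta.json", config, "group")
    d = out / "group"
    d.mkdir(parents=True, exist_ok=True)
    manifest = io.read_table(conn / "manifest.tsv")
    run_fatigue = io.read_table(beh / "run_fatigue.tsv")
    grid = config.grid()
    singular_counts = {}
    for seed in _seed_specs(config):
        for grp in syn.GROUPS:
            rows = manifest[(manifest["seed"] == seed.name) & (manifest["group"] == grp)]
            if rows.empty:
                continue
            maps = []
            for r in rows.itertuples():
                data, _ = io.load_map(conn / r.file)
                maps.append(
                    cn.ConnectivityMap(
                        subject_id=r.subject_id,
                        condition=r.condition,
                        run_index=int(r.run_index),
                        seed_name=seed.name,
                        zmap=data,
                        grid=grid,
                    )
                )
            stat = gp.voxelwise_fatigue_lme(maps, run_fatigue, seed.name, grp)
            key = f"{seed.name}_{grp}"
            io.save_map(d / f"stat_{key}_estimate.nii.gz", stat.estimate, grid)
            io.save_map(d / f"stat_{key}_z.nii.gz", stat.signed_z(), grid)
            io.save_map(d / f"stat_{key}_p.nii.gz", stat.pvalue, grid)
            singular_counts[key] = stat.singular_voxels
            if stat.singular_voxels:
                log.warning(
                    "group model %s: %d voxels with singular (OLS) fits", key, stat.singular_voxels
                )
    _write_meta(d, config, singular_voxel_counts=singular_counts)


def stage_clusters(config: PipelineConfig, out: Path) -> None:
    grp_dir, conn = out / "group", out / "connectivity"
    _check_hash(grp_dir / "meta.json", config, "clusters")
    d = out / "clusters"
    d.mkdir(parents=True, exist_ok=True)
    grid = config.grid()
    manifest = io.read_table(conn / "manifest.tsv")
    # smoothness from demeaned z-maps (noise smoothness proxy for the nulls)
    sample = manifest.head(24)
    maps = [io.load_map(conn / r.file)[0] for r in sample.itertuples()]
    stack = np.asarray(maps)
    demeaned = stack - stack.mean(axis=0)
    smooth = cl.estimate_smoothness(list(demeaned), grid)
    k, null = cl.montecarlo_extent_threshold(
        grid,
        smooth.fwhm_mm,
        voxel_p=config.voxel_p,
        alpha=config.alpha,
        n_sims=config.n_sims,
        connectivity=config.connectivity_rule,
        rng_seed=config.rng_seed + 17,
    )
    log.info("cluster-extent threshold k = %d voxels (FWHM %s mm)", k, smooth.fwhm_mm)
    tables = {}
    for seed in _seed_specs(config):
        for grp in syn.GROUPS:
            key = f"{seed.name}_{grp}"
            est_path = grp_dir / f"stat_{key}_estimate.nii.gz"
            if not est_path.exists():
                continue
            est, _ = io.load_map(est_path)
            z, _ = io.load_map(grp_dir / f"stat_{key}_z.nii.gz")
            p, _ = io.load_map(grp_dir / f"stat_{key}_p.nii.gz")
            stat = gp.GroupStatMap(
                seed_name=seed.name, group=grp, grid=grid,
                estimate=est, tstat=z, df=np.full(grid.shape, np.nan), pvalue=p,
            )
            table = cl.cluster_table(
                stat, voxel_p=config.voxel_p, extent_k=k, connectivity=config.connectivity_rule
            )
            io.write_table(table, d / f"clusters_{key}.tsv")
            tables[key] = len(table)
    io.write_json(
        d / "thresholds.json",
        {
            "extent_k": k,
            "fwhm_mm": list(smooth.fwhm_mm),
            "voxel_p": config.voxel_p,
            "alpha": config.alpha,
            "n_sims": null.n_sims,
            "empirical_fwe_at_k": null.exceedance(k),
            "clusters_per_table": tables,
        },
    )
    _write_meta(d, config, extent_k=k)


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "first-level": stage_first_level,
    "connectivity": stage_connectivity,
    "behavior": stage_behavior,
    "group": stage_group,
    "clusters": stage_clusters,
}


def run_pipeline(config: PipelineConfig, stage: str, out_dir) -> None:
    """Run one stage, or ``"all"`` in dependency order, writing to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not logging.getLogger().handlers:
        logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(out / "run.log")
    fh.setLevel(logging.INFO)
    log.addHandler(fh)
    try:
        cfg_path = out / "config.json"
        if not cfg_path.exists():
            cfg_path.write_text(config.to_json())
        log.info("config hash %s; stage %s", config.config_hash(), stage)
        if stage == "all":
            for s in STAGES:
                _STAGE_FUNCS[s](config, out)
        elif stage in _STAGE_FUNCS:
            _STAGE_FUNCS[stage](config, out)
        else:
            raise ValueError(f"unknown stage {stage!r}; choose from {STAGES + ('all',)}")
    finally:
        log.removeHandler(fh)
        fh.close()
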