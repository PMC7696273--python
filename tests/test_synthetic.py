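"""Generator contracts: cohorts, schedules, ratings, planted BOLD coupling."""

import numpy as np
import pandas as pd
import pytest

from resifc import glm
from resifc import synthetic as syn
from conftest import make_grid, make_plant


class TestCohort:
    def test_study_counts_and_uniqueness(self):
        cohort = syn.generate_cohort(26, 14, 0.5, rng_seed=0)
        frame = cohort.frame
        assert len(frame) == 40
        assert (frame["group"] == "MS").sum() == 26
        assert (frame["group"] == "HC").sum() == 14
        assert frame["subject_id"].is_unique

    def test_empty_cohort(self):
        assert syn.generate_cohort(0, 0, 0.5, rng_seed=1).frame.empty

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_cohort(-1, 5, 0.5, rng_seed=0)

    def test_intercept_sd_matches_request(self):
        # oracle: direct sample SD over the drawn values at large n
        cohort = syn.generate_cohort(1000, 1000, 0.5, rng_seed=7)
        sd = cohort.frame["subject_intercept"].std()
        assert abs(sd - 0.5) / 0.5 < 0.05

    def test_deterministic(self):
        a = syn.generate_cohort(5, 5, 0.5, rng_seed=3)
        b = syn.generate_cohort(5, 5, 0.5, rng_seed=3)
        assert a == b


class TestSchedule:
    @pytest.mark.parametrize("seed", [0, 1, 99])
    def test_trial_count_and_budget(self, seed):
        s = syn.generate_task_schedule("2-back", 1, rng_seed=seed)
        assert s.n_trials == 65
        assert s.run_length == 260.0
        # brute-force accumulation over the emitted timeline
        gaps = np.diff(s.onsets) - syn.TRIAL_LEN_S
        assert np.all(gaps >= -1e-12)
        total = s.onsets[0] + 65 * syn.TRIAL_LEN_S + gaps.sum()
        assert total == pytest.approx(260.0, abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 5])
    def test_six_null_events_multiple_of_trial_length(self, seed):
        s = syn.generate_task_schedule("0-back", 2, rng_seed=seed)
        gaps = np.diff(s.onsets) - syn.TRIAL_LEN_S
        nulls = gaps[gaps > 1e-9]
        assert len(nulls) == 6
        assert np.allclose(nulls % syn.TRIAL_LEN_S, 0.0, atol=1e-9)
        assert nulls.sum() == pytest.approx(130.0)

    def test_no_jitter_is_periodic(self):
        s = syn.generate_task_schedule("0-back", 1, rng_seed=0, n_null_events=0, run_length=130.0)
        assert np.allclose(s.onsets, np.arange(65) * 2.0)

    def test_impossible_budget_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_task_schedule("0-back", 1, rng_seed=0, n_null_events=0)
        with pytest.raises(ValueError):
            syn.generate_task_schedule("0-back", 1, rng_seed=0, run_length=261.0)

    def test_durations_and_determinism(self):
        a = syn.generate_task_schedule("2-back", 3, rng_seed=11)
        b = syn.generate_task_schedule("2-back", 3, rng_seed=11)
        assert np.array_equal(a.onsets, b.onsets)
        assert a.letters == b.letters
        assert np.all(a.durations == 1.5)

    def test_target_flags_follow_rule(self):
        s0 = syn.generate_task_schedule("0-back", 1, rng_seed=4)
        assert np.array_equal(s0.target_flags, np.array([c == "K" for c in s0.letters]))
        s2 = syn.generate_task_schedule("2-back", 1, rng_seed=4)
        expect = [i >= 2 and s2.letters[i] == s2.letters[i - 2] for i in range(65)]
        assert np.array_equal(s2.target_flags, np.array(expect))


class TestVasf:
    def test_five_ratings_each_and_bounds(self):
        cohort = syn.generate_cohort(3, 2, 0.5, rng_seed=0)
        vasf = syn.generate_vasf(cohort, rng_seed=0)
        counts = vasf.groupby(["subject_id", "condition"]).size()
        assert (counts == 5).all()
        assert vasf["score"].between(0, 100).all()

    def test_constant_when_noiseless(self):
        cohort = syn.CohortSpec((syn.Subject("hc001", "HC", 0.0),))
        p = syn.VasfEffectParams(baseline=30.0, group_offset=0.0, ms_condition_offset=0.0,
                                 rating_trend=0.0, intercept_scale=0.0, noise_sd=0.0)
        vasf = syn.generate_vasf(cohort, p, rng_seed=0)
        assert (vasf["score"] == 30.0).all()

    def test_zero_baseline_gives_all_zero(self):
        cohort = syn.CohortSpec((syn.Subject("hc001", "HC", 0.0),))
        p = syn.VasfEffectParams(baseline=0.0, group_offset=0.0, ms_condition_offset=0.0,
                                 rating_trend=0.0, intercept_scale=0.0, noise_sd=0.0)
        vasf = syn.generate_vasf(cohort, p, rng_seed=0)
        assert (vasf["score"] == 0.0).all()

    def test_group_offset_shifts_median(self):
        cohort = syn.generate_cohort(120, 120, 0.3, rng_seed=2)
        vasf = syn.generate_vasf(cohort, rng_seed=2)
        med = vasf.groupby("group")["score"].median()
        assert med["MS"] > med["HC"]


class TestBehavior:
    def test_ranges_and_load_effect(self):
        cohort = syn.generate_cohort(30, 30, 0.3, rng_seed=5)
        vasf = syn.generate_vasf(cohort, rng_seed=5)
        behav = syn.generate_behavior(cohort, vasf, rng_seed=5)
        assert behav["accuracy"].between(0, 1).all()
        assert (behav["mean_rt"] > 0).all()
        rt = behav.groupby("condition")["mean_rt"].mean()
        assert rt["2-back"] > rt["0-back"]


class TestSimulateBold:
    def test_volume_count_and_confounds_rows(self, small_grid, subject):
        plant = make_plant(small_grid)
        sched = syn.generate_task_schedule("2-back", 1, rng_seed=0)
        bold, conf = syn.simulate_bold(subject, sched, 0.0, plant, small_grid, rng_seed=0)
        assert bold.n_volumes == 140
        assert len(conf) == 140
        assert set(syn.cf.MOTION_COLUMNS) <= set(conf.columns)

    def test_fully_modeled_signal_leaves_no_residual(self, small_grid, subject):
        plant = make_plant(small_grid).without_effects()
        scheds = [syn.generate_task_schedule("0-back", r, rng_seed=r) for r in range(1, 5)]
        runs = [
            syn.simulate_bold(subject, s, 0.0, plant, small_grid, rng_seed=10 + i)
            for i, s in enumerate(scheds)
        ]
        bold = runs[0][0].concat(*[b for b, _ in runs[1:]])
        design = glm.build_design(scheds, [c for _, c in runs], drift_order=1)
        res = glm.fit_glm(bold, design)
        assert np.max(np.abs(res.residuals.data)) < 1e-6

    def test_coupling_attainability_enforced(self, small_grid, subject):
        plant = make_plant(small_grid, coupling_intercept=0.8, coupling_slope_2back=0.3)
        sched = syn.generate_task_schedule("2-back", 1, rng_seed=0)
        with pytest.raises(ValueError, match="not attainable"):
            syn.simulate_bold(subject, sched, 1.0, plant, small_grid, rng_seed=0)

    def test_region_outside_grid_rejected(self, small_grid, subject):
        plant = make_plant(make_grid(shape=(12, 12, 12)))
        sched = syn.generate_task_schedule("0-back", 1, rng_seed=0)
        with pytest.raises(ValueError, match="region"):
            syn.simulate_bold(subject, sched, 0.0, plant, small_grid, rng_seed=0)

    def test_deterministic(self, small_grid, subject):
        plant = make_plant(small_grid)
        sched = syn.generate_task_schedule("0-back", 1, rng_seed=1)
        a, ca = syn.simulate_bold(subject, sched, 0.5, plant, small_grid, rng_seed=42)
        b, cb = syn.simulate_bold(subject, sched, 0.5, plant, small_grid, rng_seed=42)
        assert np.array_equal(a.data, b.data)
        pd.testing.assert_frame_equal(ca, cb)

    def test_residual_coupling_tracks_fatigue(self, subject):
        """Seed-target residual correlation recovers the planted ramp.

        Pearson correlation is computed directly on the generated residual
        components (per-run GLM residuals at low noise).  The grid is large
        enough that the global-signal regressor, which necessarily carries a
        small share of the planted latents, does not bias the correlation.
        """
        grid = make_grid(shape=(16, 16, 16))
        plant = make_plant(grid, coupling_intercept=0.1, coupling_slope_2back=0.5,
                           noise_sd=0.3, drift_coeffs=(0.0,))
        fatigues = [-0.5, 0.0, 0.5, 1.0]
        got = []
        for i, f in enumerate(fatigues):
            rs = []
            for rep in range(3):  # a single run's correlation is too noisy
                sched = syn.generate_task_schedule("2-back", 1, rng_seed=10 * i + rep)
                bold, conf = syn.simulate_bold(
                    subject, sched, f, plant, grid, rng_seed=100 + 10 * i + rep
                )
                design = glm.build_design([sched], [conf], drift_order=1)
                res = glm.fit_glm(bold, design)
                seed_ts = res.residuals.data[np.asarray(plant.seed_region)].mean(axis=0)
                targ_ts = res.residuals.data[np.asarray(plant.target_region)].mean(axis=0)
                rs.append(np.corrcoef(seed_ts, targ_ts)[0, 1])
            got.append(np.mean(rs))
        planted = [plant.coupling("2-back", f) for f in fatigues]
        assert np.all(np.diff(got) > 0)  # monotone in fatigue
        assert np.allclose(got, planted, atol=0.25)  # sampling error only
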