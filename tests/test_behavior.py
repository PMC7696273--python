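"""Run-level fatigue, Box-Cox, behavioral mixed models and Tukey post hocs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from resifc import behavior as bh
from resifc import synthetic as syn


def ratings_frame(score_map):
    """score_map: {(subject, group, condition): [5 scores]}"""
    rows = []
    for (sid, grp, cond), scores in score_map.items():
        for k, s in enumerate(scores):
            rows.append(
                {"subject_id": sid, "group": grp, "condition": cond, "rating_index": k, "score": s}
            )
    return pd.DataFrame(rows)


class TestRunFatigue:
    def test_run_mean_is_pre_post_average(self):
        table = bh.compute_run_fatigue(
            ratings_frame({("s1", "HC", "0-back"): [30, 50, 10, 20, 40]})
        )
        assert len(table) == 4  # 5 ratings -> 4 runs
        r1 = table[table.run_index == 1].iloc[0]
        assert (r1.pre_score, r1.post_score, r1.run_mean) == (30, 50, 40)

    def test_zero_pre_and_post_excluded(self):
        table = bh.compute_run_fatigue(
            ratings_frame({("s1", "MS", "2-back"): [0, 0, 5, 0, 0]})
        )
        assert list(table.excluded) == [True, False, False, True]

    def test_missing_ratings_reported(self):
        frame = ratings_frame({("s1", "HC", "0-back"): [1, 2, 3, 4, 5]})
        frame = frame[frame.rating_index != 2]
        with pytest.raises(ValueError, match="missing rating"):
            bh.compute_run_fatigue(frame)

    @given(st.lists(st.floats(0, 100), min_size=5, max_size=5))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_exclusion_never_removes_nonzero_run(self, scores):
        table = bh.compute_run_fatigue(ratings_frame({("s1", "HC", "0-back"): scores}))
        for row in table.itertuples():
            if row.excluded:
                assert row.pre_score == 0.0 and row.post_score == 0.0


class TestBoxCox:
    def test_lambda_one_is_shifted_identity(self):
        x = np.array([1.0, 2.0, 5.0])
        res = bh.BoxCoxResult(lmbda=1.0, transformed=x - 1, loglik=0.0)
        assert np.allclose(res.transform(x), x - 1.0)

    def test_lognormal_recovers_lambda_near_zero(self):
        rng = np.random.default_rng(0)
        x = np.exp(rng.normal(1.0, 0.6, size=4000))
        res = bh.boxcox(x)
        assert abs(res.lmbda) < 0.1

    def test_monotone_for_estimated_lambda(self):
        rng = np.random.default_rng(1)
        x = np.sort(rng.uniform(0.5, 80.0, size=200))
        res = bh.boxcox(x)
        assert np.all(np.diff(res.transform(x)) >= 0)

    def test_agrees_with_scipy_reference(self):
        from scipy import stats

        rng = np.random.default_rng(2)
        x = rng.gamma(2.0, 10.0, size=500)
        ours = bh.boxcox(x)
        lam_ref = stats.boxcox_normmax(x, method="mle")
        assert ours.lmbda == pytest.approx(float(lam_ref), abs=1e-3)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            bh.boxcox(np.array([1.0, 0.0, 2.0]))

    def test_profile_concavity_near_optimum(self):
        from scipy import stats

        rng = np.random.default_rng(3)
        x = rng.gamma(3.0, 5.0, size=300)
        lam = bh.boxcox(x).lmbda
        lams = np.linspace(lam - 0.5, lam + 0.5, 21)
        ll = np.array([stats.boxcox_llf(l, x) for l in lams])
        d2 = np.diff(ll, 2)
        assert np.all(d2 < 0)


def simulated_behavior_table(n_per_group=60, seed=0, slopes=None, group_effect=0.0):
    """Accuracy-like response with planted group effect and fatigue slopes."""
    rng = np.random.default_rng(seed)
    rows = []
    for grp, n in (("HC", n_per_group), ("MS", n_per_group)):
        for s in range(n):
            sid = f"{grp}{s:04d}"
            u = rng.normal(0, 0.05)
            for cond in syn.CONDITIONS:
                for run in range(1, 5):
                    f = rng.normal(0.0, 1.0)
                    slope = (slopes or {}).get((grp, cond), 0.0)
                    y = (
                        0.9
                        + (group_effect if grp == "MS" else 0.0)
                        + u
                        + slope * f
                        + rng.normal(0, 0.05)
                    )
                    rows.append(
                        {
                            "subject_id": sid,
                            "group": grp,
                            "condition": cond,
                            "run_index": run,
                            "fatigue_c": f,
                            "accuracy": y,
                        }
                    )
    return pd.DataFrame(rows)


class TestFitBehaviorLme:
    def test_identical_responses_zero_effects(self):
        table = simulated_behavior_table(n_per_group=6, seed=1)
        table["accuracy"] = 0.5
        fit = bh.fit_behavior_lme(table, "accuracy", "group*condition")
        summ = fit.summary().set_index("term")
        assert summ.loc["Intercept", "estimate"] == pytest.approx(0.5)
        others = summ.drop("Intercept")["estimate"].abs()
        assert (others < 1e-10).all()

    def test_response_scaling_scales_estimates(self):
        table = simulated_behavior_table(n_per_group=8, seed=2, group_effect=0.1)
        f1 = bh.fit_behavior_lme(table, "accuracy", "group*condition")
        table2 = table.assign(accuracy=2.0 * table["accuracy"])
        f2 = bh.fit_behavior_lme(table2, "accuracy", "group*condition")
        assert np.allclose(
            2.0 * f1.summary()["estimate"], f2.summary()["estimate"], atol=1e-8
        )

    def test_group_effect_recovered_within_ci(self):
        delta = 0.08
        table = simulated_behavior_table(n_per_group=60, seed=3, group_effect=delta)
        fit = bh.fit_behavior_lme(table, "accuracy", "group*condition*fatigue_c")
        summ = fit.summary().set_index("term")
        est, se = summ.loc["group[MS]", ["estimate", "se"]]
        assert abs(est - delta) < 1.96 * se * 1.5

    def test_too_few_subjects_rejected(self):
        table = simulated_behavior_table(n_per_group=1, seed=4)
        with pytest.raises(ValueError, match="subjects"):
            bh.fit_behavior_lme(table, "accuracy", "group*condition")

    def test_excluded_rows_dropped_via_nan(self):
        table = simulated_behavior_table(n_per_group=5, seed=5)
        table.loc[table.index[:8], "fatigue_c"] = np.nan
        fit = bh.fit_behavior_lme(table, "accuracy", "group*condition*fatigue_c")
        assert len(fit.data) == len(table) - 8


class TestPairwiseContrasts:
    def test_two_level_factor_matches_unadjusted(self):
        table = simulated_behavior_table(n_per_group=10, seed=6, group_effect=0.05)
        fit = bh.fit_behavior_lme(table, "accuracy", "group*condition")
        out = bh.pairwise_contrasts(fit, "group")
        assert len(out) == 1
        assert out.loc[0, "p_tukey"] == pytest.approx(out.loc[0, "p_unadjusted"], rel=1e-6)

    def test_slope_difference_recovered(self):
        slopes = {("HC", "2-back"): 0.03, ("MS", "2-back"): -0.03}
        table = simulated_behavior_table(n_per_group=80, seed=7, slopes=slopes)
        fit = bh.fit_behavior_lme(table, "accuracy", "group*condition*fatigue_c")
        out = bh.pairwise_contrasts(fit, "group:condition", slopes_of="fatigue_c")
        row = out[out.contrast == "(HC, 2-back) - (MS, 2-back)"].iloc[0]
        assert row.estimate == pytest.approx(0.06, abs=3.0 * row.se)
        assert row.p_tukey < 0.01
        null_row = out[out.contrast == "(HC, 0-back) - (MS, 0-back)"].iloc[0]
        assert abs(null_row.estimate) < 3.0 * null_row.se

    def test_unknown_factor_rejected(self):
        table = simulated_behavior_table(n_per_group=5, seed=8)
        fit = bh.fit_behavior_lme(table, "accuracy", "group*condition")
        with pytest.raises(ValueError):
            bh.pairwise_contrasts(fit, "nonexistent")
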