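"""Smoothness estimation, Monte-Carlo extent calibration, cluster labeling."""

import numpy as np
import pandas as pd
import pytest
from scipy.ndimage import gaussian_filter

from resifc import clusters as cl
from resifc import group as gp
from conftest import make_grid


# ---------------------------------------------------------------------------
# brute-force flood fill oracle
# ---------------------------------------------------------------------------

OFFSETS = {
    "faces": [o for o in np.ndindex(3, 3, 3)
              if (np.abs(np.array(o) - 1).sum() == 1)],
    "faces+edges": [o for o in np.ndindex(3, 3, 3)
                    if 1 <= np.abs(np.array(o) - 1).sum() <= 2
                    and np.max(np.abs(np.array(o) - 1)) == 1],
    "faces+edges+corners": [o for o in np.ndindex(3, 3, 3)
                            if 1 <= np.abs(np.array(o) - 1).sum() <= 3],
}


def flood_fill_clusters(mask, connectivity):
    """Exhaustive DFS connected components on a boolean array."""
    offsets = [tuple(np.array(o) - 1) for o in OFFSETS[connectivity]]
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for start in np.argwhere(mask):
        start = tuple(start)
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            cur = stack.pop()
            comp.append(cur)
            for off in offsets:
                nb = tuple(np.array(cur) + off)
                if any(c < 0 or c >= s for c, s in zip(nb, mask.shape)):
                    continue
                if mask[nb] and not seen[nb]:
                    seen[nb] = True
                    stack.append(nb)
        comps.append(frozenset(comp))
    return set(comps)


class TestLabelClusters:
    def test_empty_map_no_clusters(self):
        assert cl.label_clusters(np.zeros((4, 4, 4))) == []

    def test_l_shaped_blob_single_cluster_under_faces(self):
        m = np.zeros((5, 5, 5))
        blob = [(1, 1, 1), (2, 1, 1), (3, 1, 1), (3, 2, 1), (3, 3, 1)]
        for v in blob:
            m[v] = 4.0
        out = cl.label_clusters(m, threshold=3.0, connectivity="faces")
        assert len(out) == 1
        assert out[0].size == 5
        assert {tuple(v) for v in out[0].voxels} == set(blob)

    def test_diagonal_voxels_connectivity_rules(self):
        m = np.zeros((4, 4, 4))
        m[1, 1, 1] = m[2, 2, 2] = 5.0
        assert len(cl.label_clusters(m, 1.0, "faces")) == 2
        assert len(cl.label_clusters(m, 1.0, "faces+edges")) == 2
        assert len(cl.label_clusters(m, 1.0, "faces+edges+corners")) == 1
        m2 = np.zeros((4, 4, 4))
        m2[1, 1, 1] = m2[2, 2, 1] = 5.0  # edge-touching
        assert len(cl.label_clusters(m2, 1.0, "faces")) == 2
        assert len(cl.label_clusters(m2, 1.0, "faces+edges")) == 1

    def test_positive_negative_separated(self):
        m = np.zeros((3, 3, 3))
        m[0, 0, 0] = 5.0
        m[0, 0, 1] = -5.0
        out = cl.label_clusters(m, 1.0, "faces")
        assert sorted(c.sign for c in out) == [-1, 1]

    def test_peak_is_max_abs_with_linear_tiebreak(self):
        m = np.zeros((4, 4, 4))
        m[1, 1, 1] = m[1, 1, 2] = 3.0  # tie -> smaller linear index wins
        m[1, 1, 3] = 2.0
        out = cl.label_clusters(m, 1.0, "faces")
        assert out[0].peak_index == (1, 1, 1)

    @pytest.mark.parametrize("connectivity", list(cl.CONNECTIVITY_RULES))
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_flood_fill_on_random_small_grids(self, connectivity, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(3, 9, size=3))
        m = np.where(rng.random(shape) < 0.35, rng.normal(size=shape) * 5, 0.0)
        ours = cl.label_clusters(m, threshold=1.0, connectivity=connectivity)
        for sign in (1, -1):
            mask = m > 1.0 if sign == 1 else m < -1.0
            oracle = flood_fill_clusters(mask, connectivity)
            got = {
                frozenset(tuple(v) for v in c.voxels) for c in ours if c.sign == sign
            }
            assert got == oracle


class TestSmoothness:
    def test_white_noise_hits_estimator_floor(self):
        grid = make_grid(shape=(24, 24, 24), voxel=3.0)
        rng = np.random.default_rng(0)
        maps = [rng.standard_normal(grid.shape) for _ in range(12)]
        est = cl.estimate_smoothness(maps, grid)
        floor = 3.0 * np.sqrt(2.0 * np.log(2.0))  # d * sqrt(2 ln 2)
        assert np.allclose(est.fwhm_mm, floor, rtol=0.10)

    def test_recovers_known_6mm_kernel(self):
        grid = make_grid(shape=(30, 30, 30), voxel=3.0)
        rng = np.random.default_rng(1)
        sigma_vox = 6.0 / (2 * np.sqrt(2 * np.log(2))) / 3.0
        maps = [gaussian_filter(rng.standard_normal((44, 44, 44)), sigma_vox)[7:37, 7:37, 7:37]
                for _ in range(10)]
        est = cl.estimate_smoothness(maps, grid)
        assert np.allclose(est.fwhm_mm, 6.0, rtol=0.15)

    def test_invariant_to_global_rescaling(self):
        grid = make_grid(shape=(12, 12, 12))
        rng = np.random.default_rng(2)
        maps = [rng.standard_normal(grid.shape) for _ in range(4)]
        a = cl.estimate_smoothness(maps, grid)
        b = cl.estimate_smoothness([7.3 * m for m in maps], grid)
        assert np.allclose(a.fwhm_mm, b.fwhm_mm)

    def test_constant_map_rejected(self):
        grid = make_grid(shape=(8, 8, 8))
        with pytest.raises(ValueError):
            cl.estimate_smoothness([np.ones(grid.shape), np.ones(grid.shape)], grid)


class TestMonteCarloThreshold:
    def test_degenerate_tiny_voxel_p(self):
        grid = make_grid(shape=(10, 10, 10))
        k, null = cl.montecarlo_extent_threshold(
            grid, fwhm=0.0, voxel_p=1e-12, n_sims=200, rng_seed=0
        )
        assert k == 1
        assert null.exceedance(1) == 0.0

    def test_independent_voxels_match_binomial_closed_form(self):
        # FWHM 0: P(any suprathreshold voxel) = 1 - (1 - p)^N
        grid = make_grid(shape=(10, 10, 10))
        p = 0.01
        _, null = cl.montecarlo_extent_threshold(
            grid, fwhm=0.0, voxel_p=p, alpha=0.5, n_sims=600, rng_seed=1
        )
        expect = 1.0 - (1.0 - p) ** grid.n_voxels
        got = null.exceedance(1)
        se = np.sqrt(expect * (1 - expect) / 600)
        assert abs(got - expect) < 4 * se + 0.02

    def test_k_nonincreasing_in_alpha(self):
        grid = make_grid(shape=(14, 14, 14))
        ks = []
        for alpha in (0.01, 0.05, 0.2):
            k, _ = cl.montecarlo_extent_threshold(
                grid, fwhm=6.0, voxel_p=0.01, alpha=alpha, n_sims=400, rng_seed=2
            )
            ks.append(k)
        assert ks == sorted(ks, reverse=True)

    def test_deterministic_given_seed(self):
        grid = make_grid(shape=(10, 10, 10))
        a = cl.montecarlo_extent_threshold(grid, 6.0, n_sims=200, rng_seed=5)
        b = cl.montecarlo_extent_threshold(grid, 6.0, n_sims=200, rng_seed=5)
        assert a[0] == b[0]
        assert np.array_equal(a[1].max_extents, b[1].max_extents)

    def test_invalid_arguments_rejected(self):
        grid = make_grid(shape=(8, 8, 8))
        with pytest.raises(ValueError):
            cl.montecarlo_extent_threshold(grid, 6.0, voxel_p=0.0)
        with pytest.raises(ValueError):
            cl.montecarlo_extent_threshold(grid, 6.0, n_sims=50)
        with pytest.raises(ValueError):
            cl.montecarlo_extent_threshold(grid, 6.0, connectivity="nope")


def statmap_with_blob(grid, center, strength=8.0, extent=2):
    est = np.zeros(grid.shape)
    p = np.ones(grid.shape)
    sl = tuple(slice(c - extent, c + extent + 1) for c in center)
    est[sl] = 0.5
    p[sl] = 2.0 * 1e-8
    est[center] = 1.0
    p[center] = 1e-12
    return gp.GroupStatMap(
        seed_name="s", group="MS", grid=grid, estimate=est,
        tstat=np.zeros(grid.shape), df=np.full(grid.shape, 20.0), pvalue=p,
    )


class TestClusterTable:
    def test_empty_when_nothing_survives(self):
        grid = make_grid(shape=(8, 8, 8))
        stat = gp.GroupStatMap(
            seed_name="s", group="HC", grid=grid,
            estimate=np.zeros(grid.shape), tstat=np.zeros(grid.shape),
            df=np.full(grid.shape, 10.0), pvalue=np.ones(grid.shape),
        )
        assert len(cl.cluster_table(stat, extent_k=5)) == 0

    def test_planted_blob_peak_recovered_in_mm(self):
        grid = make_grid(shape=(12, 12, 12), voxel=3.0)
        stat = statmap_with_blob(grid, (6, 6, 6))
        table = cl.cluster_table(stat, voxel_p=0.001, extent_k=5)
        assert len(table) == 1
        peak_mm = grid.voxel_to_mm(np.array([6, 6, 6]))
        got = table.loc[0, ["X", "Y", "Z"]].to_numpy(dtype=float)
        assert np.all(np.abs(got - peak_mm) <= 3.0)  # within one voxel
        assert table.loc[0, "Voxels"] == 5 ** 3
        assert table.loc[0, "Z Stat"] > 0

    def test_all_counts_at_least_extent_k(self):
        grid = make_grid(shape=(12, 12, 12))
        stat = statmap_with_blob(grid, (4, 4, 4), extent=1)
        for k in (1, 10, 30):
            table = cl.cluster_table(stat, extent_k=k)
            assert (table["Voxels"] >= k).all()

    def test_extent_k_validation(self):
        grid = make_grid(shape=(6, 6, 6))
        stat = statmap_with_blob(grid, (3, 3, 3), extent=1)
        with pytest.raises(ValueError):
            cl.cluster_table(stat, extent_k=0)
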