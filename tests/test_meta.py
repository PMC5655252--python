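"""Random-effects pooling, heterogeneity, and meta-regression."""

import numpy as np
import pytest
from scipy import stats

import coordmeta as cm
from coordmeta.meta import _metareg_arrays


def _random_instance(rng, k=None):
    k = k or int(rng.integers(3, 12))
    g = rng.normal(0.3, 0.5, k)
    v = rng.uniform(0.02, 0.3, k)
    return g, v


def brute_force_dl(g, v):
    """Textbook DerSimonian–Laird, written independently of the package."""
    w = [1.0 / vi for vi in v]
    gbar = sum(wi * gi for wi, gi in zip(w, g)) / sum(w)
    Q = sum(wi * (gi - gbar) ** 2 for wi, gi in zip(w, g))
    C = sum(w) - sum(wi**2 for wi in w) / sum(w)
    tau2 = max(0.0, (Q - (len(g) - 1)) / C)
    ws = [1.0 / (vi + tau2) for vi in v]
    mu = sum(wi * gi for wi, gi in zip(ws, g)) / sum(ws)
    se = (1.0 / sum(ws)) ** 0.5
    return tau2, Q, mu, se


class TestDLTau2:
    def test_worked_example(self):
        # g=(0.2,0.6), v=(0.04,0.04): Q=2, C=25, tau2=0.04
        g, v = [0.2, 0.6], [0.04, 0.04]
        assert cm.dl_tau2(g, v) == pytest.approx(0.04, abs=1e-12)
        res = cm.pool_voxel(g, v)
        assert res.Q == pytest.approx(2.0, abs=1e-12)
        assert res.tau2 == pytest.approx(0.04, abs=1e-12)
        assert res.pooled_effect == pytest.approx(0.4, abs=1e-12)
        assert res.pooled_se == pytest.approx(0.2, abs=1e-12)
        assert res.z == pytest.approx(2.0, abs=1e-12)
        assert res.p_two_tailed == pytest.approx(2 * stats.norm.sf(2.0), abs=1e-12)

    def test_identical_effects_zero_tau2(self):
        assert cm.dl_tau2([0.5] * 6, [0.1] * 6) == 0.0

    def test_variance_scaling_consistency(self):
        g = [0.1, 0.5, 0.9, 0.3]
        v = [0.05, 0.08, 0.02, 0.1]
        for c in (0.5, 2.0, 10.0):
            scaled = cm.dl_tau2(g, [c * vi for vi in v])
            # closed form evaluated symbolically: Q/c, C/c
            w = [1.0 / vi for vi in v]
            gbar = sum(wi * gi for wi, gi in zip(w, g)) / sum(w)
            Q = sum(wi * (gi - gbar) ** 2 for wi, gi in zip(w, g))
            C = sum(w) - sum(wi**2 for wi in w) / sum(w)
            expected = max(0.0, (Q / c - 3) / (C / c))
            assert scaled == pytest.approx(expected, abs=1e-12)

    def test_single_study_rejected(self):
        with pytest.raises(ValueError):
            cm.dl_tau2([0.5], [0.1])
        with pytest.raises(ValueError):
            cm.pool_voxel([0.5], [0.1])


class TestPooling:
    def test_equal_variances_give_arithmetic_mean(self):
        res = cm.pool_voxel([0.1, 0.7], [0.05, 0.05])
        assert res.pooled_effect == pytest.approx(0.4)

    def test_forced_zero_tau2_is_fixed_effect(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            g, v = _random_instance(rng)
            res = cm.pool_voxel(g, v, tau2=0.0)
            w = 1.0 / v
            assert res.pooled_effect == pytest.approx((w * g).sum() / w.sum(), abs=1e-12)
            assert res.pooled_se == pytest.approx((1.0 / w.sum()) ** 0.5, abs=1e-12)

    def test_pooled_se_below_any_study_random_effects_se(self):
        # on the random-effects scale each study's SE is sqrt(v_i + tau2);
        # the pooled SE is strictly below even the smallest of them
        rng = np.random.default_rng(2)
        for _ in range(30):
            g, v = _random_instance(rng)
            res = cm.pool_voxel(g, v)
            assert res.pooled_se < np.sqrt(v + res.tau2).min()

    def test_k_identical_studies_closed_form_se(self):
        for k in (2, 5, 11):
            res = cm.pool_voxel([0.4] * k, [0.09] * k)
            assert res.pooled_se == pytest.approx((0.09 / k) ** 0.5, abs=1e-12)
            assert res.tau2 == 0.0

    def test_q_invariant_to_effect_shift(self):
        rng = np.random.default_rng(3)
        g, v = _random_instance(rng, k=7)
        q0 = cm.pool_voxel(g, v).Q
        q1 = cm.pool_voxel(g + 1.7, v).Q
        assert q1 == pytest.approx(q0, rel=1e-10)

    def test_z_consistent_with_p(self):
        res = cm.pool_voxel([0.3, 0.9, 0.1], [0.04, 0.06, 0.1])
        assert res.z == pytest.approx(res.pooled_effect / res.pooled_se)
        assert res.p_two_tailed == pytest.approx(2 * stats.norm.sf(abs(res.z)))


class TestPooledMaps:
    def _identical_maps(self, grid, k, value=0.6, v=0.1):
        eff = cm.VolumeMap(grid, np.full(grid.n_voxels, value), "effect_size")
        var = cm.VolumeMap(grid, np.full(grid.n_voxels, v), "variance")
        return [cm.StudyMaps(f"S{i}", eff, var) for i in range(k)]

    def test_identical_copies_reproduce_map(self, small_grid):
        maps = cm.pooled_maps(self._identical_maps(small_grid, 5))
        assert np.allclose(maps["effect"].values, 0.6)
        assert np.all(maps["tau2"].values == 0.0)
        assert np.allclose(maps["se"].values, (0.1 / 5) ** 0.5)

    def test_outputs_cover_only_the_mask(self, small_grid):
        maps = cm.pooled_maps(self._identical_maps(small_grid, 3))
        for m in maps.values():
            assert m.values.shape == (small_grid.n_voxels,)
            assert m.grid == small_grid

    def test_grid_mismatch_rejected(self, small_grid):
        other = cm.BrainGrid.from_box(half_extent_mm=20.0, voxel_mm=2.0, mask_radius_mm=18.0)
        maps = self._identical_maps(small_grid, 2) + self._identical_maps(other, 1)
        with pytest.raises(ValueError, match="grid"):
            cm.pooled_maps(maps)

    def test_voxelwise_matches_scalar_pooling(self, small_grid):
        rng = np.random.default_rng(4)
        k = 6
        sm = []
        for i in range(k):
            g = rng.normal(0, 0.5, small_grid.n_voxels)
            v = rng.uniform(0.05, 0.2, small_grid.n_voxels)
            sm.append(
                cm.StudyMaps(
                    f"S{i}",
                    cm.VolumeMap(small_grid, g, "effect_size"),
                    cm.VolumeMap(small_grid, v, "variance"),
                )
            )
        maps = cm.pooled_maps(sm)
        for vox in (0, 100, small_grid.n_voxels - 1):
            res = cm.pool_voxel(
                [m.effect.values[vox] for m in sm], [m.variance.values[vox] for m in sm]
            )
            assert maps["effect"].values[vox] == pytest.approx(res.pooled_effect, abs=1e-12)
            assert maps["tau2"].values[vox] == pytest.approx(res.tau2, abs=1e-12)


class TestHeterogeneityMap:
    def test_identical_studies_zero_q(self, small_grid):
        eff = cm.VolumeMap(small_grid, np.full(small_grid.n_voxels, 0.4), "effect_size")
        var = cm.VolumeMap(small_grid, np.full(small_grid.n_voxels, 0.1), "variance")
        q, p = cm.q_heterogeneity_map([cm.StudyMaps(f"S{i}", eff, var) for i in range(4)])
        assert np.allclose(q.values, 0.0)
        assert np.allclose(p.values, 1.0)

    def test_two_study_closed_form(self, small_grid):
        d1, d2, v = 0.2, 0.9, 0.05
        sm = [
            cm.StudyMaps(
                "A",
                cm.VolumeMap(small_grid, np.full(small_grid.n_voxels, d1), "effect_size"),
                cm.VolumeMap(small_grid, np.full(small_grid.n_voxels, v), "variance"),
            ),
            cm.StudyMaps(
                "B",
                cm.VolumeMap(small_grid, np.full(small_grid.n_voxels, d2), "effect_size"),
                cm.VolumeMap(small_grid, np.full(small_grid.n_voxels, v), "variance"),
            ),
        ]
        q, p = cm.q_heterogeneity_map(sm)
        assert np.allclose(q.values, (d1 - d2) ** 2 / (2 * v))
        assert np.allclose(p.values, stats.chi2.sf((d1 - d2) ** 2 / (2 * v), 1))

    def test_planted_heterogeneity_is_localised(self, small_grid):
        # half the studies carry 0.3, half 0.9, inside a blob; Q concentrates there
        rng = np.random.default_rng(5)
        coords = small_grid.mask_coords_mm()
        blob = np.linalg.norm(coords - np.array([4.0, -4.0, 0.0]), axis=1) <= 8.0
        sm = []
        for i in range(10):
            base = 0.3 if i % 2 == 0 else 0.9
            g = rng.normal(0.0, 0.01, small_grid.n_voxels)
            g[blob] += base
            sm.append(
                cm.StudyMaps(
                    f"S{i}",
                    cm.VolumeMap(small_grid, g, "effect_size"),
                    cm.VolumeMap(small_grid, np.full(small_grid.n_voxels, 0.02), "variance"),
                )
            )
        q, p = cm.q_heterogeneity_map(sm)
        sig = p.values < 0.001
        assert sig[blob].mean() > 0.95
        assert sig[~blob].mean() < 0.01


def brute_force_metareg(g, v, x):
    """Independent WLS meta-regression with moment tau2 (matrix form)."""
    g, v, x = map(np.asarray, (g, v, x))
    X = np.column_stack([np.ones_like(x), x])
    W0 = np.diag(1.0 / v)
    A = X.T @ W0 @ X
    beta0 = np.linalg.solve(A, X.T @ W0 @ g)
    resid = g - X @ beta0
    Q = float(resid @ W0 @ resid)
    P = W0 - W0 @ X @ np.linalg.solve(A, X.T @ W0)
    C = float(np.trace(np.diag(1.0 / v))) - float(
        np.trace(np.linalg.solve(A, X.T @ (W0 @ W0) @ X))
    )
    tau2 = max(0.0, (Q - (len(g) - 2)) / C)
    W = np.diag(1.0 / (v + tau2))
    Aw = X.T @ W @ X
    beta = np.linalg.solve(Aw, X.T @ W @ g)
    cov = np.linalg.inv(Aw)
    return float(beta[1]), float(np.sqrt(cov[1, 1])), tau2


class TestMetaRegression:
    def test_two_studies_rejected(self):
        with pytest.raises(ValueError):
            cm.meta_regress_voxel([0.1, 0.5], [0.05, 0.05], [1.0, 2.0])

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cm.meta_regress_voxel([0.1, 0.5, 0.3], [0.05] * 3, [2.0, 2.0, 2.0])

    def test_missing_covariates_dropped_and_counted(self):
        res = cm.meta_regress_voxel(
            [0.1, 0.5, 0.3, 0.6], [0.05] * 4, [1.0, None, 2.0, 3.0]
        )
        assert res.n_studies_used == 3

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            k = int(rng.integers(4, 15))
            g = rng.normal(0.2, 0.4, k)
            v = rng.uniform(0.02, 0.2, k)
            x = rng.normal(65, 5, k)
            res = cm.meta_regress_voxel(g, v, x)
            slope, se, _ = brute_force_metareg(g, v, x)
            assert res.slope == pytest.approx(slope, abs=1e-10)
            assert res.slope_se == pytest.approx(se, abs=1e-10)
            assert res.z == pytest.approx(res.slope / res.slope_se)

    def test_null_covariate_slope_unbiased(self):
        rng = np.random.default_rng(7)
        slopes = []
        for _ in range(300):
            k = 18
            v = np.full(k, 0.1)
            g = rng.normal(0.4, np.sqrt(v))
            x = rng.normal(68, 4, k)
            slopes.append(cm.meta_regress_voxel(g, v, x).slope)
        mc_se = np.std(slopes) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes)) < 2 * mc_se + 1e-4

    def test_map_interface_matches_scalar(self, small_grid):
        rng = np.random.default_rng(8)
        k = 8
        x = rng.normal(65, 5, k)
        sm = [
            cm.StudyMaps(
                f"S{i}",
                cm.VolumeMap(small_grid, rng.normal(0, 0.4, small_grid.n_voxels), "effect_size"),
                cm.VolumeMap(small_grid, rng.uniform(0.05, 0.2, small_grid.n_voxels), "variance"),
            )
            for i in range(k)
        ]
        maps, n_used = cm.meta_regress_maps(sm, x)
        assert n_used == k
        vox = 321
        res = cm.meta_regress_voxel(
            [m.effect.values[vox] for m in sm],
            [m.variance.values[vox] for m in sm],
            x,
        )
        assert maps["slope"].values[vox] == pytest.approx(res.slope, abs=1e-12)
        assert maps["p"].values[vox] == pytest.approx(res.p, abs=1e-12)
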